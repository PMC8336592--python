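"""Ground-truth verification machinery.

Everything here is deliberately independent of the selection algorithms: paths
are enumerated explicitly from the edge structure, distances are computed by
shortest-path dynamic programming over (vertex, string-offset) states, and the
brute-force solver tries every subset of loci.  Intended for small instances;
path enumeration is exponential in local branching and guarded by a cap.

Compatibility (the property the selection algorithms must preserve): every
string spelled by a path with ``alpha`` labeled edges in the complete graph
must map, starting from its corresponding vertex in the reduced graph, within
``delta`` differences — positionwise Hamming distance for SNP-only graphs,
semi-global edit distance (whole string consumed, path end free) otherwise.
A path that starts inside a dropped insertion is anchored at the insertion's
host coordinate vertex.
"""

from __future__ import annotations

import heapq
import itertools
from dataclasses import dataclass
from typing import Iterator

import numpy as np

from .graph_model import (
    DEL,
    INS,
    SNP,
    SelectionResult,
    VariationGraph,
    make_selection,
)
from .indel_select import compute_penalties, compute_windows, window_removed_penalties

HAMMING = "hamming"
EDIT = "edit"


class InstanceTooLargeError(RuntimeError):
    """Raised instead of silently truncating an enumeration."""


@dataclass(frozen=True)
class GraphPath:
    """A path with exactly alpha labeled edges; spells ``string``."""

    start: object  # coordinate int or insertion-chain vertex tuple
    edges: tuple
    string: str


@dataclass(frozen=True)
class CompatibilityReport:
    compatible: bool
    n_paths_checked: int
    worst: tuple  # (start, string, distance)
    metric: str
    delta: int


def _ins_vertex(coord: int, allele: str, k: int) -> tuple:
    return ("ins", coord, allele, k)


def build_adjacency(graph: VariationGraph) -> dict:
    """Edge-labeled adjacency: vertex -> list of (target, label, edge_key).

    Coordinate vertices are ints 0..|R|; an insertion allele a at coordinate c
    contributes a chain v_c -a[0]-> w_1 -a[1]-> ... -a[-1]-> v_c whose interior
    vertices are ("ins", c, a, k).  Deletion edges carry label None (epsilon).
    """
    adj: dict = {}
    seq = graph.axis.sequence
    L = graph.axis.length

    def add(u, target, label, key):
        adj.setdefault(u, []).append((target, label, key))

    for i in range(L):
        add(i, i + 1, seq[i], ("ref", i))
    adj.setdefault(L, [])

    for locus in graph.loci:
        c = locus.coordinate
        for v in locus.variants:
            if v.vtype == SNP:
                add(c, c + 1, v.allele, ("snp", c, v.allele))
            elif v.vtype == DEL:
                add(c, c + v.span, None, ("del", c, v.span))
            elif v.vtype == INS:
                a = v.allele
                prev = c
                for k in range(1, len(a)):
                    w = _ins_vertex(c, a, k)
                    add(prev, w, a[k - 1], ("insedge", c, a, k - 1))
                    prev = w
                add(prev, c, a[-1], ("insedge", c, a, len(a) - 1))
    return adj


def graph_vertices(graph: VariationGraph) -> list:
    """All coordinate vertices plus insertion-chain interior vertices."""
    verts: list = list(range(graph.axis.length + 1))
    for locus in graph.loci:
        for v in locus.variants:
            if v.vtype == INS:
                verts.extend(
                    _ins_vertex(locus.coordinate, v.allele, k)
                    for k in range(1, len(v.allele))
                )
    return verts


def enumerate_alpha_paths(
    graph: VariationGraph,
    alpha: int,
    max_paths: int = 10**6,
    starts=None,
) -> Iterator[GraphPath]:
    """Yield every path with exactly alpha labeled edges from every start.

    Two admissibility rules, both serving the same purpose — a path uses at
    most one insertion traversal per coordinate: no vertex is visited more
    than twice, and an insertion chain is entered at most once per host
    coordinate (a partial second entry would let a path collect an
    insertion's characters twice, voiding the per-locus penalty bound).  A
    path starting inside a chain counts as that chain's one traversal.
    """
    if alpha < 1:
        raise ValueError(f"alpha must be >= 1, got {alpha}")
    adj = build_adjacency(graph)
    if starts is None:
        starts = graph_vertices(graph)
    count = 0

    labels: list[str] = []
    edges: list = []

    def dfs(u, visits, ins_used, n_labeled) -> Iterator[GraphPath]:
        nonlocal count
        if n_labeled == alpha:
            count += 1
            if count > max_paths:
                raise InstanceTooLargeError(
                    f"more than {max_paths} alpha-paths; raise max_paths explicitly"
                )
            yield GraphPath(start, tuple(edges), "".join(labels))
            return
        for target, label, key in adj.get(u, ()):
            if visits.get(target, 0) >= 2:
                continue
            entering = key[0] == "insedge" and key[3] == 0
            if entering and ins_used.get(key[1], 0) >= 1:
                continue
            if entering:
                ins_used[key[1]] = ins_used.get(key[1], 0) + 1
            visits[target] = visits.get(target, 0) + 1
            edges.append(key)
            if label is not None:
                labels.append(label)
            yield from dfs(target, visits, ins_used, n_labeled + (label is not None))
            if label is not None:
                labels.pop()
            edges.pop()
            visits[target] -= 1
            if entering:
                ins_used[key[1]] -= 1

    for start in starts:
        if start not in adj and not isinstance(start, tuple):
            continue
        ins_used = {start[1]: 1} if isinstance(start, tuple) else {}
        yield from dfs(start, {start: 1}, ins_used, 0)


def min_distance_from_vertex(
    string: str,
    graph: VariationGraph,
    start_vertex,
    metric: str = EDIT,
    adjacency: dict | None = None,
) -> float:
    """Minimum distance of ``string`` against paths of ``graph`` starting at
    ``start_vertex``.

    Hamming: positionwise mismatches against paths with exactly ``len(string)``
    labeled edges (epsilon edges are free).  Edit: semi-global unit-cost edit
    distance — the whole string must be consumed, the path end is free.
    Computed as a shortest path over (vertex, offset) states (Dijkstra; costs
    are non-negative and insertion chains create cycles).  Returns ``inf`` if
    no admissible path exists (Hamming on a too-short backbone).
    """
    if metric not in (HAMMING, EDIT):
        raise ValueError(f"unknown metric {metric!r}")
    adj = adjacency if adjacency is not None else build_adjacency(graph)
    if start_vertex not in adj:
        raise ValueError(
            f"start vertex {start_vertex!r} absent from graph; remap dropped-"
            "insertion starts to the host coordinate vertex first"
        )
    m = len(string)
    dist: dict = {}
    heap = [(0, 0, start_vertex, 0)]  # (cost, tiebreak, vertex, offset)
    tie = itertools.count()
    while heap:
        cost, _, u, k = heapq.heappop(heap)
        if (u, k) in dist:
            continue
        dist[(u, k)] = cost
        if k == m:
            return cost
        for target, label, _key in adj.get(u, ()):
            if label is None:
                step = [(target, k, 0)]
            else:
                step = [(target, k + 1, 0 if label == string[k] else 1)]
                if metric == EDIT:
                    step.append((target, k, 1))  # extra path char
            for tv, tk, c in step:
                if (tv, tk) not in dist:
                    heapq.heappush(heap, (cost + c, next(tie), tv, tk))
        if metric == EDIT and (u, k + 1) not in dist:
            heapq.heappush(heap, (cost + 1, next(tie), u, k + 1))  # extra string char
    return float("inf")


def _map_start(start, reduced: VariationGraph):
    """Corresponding start vertex in the reduced graph: identical if still
    present, else the closest coordinate-axis vertex (the insertion's host)."""
    if not isinstance(start, tuple):
        return start
    _, coord, allele, _k = start
    for c in reduced.variant_coordinates:
        if int(c) == coord:
            locus = reduced.locus_at(coord)
            if any(v.vtype == INS and v.allele == allele for v in locus.variants):
                return start
            break
    return coord


def verify_compatibility(
    graph: VariationGraph,
    reduced: VariationGraph,
    alpha: int,
    delta: int,
    metric: str | None = None,
    max_paths: int = 10**6,
) -> CompatibilityReport:
    """Check every alpha-path of the complete graph against the reduced one."""
    if metric is None:
        metric = HAMMING if graph.snp_only else EDIT
    adj_red = build_adjacency(reduced)
    cache: dict = {}
    worst = (None, "", 0)
    n_checked = 0
    for path in enumerate_alpha_paths(graph, alpha, max_paths=max_paths):
        n_checked += 1
        start = _map_start(path.start, reduced)
        key = (start, path.string)
        if key not in cache:
            cache[key] = min_distance_from_vertex(
                path.string, reduced, start, metric=metric, adjacency=adj_red
            )
        if cache[key] > worst[2]:
            worst = (path.start, path.string, cache[key])
    return CompatibilityReport(
        compatible=worst[2] <= delta,
        n_paths_checked=n_checked,
        worst=worst,
        metric=metric,
        delta=delta,
    )


def window_start_bfs(graph: VariationGraph, alpha: int, locus_coordinate: int) -> int:
    """Independent window oracle: leftmost coordinate from which the locus
    vertex is reachable with < alpha labeled edges, by 0-1 BFS over the
    deletion-only graph traversed backwards (backbone edge costs 1, deletion
    edge costs 0)."""
    from collections import deque

    dels_by_target: dict[int, list[int]] = {}
    for locus in graph.loci:
        for v in locus.variants:
            if v.vtype == DEL:
                dels_by_target.setdefault(v.coordinate + v.span, []).append(v.coordinate)

    dist = {locus_coordinate: 0}
    dq = deque([locus_coordinate])
    best = locus_coordinate
    while dq:
        u = dq.popleft()
        d = dist[u]
        best = min(best, u)
        for src in dels_by_target.get(u, ()):  # epsilon, cost 0
            if src not in dist or dist[src] > d:
                dist[src] = d
                dq.appendleft(src)
        if u - 1 >= 0 and d + 1 < alpha:  # labeled backbone edge, cost 1
            if u - 1 not in dist or dist[u - 1] > d + 1:
                dist[u - 1] = d + 1
                dq.append(u - 1)
    return best


def brute_force_select(
    graph: VariationGraph,
    alpha: int,
    delta: int,
    objective: str = "positions",
    feasibility: str = "windows",
    metric: str | None = None,
    max_loci: int = 16,
) -> SelectionResult:
    """Exhaustive optimum over all 2^n locus subsets.

    ``feasibility='windows'`` checks the window/penalty constraint system
    (exact for SNP-only graphs, where it coincides with Hamming
    compatibility); ``feasibility='oracle'`` runs full path verification per
    subset and is far costlier (guarded to n <= 10).
    """
    n = graph.n_loci
    if n > max_loci:
        raise InstanceTooLargeError(f"{n} loci exceeds brute-force limit {max_loci}")
    if objective not in ("positions", "variants"):
        raise ValueError(f"unknown objective {objective!r}")
    p = graph.variant_coordinates
    gains = (
        np.ones(n, dtype=np.int64)
        if objective == "positions"
        else np.asarray([l.n_variants for l in graph.loci], dtype=np.int64)
    )

    if n == 0:
        return make_selection(graph, set(), "brute_force", alpha, delta)

    if feasibility == "windows":
        windows = compute_windows(graph, alpha)
        penalties = compute_penalties(graph)
        pen = penalties.penalty
        lo = np.searchsorted(p, windows.window_start, side="left")
        W = np.zeros((n, n), dtype=np.int64)
        for i in range(n):
            W[i, lo[i] : i + 1] = pen[lo[i] : i + 1]
        subsets = np.arange(2**n, dtype=np.uint32)
        bits = ((subsets[:, None] >> np.arange(n)) & 1).astype(np.int64)
        feas = np.all(bits @ W.T <= delta, axis=1)
        obj = bits @ gains
        obj[~feas] = -1
        best = int(np.argmax(obj))
        removed = {int(p[j]) for j in range(n) if (best >> j) & 1}
        return make_selection(
            graph, removed, "brute_force", alpha, delta, meta={"objective": int(obj[best])}
        )

    if feasibility == "oracle":
        if n > 10:
            raise InstanceTooLargeError(f"oracle-mode brute force limited to 10 loci, got {n}")
        from .graph_model import apply_selection

        best_obj, best_removed = -1, set()
        for mask in range(2**n):
            removed = {int(p[j]) for j in range(n) if (mask >> j) & 1}
            sel = make_selection(graph, removed, "candidate", alpha, delta)
            report = verify_compatibility(
                graph, apply_selection(graph, sel), alpha, delta, metric=metric
            )
            if report.compatible:
                obj = sum(int(gains[j]) for j in range(n) if (mask >> j) & 1)
                if obj > best_obj:
                    best_obj, best_removed = obj, removed
        return make_selection(
            graph, best_removed, "brute_force", alpha, delta, meta={"objective": best_obj}
        )

    raise ValueError(f"unknown feasibility mode {feasibility!r}")
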