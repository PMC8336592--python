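"""Heuristic selection for variation graphs containing indels.

With deletions in the graph, an alpha-long path can span more than alpha
backbone coordinates, so the fixed-width SNP windows no longer bound which
removals a path can see.  Instead, each locus gets a *window*: the leftmost
backbone coordinate from which its vertex is reachable using fewer than alpha
labeled edges (deletion edges are unlabeled and stretch windows leftward).
Dropping all variants at a locus costs any overlapping path at most a
*penalty* of ``delta_ins + delta_del`` edit operations, so keeping the summed
penalty of removed loci within every window at or below delta guarantees
edit-distance compatibility of the reduced graph.

Both the conservative greedy and the window-constrained ILP enforce exactly
those constraints; the ILP additionally optimizes the removal objective and is
therefore at least as good as the greedy on every instance.  Neither is
optimal in general — no polynomial-time optimal algorithm is known for the
indel problems.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import sparse
from scipy.optimize import Bounds, LinearConstraint, milp

from .graph_model import (
    DEL,
    SelectionResult,
    VariantLocus,
    VariationGraph,
    make_selection,
)

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class WindowTable:
    """Per-locus window starts: leftmost coordinate reaching the locus with
    fewer than alpha labeled edges."""

    alpha: int
    window_start: np.ndarray  # aligned with graph.loci

    def __len__(self) -> int:
        return len(self.window_start)


@dataclass(frozen=True)
class PenaltyVector:
    """Per-locus upper bounds on the edit cost of dropping the locus."""

    penalty: np.ndarray  # aligned with graph.loci

    def __len__(self) -> int:
        return len(self.penalty)


def locus_penalty(locus: VariantLocus) -> int:
    """Edit-distance penalty bound for dropping every variant at a locus."""
    return locus.penalty


def compute_penalties(graph: VariationGraph) -> PenaltyVector:
    return PenaltyVector(np.asarray([l.penalty for l in graph.loci], dtype=np.int64))


def compute_windows(graph: VariationGraph, alpha: int) -> WindowTable:
    """Window starts via the left-to-right recursion over deletion edges.

    ``f(v_i, x)`` is the leftmost vertex from which ``v_i`` is reachable with
    fewer than ``x`` labeled edges:

        f(v_i, x) = min( i, f(v_{i-1}, x-1), f(v_j, x) for each deletion j->i )

    SNPs and insertions never move a path leftward along the axis, so only
    deletion edges matter.  The vector ``f(v_i, 1..alpha)`` is advanced left to
    right; between deletion endpoints and loci the recursion has the closed
    form ``f(v_i, x) = max(0, i - x + 1)``, so only those event positions are
    visited explicitly (the vector shift across a variant-free, deletion-free
    stretch of length k is ``f`` shifted by k with fresh prefix values).
    """
    if alpha < 1:
        raise ValueError(f"alpha must be >= 1, got {alpha}")
    n = graph.n_loci
    ws = np.empty(n, dtype=np.int64)
    if n == 0:
        return WindowTable(alpha=alpha, window_start=ws)

    xs = np.arange(1, alpha + 1, dtype=np.int64)

    def closed(i: int) -> np.ndarray:
        return np.maximum(0, i - xs + 1)

    # deletion edges grouped by target vertex
    dels_by_target: dict[int, list[int]] = {}
    sources: set[int] = set()
    for locus in graph.loci:
        for v in locus.variants:
            if v.vtype == DEL:
                dels_by_target.setdefault(v.coordinate + v.span, []).append(v.coordinate)
                sources.add(v.coordinate)

    loci_pos = {int(c): idx for idx, c in enumerate(graph.variant_coordinates)}
    special = sorted(set(dels_by_target) | sources | set(loci_pos))

    saved: dict[int, np.ndarray] = {}
    f: np.ndarray | None = None
    cur = -1
    for i in special:
        if f is None:
            f = closed(i)
        else:
            k = i - cur
            if k >= alpha:
                f = closed(i)
            elif k > 0:
                shifted = np.empty(alpha, dtype=np.int64)
                shifted[k:] = f[: alpha - k]
                shifted[:k] = np.maximum(0, i - xs[:k] + 1)
                f = shifted
        for src in dels_by_target.get(i, ()):
            f = np.minimum(f, saved[src] if src in saved else closed(src))
        if i in sources:
            saved[i] = f.copy()
        if i in loci_pos:
            ws[loci_pos[i]] = int(f[alpha - 1])
        cur = i
    return WindowTable(alpha=alpha, window_start=ws)


def window_members(graph: VariationGraph, windows: WindowTable) -> list[range]:
    """For each locus i, the contiguous locus-index range covered by its
    window ``[window_start_i, p_i]``."""
    p = graph.variant_coordinates
    lo = np.searchsorted(p, windows.window_start, side="left")
    return [range(int(lo[i]), i + 1) for i in range(graph.n_loci)]


def window_removed_penalties(
    graph: VariationGraph,
    windows: WindowTable,
    penalties: PenaltyVector,
    removed: set[int] | frozenset[int],
) -> np.ndarray:
    """Summed penalty of removed loci inside each window — the quantity every
    constraint bounds by delta.  Used as an independent feasibility check."""
    rem = np.asarray(
        [c in removed for c in graph.variant_coordinates], dtype=np.int64
    )
    w = rem * penalties.penalty
    csum = np.concatenate(([0], np.cumsum(w)))
    p = graph.variant_coordinates
    lo = np.searchsorted(p, windows.window_start, side="left")
    return csum[np.arange(1, graph.n_loci + 1)] - csum[lo]


def greedy_indel(
    graph: VariationGraph,
    windows: WindowTable | None = None,
    penalties: PenaltyVector | None = None,
    alpha: int | None = None,
    delta: int | None = None,
) -> SelectionResult:
    """Conservative left-to-right greedy.

    Locus i is removed iff, for *every* window containing ``p_i`` (windows of
    later loci reach left), the accumulated penalty of already-removed loci in
    that window plus ``penalty_i`` stays within delta.  The output therefore
    satisfies the full window constraint system, which both guarantees
    edit-compatibility and makes it a feasible point of the ILP below.
    """
    windows, penalties, alpha, delta = _resolve(graph, windows, penalties, alpha, delta)
    n = graph.n_loci
    members = window_members(graph, windows)
    # inverted index: locus index -> windows whose member range contains it
    member_of: list[list[int]] = [[] for _ in range(n)]
    for k in range(n):
        for j in members[k]:
            member_of[j].append(k)

    acc = np.zeros(n, dtype=np.int64)  # removed penalty accumulated per window
    pen = penalties.penalty
    removed_idx = []
    for i in range(n):
        if all(acc[k] + pen[i] <= delta for k in member_of[i]):
            removed_idx.append(i)
            for k in member_of[i]:
                acc[k] += pen[i]

    p = graph.variant_coordinates
    removed = {int(p[i]) for i in removed_idx}
    return make_selection(graph, removed, "greedy_i", alpha, delta)


def ilp_indel(
    graph: VariationGraph,
    windows: WindowTable | None = None,
    penalties: PenaltyVector | None = None,
    alpha: int | None = None,
    delta: int | None = None,
    objective: str = "variants",
    time_limit: float = 60.0,
) -> SelectionResult:
    """Window-constrained ILP.

    Maximize ``sum C[i] X[i]`` subject to, per window i,
    ``sum penalty_j X[j] <= delta`` over member loci j, X binary.
    ``objective='variants'`` weighs loci by allele count (ILP_iv);
    ``objective='positions'`` weighs each locus 1 (ILP_ip).  On solver timeout
    the best incumbent is returned if feasible, otherwise the greedy solution;
    both cases are flagged in ``meta``.
    """
    if objective not in ("variants", "positions"):
        raise ValueError(f"objective must be 'variants' or 'positions', got {objective!r}")
    windows, penalties, alpha, delta = _resolve(graph, windows, penalties, alpha, delta)
    algorithm = "ilp_iv" if objective == "variants" else "ilp_ip"
    n = graph.n_loci
    if n == 0:
        return make_selection(graph, set(), algorithm, alpha, delta)

    if objective == "variants":
        gains = np.asarray([l.n_variants for l in graph.loci], dtype=float)
    else:
        gains = np.ones(n, dtype=float)

    pen = penalties.penalty.astype(float)
    rows, cols, data = [], [], []
    for i, rng in enumerate(window_members(graph, windows)):
        for j in rng:
            rows.append(i)
            cols.append(j)
            data.append(pen[j])
    A = sparse.csr_matrix((data, (rows, cols)), shape=(n, n))

    res = milp(
        c=-gains,
        constraints=LinearConstraint(A, -np.inf, np.full(n, float(delta))),
        integrality=np.ones(n),
        bounds=Bounds(0, 1),
        options={"time_limit": time_limit},
    )

    meta: dict = {"objective_kind": objective, "timed_out": res.status == 1}
    x = None
    if res.x is not None:
        cand = np.round(res.x).astype(np.int64)
        if np.all(A @ cand <= delta + 1e-9):
            x = cand
    if x is None:
        logger.warning("ILP returned no feasible incumbent; falling back to greedy")
        fallback = greedy_indel(graph, windows, penalties, alpha, delta)
        meta["fallback_greedy"] = True
        return SelectionResult(
            removed_coordinates=fallback.removed_coordinates,
            retained_coordinates=fallback.retained_coordinates,
            retained_variant_count=fallback.retained_variant_count,
            retained_locus_count=fallback.retained_locus_count,
            algorithm=algorithm,
            alpha=alpha,
            delta=delta,
            meta=meta,
        )

    p = graph.variant_coordinates
    removed = {int(p[i]) for i in range(n) if x[i] == 1}
    meta["objective"] = float(gains @ x)
    return make_selection(graph, removed, algorithm, alpha, delta, meta=meta)


def _resolve(graph, windows, penalties, alpha, delta):
    if alpha is None or delta is None:
        raise ValueError("alpha and delta are required")
    if alpha < 1:
        raise ValueError(f"alpha must be >= 1, got {alpha}")
    if delta < 0:
        raise ValueError(f"delta must be >= 0, got {delta}")
    if windows is None:
        windows = compute_windows(graph, alpha)
    elif windows.alpha != alpha:
        raise ValueError(f"window table was built for alpha={windows.alpha}, not {alpha}")
    if penalties is None:
        penalties = compute_penalties(graph)
    if len(windows) != graph.n_loci or len(penalties) != graph.n_loci:
        raise ValueError("window/penalty tables inconsistent with graph")
    return windows, penalties, alpha, delta
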