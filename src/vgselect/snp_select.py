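"""Optimal selection for SNP-only variation graphs.

Two objectives, both solved exactly:

* :func:`greedy_snp` — minimize the number of variant-containing loci retained
  (equivalently, maximize the loci removed) with a left-to-right sweep line.
  It is optimal: whenever the greedy and an optimal solution first differ, the
  optimal retained locus can be exchanged for the greedy one without breaking
  feasibility further right.
* :func:`lp_snp` — minimize the total number of variants retained by an LP
  relaxation of the natural ILP.  The constraint matrix is an interval matrix
  (each row's 1s are consecutive), hence totally unimodular, so the LP optimum
  is integral.

Feasibility means: no window ``(p_i - alpha, p_i]`` anchored at a variant
coordinate contains more than ``delta`` removed loci.  Any length-``alpha``
segment containing more than ``delta`` removed loci would break
Hamming-compatibility (the recombinant path taking every dropped alternative
allele in the segment has no match within ``delta``), and it suffices to check
segments ending at variant coordinates.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import sparse
from scipy.optimize import Bounds, LinearConstraint, linprog, milp

from .graph_model import SelectionResult, VariationGraph, make_selection

logger = logging.getLogger(__name__)

_INTEGRALITY_TOL = 1e-6


class NotSnpOnlyError(ValueError):
    """Raised when a SNP-only algorithm meets an indel locus."""


def _require_snp_only(graph: VariationGraph) -> None:
    for locus in graph.loci:
        if not locus.snp_only:
            raise NotSnpOnlyError(
                f"locus at {locus.coordinate} has indel variants; "
                "use the indel-aware algorithms (greedy_i / ilp_iv / ilp_ip)"
            )


def _check_params(alpha: int, delta: int) -> None:
    if alpha < 1:
        raise ValueError(f"alpha must be >= 1, got {alpha}")
    if delta < 0:
        raise ValueError(f"delta must be >= 0, got {delta}")


@dataclass(frozen=True)
class IntervalConstraintSystem:
    """Window constraints of the SNP selection ILP.

    Row ``i`` covers the contiguous locus-index range ``[lo[i], i]``: the loci
    whose coordinate lies in the segment ``(p_i - alpha, p_i]``.  ``gains[i]``
    is the number of variants freed by removing locus ``i``.
    """

    n: int
    lo: np.ndarray
    gains: np.ndarray
    alpha: int
    delta: int

    def row_indices(self, i: int) -> range:
        return range(int(self.lo[i]), i + 1)


def build_interval_constraints(
    graph: VariationGraph, alpha: int, delta: int
) -> IntervalConstraintSystem:
    """Two-pointer scan computing, per locus i, the first locus index inside
    the window ``(p_i - alpha, p_i]``."""
    _check_params(alpha, delta)
    p = graph.variant_coordinates
    n = graph.n_loci
    lo = np.empty(n, dtype=np.int64)
    j = 0
    for i in range(n):
        while p[j] <= p[i] - alpha:
            j += 1
        lo[i] = j
    gains = np.asarray([l.n_variants for l in graph.loci], dtype=np.int64)
    return IntervalConstraintSystem(n=n, lo=lo, gains=gains, alpha=alpha, delta=delta)


def window_removed_counts(
    graph: VariationGraph, removed: set[int] | frozenset[int], alpha: int
) -> np.ndarray:
    """Number of removed loci inside each window ``(p_i - alpha, p_i]``.

    Independent feasibility check used by tests and the verifier: a selection
    is Hamming-safe iff every entry is <= delta.
    """
    p = graph.variant_coordinates
    rem = np.asarray([c in removed for c in p], dtype=np.int64)
    csum = np.concatenate(([0], np.cumsum(rem)))
    lo = np.searchsorted(p, p - alpha, side="right")
    return csum[np.arange(1, len(p) + 1)] - csum[lo]


def greedy_snp(graph: VariationGraph, alpha: int, delta: int) -> SelectionResult:
    """Sweep-line greedy maximizing the number of removed loci.

    Each locus i contributes a *start* event at ``max(0, p_i - alpha + 1)``
    and an *end* event at ``p_i``; start sorts before end at equal positions.
    A running count tracks removed loci active in the current segment: a locus
    is removed at its start event iff the count is below delta.
    """
    _require_snp_only(graph)
    _check_params(alpha, delta)
    p = graph.variant_coordinates
    n = graph.n_loci

    # (position, etype, locus index); etype 0 = start sorts before 1 = end
    events = sorted(
        [(max(0, int(p[i]) - alpha + 1), 0, i) for i in range(n)]
        + [(int(p[i]), 1, i) for i in range(n)]
    )
    removed_mask = np.zeros(n, dtype=bool)
    count = 0
    for _, etype, i in events:
        if etype == 0:
            if count < delta:
                removed_mask[i] = True
                count += 1
        elif removed_mask[i]:
            count -= 1

    removed = {int(p[i]) for i in range(n) if removed_mask[i]}
    return make_selection(graph, removed, "greedy_s", alpha, delta)


def lp_snp(
    graph: VariationGraph, alpha: int, delta: int
) -> SelectionResult:
    """LP relaxation maximizing the total number of removed variants.

    Maximize ``gains . X`` subject to, for each window, ``sum X[j] <= delta``
    over the loci it covers, ``0 <= X <= 1``.  The interval structure makes
    the optimal vertex integral; the solution is rounded within 1e-6 and
    re-checked, with an exact ILP fallback should the solver ever return a
    fractional point.
    """
    _require_snp_only(graph)
    _check_params(alpha, delta)
    n = graph.n_loci
    if n == 0:
        return make_selection(graph, set(), "lp_s", alpha, delta)

    sys_ = build_interval_constraints(graph, alpha, delta)
    A = _window_matrix(sys_)
    b = np.full(n, float(delta))
    res = linprog(
        c=-sys_.gains.astype(float),
        A_ub=A,
        b_ub=b,
        bounds=(0.0, 1.0),
        method="highs",
    )
    if not res.success:  # pragma: no cover - X=0 is always feasible
        raise RuntimeError(f"LP solver failed on a feasible instance: {res.message}")

    x = res.x
    frac = np.abs(x - np.round(x))
    meta: dict = {"objective": float(res.fun * -1), "fallback_ilp": False}
    if frac.max(initial=0.0) > _INTEGRALITY_TOL:
        logger.warning(
            "LP solution fractional beyond tolerance (max %.3g); solving exact ILP",
            frac.max(),
        )
        x = _solve_binary(sys_.gains, A, b)
        meta["fallback_ilp"] = True
    x_int = np.round(x).astype(np.int64)
    if np.any(A @ x_int > delta + 1e-9):
        logger.warning("rounded LP point infeasible; solving exact ILP")
        x_int = np.round(_solve_binary(sys_.gains, A, b)).astype(np.int64)
        meta["fallback_ilp"] = True

    p = graph.variant_coordinates
    removed = {int(p[i]) for i in range(n) if x_int[i] == 1}
    meta["objective"] = int(sys_.gains @ x_int)
    return make_selection(graph, removed, "lp_s", alpha, delta, meta=meta)


def _window_matrix(sys_: IntervalConstraintSystem) -> sparse.csr_matrix:
    rows, cols = [], []
    for i in range(sys_.n):
        for j in sys_.row_indices(i):
            rows.append(i)
            cols.append(j)
    data = np.ones(len(rows))
    return sparse.csr_matrix((data, (rows, cols)), shape=(sys_.n, sys_.n))


def _solve_binary(gains: np.ndarray, A: sparse.csr_matrix, b: np.ndarray) -> np.ndarray:
    res = milp(
        c=-gains.astype(float),
        constraints=LinearConstraint(A, -np.inf, b),
        integrality=np.ones(len(gains)),
        bounds=Bounds(0, 1),
    )
    if res.x is None:  # pragma: no cover
        raise RuntimeError(f"ILP fallback failed: {res.message}")
    return res.x
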