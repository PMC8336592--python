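"""In-memory model of an edge-labeled variation graph.

A variation graph is a linear reference backbone — a chain of ``|R|+1``
coordinate vertices ``v_0 .. v_|R|`` whose edges spell the reference — augmented
with alternative alleles:

* a SNP is an extra labeled edge between two adjacent coordinate vertices,
* a deletion is an epsilon-labeled edge skipping ``span`` backbone bases,
* an insertion is a labeled chain that leaves and re-enters one vertex.

Selection algorithms operate on *loci*: the coordinates carrying at least one
alternative allele.  All variants at a coordinate are retained or removed as a
unit (an optimal reduction never splits a locus: once one allele at a
coordinate is dropped, paths through that coordinate already pay an error
there, so dropping the rest is free).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

SNP = "SNP"
INS = "INS"
DEL = "DEL"

_VTYPES = (SNP, INS, DEL)


class VariantInputError(ValueError):
    """Raised for malformed or out-of-bounds variant records."""


@dataclass(frozen=True)
class ReferenceAxis:
    """The linear reference backbone providing the coordinate axis."""

    sequence: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "sequence", self.sequence.upper())

    @property
    def length(self) -> int:
        return len(self.sequence)

    def base(self, coordinate: int) -> str:
        return self.sequence[coordinate]


@dataclass(frozen=True, order=True)
class VariantRecord:
    """One alternative allele at one 0-based reference coordinate.

    ``coordinate`` is the backbone vertex the first deviating edge leaves from:
    a SNP substitutes the base at ``coordinate``; a DEL skips backbone bases
    ``coordinate .. coordinate+span-1``; an INS inserts ``allele`` between the
    bases at ``coordinate-1`` and ``coordinate``.
    """

    coordinate: int
    vtype: str
    allele: str = ""
    span: int = 0

    def __post_init__(self) -> None:
        if self.vtype not in _VTYPES:
            raise VariantInputError(f"unknown variant type {self.vtype!r}")
        if self.vtype == SNP and (len(self.allele) != 1 or self.span != 1):
            raise VariantInputError(f"malformed SNP record {self}")
        if self.vtype == INS and (len(self.allele) < 1 or self.span != 0):
            raise VariantInputError(f"malformed INS record {self}")
        if self.vtype == DEL and (self.allele != "" or self.span < 1):
            raise VariantInputError(f"malformed DEL record {self}")

    @classmethod
    def snp(cls, coordinate: int, allele: str) -> "VariantRecord":
        return cls(coordinate, SNP, allele, 1)

    @classmethod
    def ins(cls, coordinate: int, allele: str) -> "VariantRecord":
        return cls(coordinate, INS, allele, 0)

    @classmethod
    def dele(cls, coordinate: int, span: int) -> "VariantRecord":
        return cls(coordinate, DEL, "", span)


@dataclass(frozen=True)
class VariantLocus:
    """All alternative alleles sharing one coordinate.

    ``n_variants`` equals the out-degree of the coordinate vertex minus one.
    ``delta_ins`` / ``delta_del`` are the longest insertion / deletion here
    (0 when absent); they drive the edit-distance penalty bound used by the
    indel-aware algorithms.
    """

    coordinate: int
    variants: tuple[VariantRecord, ...]

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    @property
    def delta_ins(self) -> int:
        return max((len(v.allele) for v in self.variants if v.vtype == INS), default=0)

    @property
    def delta_del(self) -> int:
        return max((v.span for v in self.variants if v.vtype == DEL), default=0)

    @property
    def has_snp(self) -> bool:
        return any(v.vtype == SNP for v in self.variants)

    @property
    def has_ins(self) -> bool:
        return any(v.vtype == INS for v in self.variants)

    @property
    def has_del(self) -> bool:
        return any(v.vtype == DEL for v in self.variants)

    @property
    def snp_only(self) -> bool:
        return all(v.vtype == SNP for v in self.variants)

    @property
    def penalty(self) -> int:
        """Upper bound on the edit distance any overlapping path incurs if the
        whole locus is dropped.

        With both indel types present the bound is ``delta_ins + delta_del``.
        With insertions but no deletion, a path may traverse the insertion and
        then a SNP edge, so a coexisting SNP adds 1.  A lone SNP costs exactly
        one substitution.
        """
        if self.has_del:
            pen = self.delta_ins + self.delta_del
        elif self.has_ins:
            pen = self.delta_ins + (1 if self.has_snp else 0)
        else:
            pen = 1
        return max(pen, 1)


@dataclass(frozen=True)
class VariationGraph:
    """Reference backbone plus variant loci, ordered by coordinate."""

    axis: ReferenceAxis
    loci: tuple[VariantLocus, ...]
    variant_coordinates: np.ndarray = field(repr=False, compare=False, default=None)

    def __post_init__(self) -> None:
        coords = np.asarray([l.coordinate for l in self.loci], dtype=np.int64)
        object.__setattr__(self, "variant_coordinates", coords)

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    @property
    def total_variants(self) -> int:
        return sum(l.n_variants for l in self.loci)

    @property
    def snp_only(self) -> bool:
        return all(l.snp_only for l in self.loci)

    def locus_at(self, coordinate: int) -> VariantLocus:
        idx = int(np.searchsorted(self.variant_coordinates, coordinate))
        if idx >= self.n_loci or self.loci[idx].coordinate != coordinate:
            raise KeyError(f"no variant locus at coordinate {coordinate}")
        return self.loci[idx]


@dataclass(frozen=True)
class SelectionResult:
    """Outcome of a selection algorithm: which loci were removed/retained."""

    removed_coordinates: frozenset[int]
    retained_coordinates: frozenset[int]
    retained_variant_count: int
    retained_locus_count: int
    algorithm: str
    alpha: int
    delta: int
    meta: dict = field(default_factory=dict, compare=False)

    @property
    def removed_locus_count(self) -> int:
        return len(self.removed_coordinates)


def make_selection(
    graph: VariationGraph,
    removed: Iterable[int],
    algorithm: str,
    alpha: int,
    delta: int,
    meta: dict | None = None,
) -> SelectionResult:
    """Package a removed-coordinate set as a :class:`SelectionResult`."""
    removed = frozenset(int(c) for c in removed)
    all_coords = frozenset(int(c) for c in graph.variant_coordinates)
    if not removed <= all_coords:
        raise VariantInputError(
            f"removed coordinates {sorted(removed - all_coords)} not in graph"
        )
    retained = all_coords - removed
    rv = sum(l.n_variants for l in graph.loci if l.coordinate in retained)
    return SelectionResult(
        removed_coordinates=removed,
        retained_coordinates=retained,
        retained_variant_count=rv,
        retained_locus_count=len(retained),
        algorithm=algorithm,
        alpha=alpha,
        delta=delta,
        meta=meta or {},
    )


def build_variation_graph(
    reference: ReferenceAxis,
    variants: Sequence[VariantRecord],
    lenient: bool = False,
) -> VariationGraph:
    """Group variants by coordinate into loci and assemble the graph.

    Variants need not be sorted; identical alleles at one coordinate are
    deduplicated.  A SNP whose allele equals the reference base is rejected
    (or skipped under ``lenient=True``), as is any out-of-bounds record.
    """
    L = reference.length
    by_coord: dict[int, list[VariantRecord]] = {}
    for rec in variants:
        if rec.coordinate < 0 or rec.coordinate > L:
            raise VariantInputError(f"variant out of reference bounds: {rec}")
        if rec.vtype == SNP:
            if rec.coordinate >= L:
                raise VariantInputError(f"SNP coordinate beyond last base: {rec}")
            if rec.allele == reference.base(rec.coordinate):
                if lenient:
                    continue
                raise VariantInputError(
                    f"SNP allele equals reference base {reference.base(rec.coordinate)!r}: {rec}"
                )
        if rec.vtype == DEL and rec.coordinate + rec.span > L:
            raise VariantInputError(f"deletion extends past reference end: {rec}")
        by_coord.setdefault(rec.coordinate, []).append(rec)

    loci = tuple(
        VariantLocus(coord, tuple(sorted(set(recs))))
        for coord, recs in sorted(by_coord.items())
    )
    return VariationGraph(axis=reference, loci=loci)


def apply_selection(graph: VariationGraph, result: SelectionResult) -> VariationGraph:
    """Materialize the reduced graph: drop every removed locus.

    The backbone is unchanged; at a removed locus the outgoing label falls
    back to the reference base.
    """
    coords = set(int(c) for c in graph.variant_coordinates)
    stray = result.removed_coordinates - coords
    if stray:
        raise VariantInputError(f"removed coordinates not in graph: {sorted(stray)}")
    kept = tuple(l for l in graph.loci if l.coordinate not in result.removed_coordinates)
    return VariationGraph(axis=graph.axis, loci=kept)
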