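"""Shared builders for random test instances."""

from __future__ import annotations

import numpy as np
import pytest

from vgselect.graph_model import (
    ReferenceAxis,
    VariantRecord,
    VariationGraph,
    build_variation_graph,
)

BASES = "ACGT"


def random_reference(rng: np.random.Generator, length: int) -> ReferenceAxis:
    return ReferenceAxis("".join(rng.choice(list(BASES), size=length)))


def snp_graph(
    axis: ReferenceAxis,
    coordinates,
    n_alleles=None,
    rng: np.random.Generator | None = None,
) -> VariationGraph:
    """SNP-only graph with given locus coordinates; ``n_alleles`` maps a
    coordinate (or all) to its allele count (1..3)."""
    rng = rng or np.random.default_rng(0)
    recs = []
    for i, c in enumerate(coordinates):
        k = 1
        if n_alleles is not None:
            k = n_alleles[i] if not isinstance(n_alleles, int) else n_alleles
        alts = [b for b in BASES if b != axis.base(c)]
        for a in alts[:k]:
            recs.append(VariantRecord.snp(int(c), a))
    return build_variation_graph(axis, recs)


def random_snp_instance(
    rng: np.random.Generator, length: int, n_loci: int, max_alleles: int = 1
):
    axis = random_reference(rng, length)
    coords = np.sort(rng.choice(length, size=n_loci, replace=False))
    alleles = rng.integers(1, max_alleles + 1, size=n_loci).tolist()
    return snp_graph(axis, coords.tolist(), n_alleles=alleles, rng=rng)


def random_mixed_instance(
    rng: np.random.Generator,
    length: int = 40,
    n_loci: int = 5,
    max_ins: int = 3,
    max_del: int = 4,
) -> VariationGraph:
    """Small graph mixing SNPs, short insertions and deletions."""
    axis = random_reference(rng, length)
    coords = np.sort(rng.choice(np.arange(1, length - max_del), size=n_loci, replace=False))
    recs = []
    for c in coords:
        c = int(c)
        kind = rng.choice(["SNP", "INS", "DEL"])
        if kind == "SNP":
            alts = [b for b in BASES if b != axis.base(c)]
            recs.append(VariantRecord.snp(c, str(rng.choice(alts))))
        elif kind == "INS":
            ln = int(rng.integers(1, max_ins + 1))
            recs.append(VariantRecord.ins(c, "".join(rng.choice(list(BASES), size=ln))))
        else:
            ln = int(rng.integers(1, max_del + 1))
            recs.append(VariantRecord.dele(c, ln))
    return build_variation_graph(axis, recs)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240901)
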