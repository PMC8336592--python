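"""Seeded generators for references and variant catalogues.

Three regimes mirror the composition of real human call sets so every
algorithm is testable without downloads:

* dense biallelic SNPs — mean inter-SNP gap of 39 bp, the chromosome-1
  density of the 1000 Genomes Phase 3 call set, with a small multi-allelic
  fraction (~0.3% of loci carry a second allele there);
* SNPs plus short indels (1–50 bp, geometric lengths) at roughly one short
  indel per kilobase;
* indel SVs only — insertions/deletions of at least 50 bp with log-uniform
  lengths, placed without mutual overlap, at a handful per 100 kbp.

Generation is deterministic given the seed.  Linkage/phasing is not
simulated: the selection problems treat all recombinant paths as valid, so
haplotype structure is irrelevant to them.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .graph_model import ReferenceAxis, VariantRecord

_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class SimSpec:
    """Parameters of one simulated reference + catalogue."""

    ref_length: int = 100_000
    snp_rate: float = 1.0 / 39.0  # per-base probability of a SNP locus
    p_multiallelic: float = 0.003  # chance of a 2nd (and, squared, a 3rd) alt
    indel_rate: float = 0.0  # per-base probability of a short indel
    indel_len_p: float = 0.35  # geometric length parameter, truncated to [1,50]
    sv_count: int = 0
    sv_min_len: int = 50
    sv_max_len: int = 5_000  # log-uniform lengths in [sv_min_len, sv_max_len]
    sv_allow_overlap: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("snp_rate", "p_multiallelic", "indel_rate", "indel_len_p"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.ref_length < 1 or self.sv_count < 0:
            raise ValueError("ref_length must be >= 1 and sv_count >= 0")
        if not 50 <= self.sv_min_len <= self.sv_max_len:
            raise ValueError("need 50 <= sv_min_len <= sv_max_len")

    # regime presets
    @classmethod
    def snps(cls, ref_length: int = 100_000, seed: int = 0, **kw) -> "SimSpec":
        return cls(ref_length=ref_length, seed=seed, **kw)

    @classmethod
    def snps_indels(cls, ref_length: int = 100_000, seed: int = 0, **kw) -> "SimSpec":
        kw.setdefault("indel_rate", 1.0 / 1000.0)
        return cls(ref_length=ref_length, seed=seed, **kw)

    @classmethod
    def svs(cls, ref_length: int = 1_000_000, sv_count: int = 26, seed: int = 0, **kw) -> "SimSpec":
        return cls(
            ref_length=ref_length, snp_rate=0.0, indel_rate=0.0,
            sv_count=sv_count, seed=seed, **kw,
        )


def simulate(spec: SimSpec) -> tuple[ReferenceAxis, list[VariantRecord]]:
    """Draw a random reference and variant catalogue per ``spec``."""
    rng = np.random.default_rng(spec.seed)
    L = spec.ref_length
    seq = rng.choice(_BASES, size=L)
    axis = ReferenceAxis("".join(seq))

    variants: list[VariantRecord] = []

    if spec.snp_rate > 0:
        snp_pos = np.flatnonzero(rng.random(L) < spec.snp_rate)
        for pos in snp_pos:
            ref_base = axis.base(int(pos))
            alts = [b for b in "ACGT" if b != ref_base]
            n_alt = 1
            if rng.random() < spec.p_multiallelic:
                n_alt = 3 if rng.random() < spec.p_multiallelic else 2
            chosen = rng.choice(alts, size=n_alt, replace=False)
            variants.extend(VariantRecord.snp(int(pos), a) for a in chosen)

    if spec.indel_rate > 0:
        # short indels, coordinates in [1, L-1] so VCF anchoring is clean
        idl_pos = np.flatnonzero(rng.random(L - 1) < spec.indel_rate) + 1
        for pos in idl_pos:
            length = min(50, int(rng.geometric(spec.indel_len_p)))
            if rng.random() < 0.5 and int(pos) + length <= L:
                variants.append(VariantRecord.dele(int(pos), length))
            else:
                allele = "".join(rng.choice(_BASES, size=length))
                variants.append(VariantRecord.ins(int(pos), allele))

    if spec.sv_count > 0:
        variants.extend(_place_svs(spec, rng, L))

    variants.sort()
    return axis, variants


def _place_svs(spec: SimSpec, rng: np.random.Generator, L: int) -> list[VariantRecord]:
    log_lo, log_hi = np.log(spec.sv_min_len), np.log(spec.sv_max_len)
    out: list[VariantRecord] = []
    taken: list[tuple[int, int]] = []  # occupied [start, end) backbone intervals
    attempts = 0
    max_attempts = 200 * spec.sv_count + 1000
    while len(out) < spec.sv_count:
        attempts += 1
        if attempts > max_attempts:
            raise ValueError(
                f"could not place {spec.sv_count} non-overlapping SVs of "
                f"{spec.sv_min_len}-{spec.sv_max_len} bp on a {L} bp reference"
            )
        length = int(np.exp(rng.uniform(log_lo, log_hi)))
        length = max(spec.sv_min_len, min(length, spec.sv_max_len))
        is_del = rng.random() < 0.5
        span = length if is_del else 1
        pos = int(rng.integers(1, max(2, L - span)))
        if pos + span > L:
            continue
        if not spec.sv_allow_overlap:
            if any(pos < e and pos + span > s for s, e in taken):
                continue
            taken.append((pos, pos + span))
        if is_del:
            out.append(VariantRecord.dele(pos, length))
        else:
            out.append(VariantRecord.ins(pos, "".join(rng.choice(_BASES, size=length))))
    return out


def count_by_type(variants: list[VariantRecord]) -> dict[str, int]:
    """Ground-truth per-type tallies of a generated catalogue."""
    counts = {"SNP": 0, "INS": 0, "DEL": 0}
    for v in variants:
        counts[v.vtype] += 1
    return counts
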