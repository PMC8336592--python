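"""FASTA/VCF input and output at the domain-type boundary.

VCF is 1-based and anchor-based; the in-memory model is 0-based with
de-anchored indels.  All conversion happens here and only here:

* ``POS p, REF A, ALT G``      -> SNP at coordinate ``p-1``
* ``POS p, REF ACCT, ALT A``   -> DEL at coordinate ``p`` (span 3)
* ``POS p, REF A, ALT ACCT``   -> INS at coordinate ``p`` (allele ``CCT``)

Each ALT allele of a multi-allelic record becomes its own record.  Symbolic
``<DEL>``/``<INS>`` alleles are accepted when END/SVLEN information is present
(long-read SV call sets are often not sequence-resolved); a symbolic insertion
gets a placeholder allele of Ns of the stated length, which selection treats
purely by its length.  Complex/mixed ALTs and non-indel SV types are skipped
and counted, never silently dropped.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import pysam
from pyfaidx import Fasta

from .graph_model import (
    DEL,
    INS,
    SNP,
    ReferenceAxis,
    SelectionResult,
    VariantInputError,
    VariantRecord,
    VariationGraph,
)

logger = logging.getLogger(__name__)


@dataclass
class VcfParseStats:
    n_records: int = 0
    n_alleles_kept: int = 0
    n_skipped_non_indel_sv: int = 0
    n_skipped_other: int = 0


def read_reference(fasta_path, contig: str | None = None) -> tuple[ReferenceAxis, str]:
    """Load one contig (the first by default) as the reference axis."""
    fa = Fasta(str(fasta_path), as_raw=True, sequence_always_upper=True)
    names = list(fa.keys())
    if not names:
        raise VariantInputError(f"no sequences in {fasta_path}")
    if contig is None:
        contig = names[0]
    elif contig not in names:
        raise VariantInputError(f"contig {contig!r} not in {fasta_path} (has {names})")
    return ReferenceAxis(str(fa[contig][:])), contig


def write_fasta(axis: ReferenceAxis, path, name: str = "ref", width: int = 70) -> None:
    seq = axis.sequence
    with open(path, "w") as fh:
        fh.write(f">{name}\n")
        for i in range(0, len(seq), width):
            fh.write(seq[i : i + width] + "\n")


def _classify_alt(pos1: int, ref: str, alt: str, axis: ReferenceAxis):
    """Classify one (POS, REF, ALT) as a domain record; None if complex.

    ``pos1`` is 1-based.  Handles left-anchored indels (the normal case) and
    right-anchored ones (indels at the very start of a contig).
    """
    ref = ref.upper()
    alt = alt.upper()
    if len(ref) == 1 and len(alt) == 1:
        if ref == alt:
            return None
        return VariantRecord.snp(pos1 - 1, alt)
    if len(alt) == 1 < len(ref):
        if ref[0] == alt:  # left anchor
            return VariantRecord.dele(pos1, len(ref) - 1)
        if ref[-1] == alt:  # right anchor (contig start)
            return VariantRecord.dele(pos1 - 1, len(ref) - 1)
        return None
    if len(ref) == 1 < len(alt):
        if alt[0] == ref:
            return VariantRecord.ins(pos1, alt[1:])
        if alt[-1] == ref:
            return VariantRecord.ins(pos1 - 1, alt[:-1])
        return None
    return None


def _symbolic_alt(rec, alt: str):
    """<DEL>/<INS> via END / SVLEN INFO fields; None when undecodable."""
    sv = alt.strip("<>").upper()
    svlen = rec.info.get("SVLEN", None)
    if isinstance(svlen, (tuple, list)):
        svlen = svlen[0] if svlen else None
    if sv == "DEL":
        span = None
        if rec.stop is not None and rec.stop > rec.pos:
            span = rec.stop - rec.pos
        elif svlen is not None:
            span = abs(int(svlen))
        if span and span >= 1:
            return VariantRecord.dele(rec.pos, span)  # rec.pos is 1-based anchor
        return None
    if sv == "INS":
        if svlen is not None and int(svlen) >= 1:
            return VariantRecord.ins(rec.pos, "N" * int(svlen))
        return None
    return None


def read_variants(
    vcf_path,
    reference: ReferenceAxis,
    contig: str | None = None,
    min_sv_len: int | None = None,
) -> tuple[list[VariantRecord], VcfParseStats]:
    """Parse a VCF into domain records against ``reference``.

    ``min_sv_len`` switches to SV mode: only indels of at least that length
    are kept, everything else is counted in ``n_skipped_non_indel_sv``.
    REF fields are checked against the reference sequence; a mismatch is an
    error naming the offending record.  Unsorted input is tolerated.
    """
    stats = VcfParseStats()
    out: list[VariantRecord] = []
    L = reference.length
    with pysam.VariantFile(str(vcf_path)) as vf:
        for rec in vf:
            stats.n_records += 1
            if contig is not None and rec.chrom != contig:
                stats.n_skipped_other += len(rec.alts or ())
                continue
            for alt in rec.alts or ():
                if alt.startswith("<"):
                    parsed = _symbolic_alt(rec, alt)
                else:
                    ref0 = rec.pos - 1
                    if ref0 + len(rec.ref) > L or reference.sequence[
                        ref0 : ref0 + len(rec.ref)
                    ] != rec.ref.upper():
                        raise VariantInputError(
                            f"REF mismatch at {rec.chrom}:{rec.pos} "
                            f"(VCF REF {rec.ref!r} vs reference "
                            f"{reference.sequence[ref0:ref0 + len(rec.ref)]!r})"
                        )
                    parsed = _classify_alt(rec.pos, rec.ref, alt, reference)
                if parsed is None:
                    stats.n_skipped_other += 1
                    continue
                if parsed.vtype == DEL and parsed.coordinate + parsed.span > L:
                    raise VariantInputError(
                        f"deletion at {rec.chrom}:{rec.pos} extends past reference end"
                    )
                if min_sv_len is not None:
                    length = parsed.span if parsed.vtype == DEL else len(parsed.allele)
                    if parsed.vtype == SNP or length < min_sv_len:
                        stats.n_skipped_non_indel_sv += 1
                        continue
                out.append(parsed)
                stats.n_alleles_kept += 1
    out.sort()
    return out, stats


def _locus_vcf_rows(locus, axis: ReferenceAxis):
    """Reconstruct anchored (POS, REF, ALT) rows for one locus."""
    seq = axis.sequence
    rows = []
    for v in locus.variants:
        c = v.coordinate
        if v.vtype == SNP:
            rows.append((c + 1, seq[c], v.allele))
        elif v.vtype == DEL:
            if c >= 1:
                rows.append((c, seq[c - 1 : c + v.span], seq[c - 1]))
            else:  # right-anchored at contig start
                rows.append((1, seq[: v.span + 1], seq[v.span]))
        elif v.vtype == INS:
            if c >= 1:
                rows.append((c, seq[c - 1], seq[c - 1] + v.allele))
            else:
                rows.append((1, seq[0], v.allele + seq[0]))
    return rows


def write_vcf(
    graph: VariationGraph,
    path,
    contig: str = "ref",
    coordinates: set[int] | frozenset[int] | None = None,
) -> None:
    """Write the loci of ``graph`` (optionally restricted to ``coordinates``)
    as a sequence-resolved VCF."""
    header = pysam.VariantHeader()
    header.contigs.add(contig, length=graph.axis.length)
    with pysam.VariantFile(str(path), "w", header=header) as vf:
        for locus in graph.loci:
            if coordinates is not None and locus.coordinate not in coordinates:
                continue
            for pos1, ref, alt in _locus_vcf_rows(locus, graph.axis):
                rec = vf.new_record(
                    contig=contig, start=pos1 - 1, alleles=(ref, alt)
                )
                vf.write(rec)


def write_selection(
    result: SelectionResult,
    graph: VariationGraph,
    vcf_out,
    report_out,
    contig: str = "ref",
) -> None:
    """Write the retained subset as VCF plus a per-locus TSV report."""
    coords = set(int(c) for c in graph.variant_coordinates)
    if not result.removed_coordinates <= coords:
        raise VariantInputError("selection result inconsistent with graph")
    try:
        if vcf_out is not None:
            write_vcf(graph, vcf_out, contig=contig, coordinates=result.retained_coordinates)
    except OSError as exc:
        raise OSError(f"failed writing VCF to {vcf_out}: {exc}") from exc

    total_variants = graph.total_variants
    try:
        with open(report_out, "w") as fh:
            fh.write(f"# algorithm={result.algorithm}\talpha={result.alpha}\tdelta={result.delta}\n")
            fh.write(
                f"# loci_total={graph.n_loci}\tloci_retained={result.retained_locus_count}\t"
                f"variants_total={total_variants}\tvariants_retained={result.retained_variant_count}\n"
            )
            fh.write("coordinate\tn_variants\tpenalty\tdecision\n")
            for locus in graph.loci:
                decision = (
                    "drop" if locus.coordinate in result.removed_coordinates else "keep"
                )
                fh.write(
                    f"{locus.coordinate}\t{locus.n_variants}\t{locus.penalty}\t{decision}\n"
                )
    except OSError as exc:
        raise OSError(f"failed writing report to {report_out}: {exc}") from exc
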