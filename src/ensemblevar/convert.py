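"""Input-VCF normalization and population-level filtering.

Graph genotypers need sequence-explicit alleles without special
characters, so ``reformat_vcf`` resolves symbolic ALTs (<DEL>, <INV>,
<DUP>) against the reference, upper-cases soft-masked bases, drops
anything whose alleles fall outside {A,C,G,T,N}, and collapses
byte-identical duplicates. ``filter_population_vcf`` optionally screens
a multi-sample input by minor allele frequency (MAF) and missing rate;
by default no filtering is applied.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .core import GenotypeCall, SVType, VariantRecord

__all__ = [
    "FilterConfig",
    "Rejection",
    "FilterResult",
    "reformat_vcf",
    "compute_maf",
    "compute_missing_rate",
    "filter_population_vcf",
    "write_rejection_log",
]

_VALID_ALLELE = re.compile(r"^[ACGTN]+$")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def _revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class FilterConfig:
    """MAF / missing-rate filter settings. Disabled by default."""

    min_maf: float = 0.0
    max_missing_rate: float = 1.0
    enabled: bool = False

    def __post_init__(self) -> None:
        if not 0.0 <= self.min_maf <= 0.5:
            raise ValueError("min_maf must lie in [0, 0.5]")
        if not 0.0 <= self.max_missing_rate <= 1.0:
            raise ValueError("max_missing_rate must lie in [0, 1]")


@dataclass(frozen=True)
class Rejection:
    chrom: str
    pos: int
    reason: str


def _reference_slice(reference: Mapping[str, object], chrom: str, start: int, end: int) -> str:
    """1-based inclusive substring of a reference sequence.

    Accepts plain strings or pyfaidx records (anything sliceable whose
    slice stringifies to sequence).
    """
    if chrom not in reference:
        raise KeyError(f"chromosome {chrom!r} absent from reference")
    return str(reference[chrom][start - 1 : end]).upper()


def reformat_vcf(
    records: Iterable[VariantRecord],
    reference: Mapping[str, object],
) -> tuple[list[VariantRecord], list[Rejection]]:
    """Reformat records into the sequence-explicit common form.

    Returns (kept records, rejection log). Symbolic deletions,
    inversions and duplications with a usable END are rewritten with
    explicit alleles from the reference; symbolic insertions (whose
    inserted sequence is unknowable) and any record with residual
    non-ACGTN characters are dropped and logged. Identical duplicates
    (same chrom/pos/ref/alt) collapse to one record, first occurrence
    kept.
    """
    kept: list[VariantRecord] = []
    rejections: list[Rejection] = []
    seen: set[tuple[str, int, str, str]] = set()

    for rec in records:
        if rec.chrom not in reference:
            raise KeyError(f"chromosome {rec.chrom!r} absent from reference")
        if rec.is_symbolic:
            span_end = rec.end
            if span_end <= rec.pos or rec.sv_type is SVType.INS or rec.sv_type is SVType.NONE:
                rejections.append(Rejection(rec.chrom, rec.pos, "unresolvable symbolic allele"))
                continue
            span = _reference_slice(reference, rec.chrom, rec.pos, span_end)
            if rec.sv_type is SVType.DEL:
                ref_seq, alt_seq = span, span[0]
            elif rec.sv_type is SVType.INV:
                ref_seq, alt_seq = span, _revcomp(span)
            else:  # DUP: tandem duplication of the span
                ref_seq, alt_seq = span, span + span
            rec = VariantRecord.from_alleles(
                rec.chrom,
                rec.pos,
                ref_seq,
                alt_seq,
                sv_type_hint=rec.sv_type,
                end=span_end,
                genotype=rec.genotype,
                gq=rec.gq,
                dp=rec.dp,
                source=rec.source,
                sample_genotypes=rec.sample_genotypes,
            )
        else:
            ref_seq = rec.ref.upper()
            alt_seq = rec.alt.upper()
            if ref_seq != rec.ref or alt_seq != rec.alt:
                rec = rec.copy(ref=ref_seq, alts=(alt_seq,))
        if not (_VALID_ALLELE.match(rec.ref) and all(_VALID_ALLELE.match(a) for a in rec.alts)):
            rejections.append(Rejection(rec.chrom, rec.pos, "forbidden character in allele"))
            continue
        key = rec.sort_key()
        if key in seen:
            continue
        seen.add(key)
        kept.append(rec)
    return kept, rejections


def compute_maf(genotypes: Sequence[GenotypeCall]) -> float | None:
    """Minor allele frequency over alleles of non-missing genotypes.

    Returns None when every genotype is missing (the record then fails
    any minimum-MAF filter).
    """
    if not genotypes:
        raise ValueError("need at least one genotype")
    alt = total = 0
    for gt in genotypes:
        if gt.missing:
            continue
        total += len(gt.alleles)
        alt += sum(1 for a in gt.alleles if a != 0)
    if total == 0:
        return None
    p = alt / total
    return min(p, 1.0 - p)


def compute_missing_rate(genotypes: Sequence[GenotypeCall]) -> float:
    """Fraction of samples without a genotype call."""
    if not genotypes:
        raise ValueError("need at least one genotype")
    return sum(1 for gt in genotypes if gt.missing) / len(genotypes)


@dataclass
class FilterResult:
    retained: list[VariantRecord] = field(default_factory=list)
    removed: list[VariantRecord] = field(default_factory=list)

    @property
    def n_retained(self) -> int:
        return len(self.retained)

    @property
    def n_removed(self) -> int:
        return len(self.removed)


def _record_genotypes(rec: VariantRecord) -> Sequence[GenotypeCall]:
    return rec.sample_genotypes if rec.sample_genotypes is not None else (rec.genotype,)


def filter_population_vcf(
    records: Sequence[VariantRecord], config: FilterConfig
) -> FilterResult:
    """Retain records with MAF >= min_maf and missing rate <= max rate.

    Thresholds are inclusive on the keep side. A disabled config is the
    identity (no variant filtered).
    """
    result = FilterResult()
    if not config.enabled:
        result.retained = list(records)
        return result
    for rec in records:
        gts = _record_genotypes(rec)
        maf = compute_maf(gts)
        missing = compute_missing_rate(gts)
        keep = maf is not None and maf >= config.min_maf and missing <= config.max_missing_rate
        (result.retained if keep else result.removed).append(rec)
    return result


def write_rejection_log(rejections: Sequence[Rejection], path) -> None:
    with open(path, "w") as fh:
        fh.write("chrom\tpos\treason\n")
        for r in rejections:
            fh.write(f"{r.chrom}\t{r.pos}\t{r.reason}\n")
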