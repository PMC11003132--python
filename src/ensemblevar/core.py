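"""Core domain types for ensemble variant genotyping.

The pipeline reasons about three classes of sequence variation: single
nucleotide polymorphisms (SNPs), short insertions/deletions (indels,
1--49 bp) and structural variants (SVs, >= 50 bp, plus inversions and
duplications of any span). Every module downstream of VCF parsing works
on :class:`VariantRecord` objects carrying a normalized, biallelic view
of one call: coordinates, explicit alleles, a class/type label, a
diploid genotype and the per-call quality (GQ) and depth (DP) fields.

Coordinates follow VCF convention: 1-based, inclusive. ``end`` is the
last affected reference base (``pos + len(ref) - 1`` for deletions,
inversions and duplications; ``pos`` itself for SNPs and insertions).
Variant length is signed: ``len(alt) - len(ref)``.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pysam

__all__ = [
    "VarClass",
    "SVType",
    "GenotypeCall",
    "VariantRecord",
    "GenotyperOutput",
    "MalformedRecordError",
    "classify_variant",
    "genotype_equal",
    "read_vcf",
    "write_vcf",
]

#: smallest |length| (bp) at which an insertion or deletion is called an SV
SV_MIN_LENGTH = 50

ALLELE_ALPHABET = frozenset("ACGTN")


class MalformedRecordError(ValueError):
    """A VCF record that cannot be interpreted as a variant call."""


class VarClass(str, enum.Enum):
    SNP = "SNP"
    INDEL = "INDEL"
    SV = "SV"


class SVType(str, enum.Enum):
    INS = "INS"
    DEL = "DEL"
    INV = "INV"
    DUP = "DUP"
    NONE = "NONE"


_SYMBOLIC_TYPES = {
    "DEL": SVType.DEL,
    "INS": SVType.INS,
    "INV": SVType.INV,
    "DUP": SVType.DUP,
}


@dataclass(frozen=True, order=True)
class GenotypeCall:
    """A diploid genotype as an unordered pair of allele indices.

    Index 0 is the REF allele, k the k-th ALT. Equality is unordered:
    0/1 and 1/0 are the same call. A missing genotype carries no allele
    indices. Half-missing calls (``./1``) are treated as fully missing,
    and haploid calls are promoted to homozygous diploid.
    """

    alleles: tuple[int, ...] = ()
    missing: bool = True

    @classmethod
    def from_alleles(cls, alleles: Iterable[int | None]) -> "GenotypeCall":
        idx = tuple(alleles)
        if not idx or any(a is None for a in idx):
            return cls()
        if len(idx) == 1:  # haploid -> homozygous diploid
            idx = (idx[0], idx[0])
        return cls(tuple(sorted(int(a) for a in idx[:2])), missing=False)

    @classmethod
    def from_string(cls, text: str) -> "GenotypeCall":
        fields = text.replace("|", "/").split("/")
        return cls.from_alleles(None if f in (".", "") else int(f) for f in fields)

    def __str__(self) -> str:
        if self.missing:
            return "./."
        return "/".join(str(a) for a in self.alleles)

    @property
    def is_het(self) -> bool:
        return not self.missing and self.alleles[0] != self.alleles[1]


MISSING_GT = GenotypeCall()


def genotype_equal(a: GenotypeCall, b: GenotypeCall) -> bool:
    """Unordered genotype identity; missing never matches anything."""
    if a.missing or b.missing:
        return False
    return a.alleles == b.alleles


def classify_variant(
    ref: str, alt: str, sv_type_hint: SVType | str | None = None
) -> tuple[VarClass, SVType, int]:
    """Classify one REF/ALT pair into (class, SV type, signed length).

    Length is ``len(alt) - len(ref)``. |length| of 1--49 bp is an indel,
    >= 50 bp an SV; an INV or DUP hint forces class SV regardless of
    length (inversions are length 0 under the signed definition).
    Length-0 substitutions without a hint are treated as SNP class.
    """
    hint = SVType(sv_type_hint) if sv_type_hint not in (None, SVType.NONE, "NONE") else None
    if not ref or not alt:
        raise MalformedRecordError("empty allele string without an SV type hint")
    length = len(alt) - len(ref)
    if hint in (SVType.INV, SVType.DUP):
        return VarClass.SV, hint, length
    if abs(length) >= SV_MIN_LENGTH:
        if hint in (SVType.INS, SVType.DEL):
            return VarClass.SV, hint, length
        return VarClass.SV, SVType.INS if length > 0 else SVType.DEL, length
    if abs(length) >= 1:
        return VarClass.INDEL, SVType.NONE, length
    return VarClass.SNP, SVType.NONE, length


@dataclass
class VariantRecord:
    """One normalized biallelic variant call.

    ``alts`` keeps the ordered-tuple shape for VCF fidelity but holds a
    single ALT after multiallelic splitting. ``sample_genotypes`` is
    populated when the source VCF carries several samples (population
    inputs); ``genotype`` is then the first sample's call.
    """

    chrom: str
    pos: int
    ref: str
    alts: tuple[str, ...]
    var_class: VarClass
    sv_type: SVType = SVType.NONE
    length: int = 0
    end: int = 0
    genotype: GenotypeCall = MISSING_GT
    gq: float | None = None
    dp: float | None = None
    source: str | None = None
    sample_genotypes: tuple[GenotypeCall, ...] | None = None
    normalized_depth: float | None = None
    info: dict = field(default_factory=dict)

    @classmethod
    def from_alleles(
        cls,
        chrom: str,
        pos: int,
        ref: str,
        alt: str,
        *,
        sv_type_hint: SVType | str | None = None,
        end: int | None = None,
        **kwargs,
    ) -> "VariantRecord":
        var_class, sv_type, length = classify_variant(ref, alt, sv_type_hint)
        if end is None:
            end = pos if sv_type is SVType.INS else pos + len(ref) - 1
        return cls(
            chrom=chrom,
            pos=pos,
            ref=ref,
            alts=(alt,),
            var_class=var_class,
            sv_type=sv_type,
            length=length,
            end=end,
            **kwargs,
        )

    @property
    def alt(self) -> str:
        return self.alts[0]

    @property
    def effective_length(self) -> int:
        """Unsigned length used for size comparisons.

        Inversions have signed length 0 and duplications are
        insertion-shaped, so both use the reference span defined by
        ``end``; insertions, deletions and indels use |length|.
        """
        if self.sv_type in (SVType.INV, SVType.DUP):
            return self.end - self.pos + 1
        return abs(self.length)

    @property
    def is_symbolic(self) -> bool:
        return any(a.startswith("<") or a == "*" for a in self.alts)

    def sort_key(self) -> tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.ref, self.alt)

    def copy(self, **changes) -> "VariantRecord":
        return replace(self, **changes)


@dataclass
class GenotyperOutput:
    """All calls emitted by one genotyper for one sample."""

    tool: str
    records: list[VariantRecord]

    def __post_init__(self) -> None:
        for rec in self.records:
            rec.source = self.tool
        self.records.sort(key=VariantRecord.sort_key)


# ---------------------------------------------------------------------------
# VCF I/O


def _parse_symbolic(alt: str) -> SVType | None:
    if alt.startswith("<") and alt.endswith(">"):
        tag = alt[1:-1].split(":")[0]
        return _SYMBOLIC_TYPES.get(tag)
    return None


def _record_hint(rec: pysam.VariantRecord, alt: str) -> SVType | str | None:
    sym = _parse_symbolic(alt)
    if sym is not None:
        return sym
    try:
        svtype = rec.info.get("SVTYPE")
    except ValueError:  # tag not declared in the header
        return None
    if isinstance(svtype, tuple):
        svtype = svtype[0]
    if svtype in _SYMBOLIC_TYPES:
        return _SYMBOLIC_TYPES[svtype]
    return None


def _remap_genotype(raw: tuple, alt_index: int) -> GenotypeCall:
    """Project a (possibly multiallelic) GT onto one ALT.

    The kept ALT becomes index 1; REF and every other ALT become 0, so
    each split record describes carrier status for its own allele.
    """
    if raw is None or all(a is None for a in raw):
        return MISSING_GT
    if any(a is None for a in raw):  # half-missing -> missing
        return MISSING_GT
    return GenotypeCall.from_alleles(1 if a == alt_index else 0 for a in raw)


def read_vcf(path: str | Path) -> list[VariantRecord]:
    """Read a VCF 4.x file (plain or bgzipped) into VariantRecords.

    Multiallelic records are split into biallelic records with genotype
    indices remapped. GT, GQ and DP are preserved; a missing GT field
    keeps the record with a missing genotype. Symbolic ALTs (<DEL>,
    <INV>, <DUP>, ...) are kept as-is with class SV for downstream
    reformatting; their ``end`` comes from INFO/END.
    """
    records: list[VariantRecord] = []
    with pysam.VariantFile(str(path)) as vcf:
        n_samples = len(vcf.header.samples)
        for rec in vcf:
            if rec.alts is None:
                continue
            for alt_index, alt in enumerate(rec.alts, start=1):
                gts = None
                gq = dp = None
                if n_samples:
                    gts = tuple(
                        _remap_genotype(sample.get("GT"), alt_index)
                        for sample in rec.samples.values()
                    )
                    first = rec.samples[0]
                    gq = first.get("GQ")
                    dp = first.get("DP")
                sym = _parse_symbolic(alt)
                if sym is not None or alt == "*":
                    end = rec.stop  # pysam stop is 0-based exclusive == 1-based END
                    length = rec.info.get("SVLEN")
                    if isinstance(length, tuple):
                        length = length[0]
                    if length is None:
                        span = end - rec.pos
                        length = -span if sym is SVType.DEL else (span if sym is SVType.DUP else 0)
                    records.append(
                        VariantRecord(
                            chrom=rec.chrom,
                            pos=rec.pos,
                            ref=rec.ref,
                            alts=(alt,),
                            var_class=VarClass.SV,
                            sv_type=sym or SVType.NONE,
                            length=int(length),
                            end=end,
                            genotype=gts[0] if gts else MISSING_GT,
                            gq=gq,
                            dp=dp,
                            sample_genotypes=gts if gts and len(gts) > 1 else None,
                        )
                    )
                    continue
                vr = VariantRecord.from_alleles(
                    rec.chrom,
                    rec.pos,
                    rec.ref,
                    alt,
                    sv_type_hint=_record_hint(rec, alt),
                    genotype=gts[0] if gts else MISSING_GT,
                    gq=gq,
                    dp=dp,
                )
                if gts and len(gts) > 1:
                    vr.sample_genotypes = gts
                records.append(vr)
    records.sort(key=VariantRecord.sort_key)
    return records


_HEADER_LINES = [
    '##INFO=<ID=SVTYPE,Number=1,Type=String,Description="Structural variant type">',
    '##INFO=<ID=TOOLS,Number=.,Type=String,Description="Genotypers supporting the consensus genotype">',
    '##INFO=<ID=SUPPORT,Number=1,Type=Integer,Description="Number of genotypers supporting the consensus genotype">',
    '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
    '##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="Genotype quality">',
    '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">',
]


def write_vcf(
    records: Sequence[VariantRecord],
    path: str | Path,
    sample_name: str = "SAMPLE",
    contig_lengths: Mapping[str, int] | None = None,
) -> None:
    """Write VariantRecords to a sorted single-sample VCF 4.2 file.

    SV records get an INFO/SVTYPE tag so the class/type survives a
    round trip (an inversion written as explicit sequence would
    otherwise be indistinguishable from a substitution).
    """
    header = pysam.VariantHeader()
    for line in _HEADER_LINES:
        header.add_line(line)
    contigs: dict[str, int] = dict(contig_lengths or {})
    for rec in records:
        need = max(rec.end, rec.pos + len(rec.ref) - 1) + 1
        if contigs.get(rec.chrom, 0) < need:
            contigs[rec.chrom] = need
    for name in sorted(contigs):
        header.add_line(f"##contig=<ID={name},length={contigs[name]}>")
    header.add_sample(sample_name)

    with pysam.VariantFile(str(path), "w", header=header) as out:
        for rec in sorted(records, key=VariantRecord.sort_key):
            row = out.new_record(
                contig=rec.chrom,
                start=rec.pos - 1,
                alleles=(rec.ref, *rec.alts),
            )
            if rec.var_class is VarClass.SV:
                row.info["SVTYPE"] = rec.sv_type.value
            for key in ("TOOLS", "SUPPORT"):
                if key in rec.info:
                    row.info[key] = rec.info[key]
            sample = row.samples[sample_name]
            if rec.genotype.missing:
                sample["GT"] = (None, None)
            else:
                sample["GT"] = rec.genotype.alleles
            if rec.gq is not None:
                sample["GQ"] = int(round(rec.gq))
            if rec.dp is not None:
                sample["DP"] = int(round(rec.dp))
            out.write(row)
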