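"""Synthetic references, spiked truth sets, and noisy genotyper outputs.

Desk-scale stand-in for a full read-simulation stack: instead of
simulating reads and running real genotypers, it (1) draws a random
reference genome, (2) spikes a truth set of SNPs, indels and SVs into
it — producing a truth VCF plus the two haplotype sequences of the
simulated diploid, with the heterozygous fraction under direct control
— and (3) emulates K noisy genotyper output VCFs by corrupting the
truth with configurable false-negative, genotype-error, breakpoint-
jitter and length-jitter processes. That is exactly the statistical
structure the merge and evaluation stages consume, so the whole
ensemble pipeline can be exercised end to end in memory.

One global seed fans out through ``numpy.random.SeedSequence`` to
per-stage and per-tool streams, so adding a tool does not perturb
earlier streams.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

from .core import (
    GenotypeCall,
    GenotyperOutput,
    SVType,
    VarClass,
    VariantRecord,
)

__all__ = [
    "SpikeConfig",
    "ErrorProfile",
    "make_reference",
    "spike_variants",
    "simulate_outputs",
    "make_profiles",
]

BASES = np.array(list("ACGT"))

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

HOM_ALT = GenotypeCall((1, 1), missing=False)
HET = GenotypeCall((0, 1), missing=False)
HOM_REF = GenotypeCall((0, 0), missing=False)

#: genotypes a caller can emit; error draws pick among these minus the truth
CALLABLE_GENOTYPES = (HOM_REF, HET, HOM_ALT)


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(BASES, size=n))


def make_reference(
    n_chrom: int, lengths: Sequence[int], seed: int
) -> dict[str, str]:
    """Uniform-random reference sequences, deterministic under seed."""
    if len(lengths) != n_chrom:
        raise ValueError("need one length per chromosome")
    if any(l < 10_000 for l in lengths):
        raise ValueError("chromosome lengths must be at least 10 kb")
    rng = np.random.default_rng(seed)
    return {f"chr{i + 1}": _random_seq(rng, l) for i, l in enumerate(lengths)}


DEFAULT_COUNTS = {"SNP": 500, "INDEL": 200, "DEL": 100, "INS": 100, "INV": 50, "DUP": 50}
DEFAULT_SIZE_RANGES = {
    "INDEL": (1, 49),
    "DEL": (50, 500),
    "INS": (50, 500),
    "INV": (50, 500),
    "DUP": (50, 500),
}


@dataclass(frozen=True)
class SpikeConfig:
    """What to spike into the reference.

    ``counts`` is per class (SNP/INDEL) or SV type (DEL/INS/INV/DUP);
    ``het_fraction`` is the probability a spiked variant lands on only
    one haplotype (0/1) rather than both (1/1), mirroring the
    heterozygous-proportion knob of variant-spiking simulators.
    ``min_spacing`` keeps events far enough apart that clusters stay
    unambiguous.
    """

    counts: Mapping[str, int] = field(default_factory=lambda: dict(DEFAULT_COUNTS))
    het_fraction: float = 0.5
    size_ranges: Mapping[str, tuple[int, int]] = field(
        default_factory=lambda: dict(DEFAULT_SIZE_RANGES)
    )
    min_spacing: int = 600
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.het_fraction <= 1.0:
            raise ValueError("het_fraction must lie in [0, 1]")
        if any(c < 0 for c in self.counts.values()):
            raise ValueError("counts must be non-negative")
        lo, hi = self.size_ranges.get("INDEL", (1, 49))
        if not (1 <= lo <= hi <= 49):
            raise ValueError("indel sizes must lie in [1, 49]")
        for key in ("DEL", "INS", "INV", "DUP"):
            lo, hi = self.size_ranges.get(key, (50, 500))
            if not (50 <= lo <= hi):
                raise ValueError(f"{key} sizes must be at least 50 bp")


def _spike_one(
    rng: np.random.Generator,
    kind: str,
    chrom: str,
    pos: int,
    reference: str,
    config: SpikeConfig,
) -> VariantRecord:
    """Build one truth record of the requested kind at pos (1-based)."""
    seq = reference
    if kind == "SNP":
        ref = seq[pos - 1]
        alt = str(rng.choice([b for b in "ACGT" if b != ref]))
        return VariantRecord.from_alleles(chrom, pos, ref, alt)
    if kind == "INDEL":
        lo, hi = config.size_ranges["INDEL"]
        size = int(rng.integers(lo, hi + 1))
        if rng.random() < 0.5:  # insertion
            ref = seq[pos - 1]
            return VariantRecord.from_alleles(chrom, pos, ref, ref + _random_seq(rng, size))
        ref = seq[pos - 1 : pos + size]
        return VariantRecord.from_alleles(chrom, pos, ref, ref[0])
    lo, hi = config.size_ranges[kind]
    size = int(rng.integers(lo, hi + 1))
    if kind == "DEL":
        ref = seq[pos - 1 : pos + size]
        return VariantRecord.from_alleles(chrom, pos, ref, ref[0])
    if kind == "INS":
        ref = seq[pos - 1]
        return VariantRecord.from_alleles(chrom, pos, ref, ref + _random_seq(rng, size))
    span = seq[pos - 1 : pos - 1 + size]
    if kind == "INV":
        alt = span.translate(_COMPLEMENT)[::-1]
        return VariantRecord.from_alleles(chrom, pos, span, alt, sv_type_hint=SVType.INV)
    # DUP: tandem duplication written as span -> span+span
    return VariantRecord.from_alleles(chrom, pos, span, span + span, sv_type_hint=SVType.DUP)


def _footprint(kind: str, config: SpikeConfig) -> int:
    """Worst-case reference span (bp) an event of this kind occupies."""
    if kind == "SNP":
        return 1
    hi = config.size_ranges.get(kind, (1, 49))[1]
    return hi + 1


def spike_variants(
    reference: Mapping[str, str], config: SpikeConfig
) -> tuple[list[VariantRecord], dict[str, tuple[str, str]]]:
    """Spike the configured variant counts into the reference.

    Returns the truth records (each with a 0/1 or 1/1 genotype drawn
    from ``het_fraction``; heterozygous variants land on one random
    haplotype) and, per chromosome, the two haplotype sequences with
    the variants applied. Raises when the requested counts cannot be
    packed at ``min_spacing``.
    """
    rng = np.random.default_rng(np.random.SeedSequence(config.seed).spawn(1)[0])
    kinds: list[str] = []
    for kind in ("SNP", "INDEL", "DEL", "INS", "INV", "DUP"):
        kinds.extend([kind] * int(config.counts.get(kind, 0)))
    if not kinds:
        return [], {c: (s, s) for c, s in reference.items()}
    rng.shuffle(kinds)

    # distribute events over chromosomes proportionally to length
    chroms = sorted(reference)
    lengths = np.array([len(reference[c]) for c in chroms], dtype=float)
    slot = max(_footprint(k, config) for k in set(kinds)) + config.min_spacing
    capacity = (lengths // slot).astype(int) - 1
    if capacity.sum() < len(kinds):
        raise ValueError(
            f"cannot place {len(kinds)} variants with min_spacing "
            f"{config.min_spacing}: capacity {int(capacity.sum())}"
        )
    assignment: list[list[str]] = [[] for _ in chroms]
    order = np.argsort(-lengths)
    i = 0
    for kind in kinds:
        # round-robin over chromosomes with free capacity
        for _ in range(len(chroms)):
            ci = int(order[i % len(chroms)])
            i += 1
            if len(assignment[ci]) < capacity[ci]:
                assignment[ci].append(kind)
                break
        else:
            raise ValueError("variant packing overflow")

    truth: list[VariantRecord] = []
    haplotypes: dict[str, tuple[str, str]] = {}
    for ci, chrom in enumerate(chroms):
        seq = reference[chrom]
        todo = assignment[ci]
        if not todo:
            haplotypes[chrom] = (seq, seq)
            continue
        n = len(todo)
        # evenly spaced slots with random jitter inside each slot
        slot_len = (len(seq) - slot) // n
        records: list[VariantRecord] = []
        for j, kind in enumerate(todo):
            base = j * slot_len + config.min_spacing // 2
            jitter = int(rng.integers(0, max(1, slot_len - _footprint(kind, config) - config.min_spacing)))
            pos = base + jitter + 1
            rec = _spike_one(rng, kind, chrom, pos, seq, config)
            if config.het_fraction >= 1.0:
                het = True
            elif config.het_fraction <= 0.0:
                het = False
            else:
                het = bool(rng.random() < config.het_fraction)
            rec.genotype = HET if het else HOM_ALT
            hap_choice = int(rng.integers(0, 2)) if het else -1
            rec.info["hap"] = hap_choice  # -1 = both haplotypes
            records.append(rec)
        records.sort(key=VariantRecord.sort_key)
        truth.extend(records)
        haplotypes[chrom] = (
            _apply_edits(seq, [r for r in records if r.info["hap"] in (-1, 0)]),
            _apply_edits(seq, [r for r in records if r.info["hap"] in (-1, 1)]),
        )
    return truth, haplotypes


def _apply_edits(seq: str, records: Sequence[VariantRecord]) -> str:
    """Apply non-overlapping variants (sorted by pos) to a sequence."""
    out: list[str] = []
    cursor = 0  # 0-based
    for rec in records:
        start = rec.pos - 1
        out.append(seq[cursor:start])
        out.append(rec.alt)
        cursor = start + len(rec.ref)
    out.append(seq[cursor:])
    return "".join(out)


@dataclass(frozen=True)
class ErrorProfile:
    """Noise model for one emulated genotyper.

    Each truth variant is dropped with probability ``fn_rate``;
    surviving calls keep the true genotype with probability
    1 - ``genotype_error_rate`` and otherwise draw a different
    genotype. SV breakpoints and lengths are perturbed by rounded
    zero-mean Gaussian jitter. DP is drawn from a truncated normal
    (min 1); GQ is drawn around ``gq_correct_mean`` for correct
    genotypes and ``gq_error_mean`` for wrong ones, so quality
    threshold sweeps are informative.
    """

    tool: str
    fn_rate: float = 0.1
    genotype_error_rate: float = 0.05
    breakpoint_jitter_sd: float = 5.0
    length_jitter_sd: float = 5.0
    depth_mean: float = 30.0
    depth_sd: float = 8.0
    gq_correct_mean: float = 55.0
    gq_error_mean: float = 20.0
    gq_sd: float = 8.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.fn_rate <= 1.0 or not 0.0 <= self.genotype_error_rate <= 1.0:
            raise ValueError("rates must lie in [0, 1]")
        if self.breakpoint_jitter_sd < 0 or self.length_jitter_sd < 0:
            raise ValueError("jitter SDs must be non-negative")


def make_profiles(
    n_tools: int,
    seed: int,
    fn_rate: float = 0.1,
    genotype_error_rate: float = 0.05,
    breakpoint_jitter_sd: float = 5.0,
    length_jitter_sd: float = 5.0,
    **kwargs,
) -> list[ErrorProfile]:
    """K identically parameterized tools with independent seed streams."""
    children = np.random.SeedSequence(seed).spawn(n_tools)
    return [
        ErrorProfile(
            tool=f"tool{i + 1}",
            fn_rate=fn_rate,
            genotype_error_rate=genotype_error_rate,
            breakpoint_jitter_sd=breakpoint_jitter_sd,
            length_jitter_sd=length_jitter_sd,
            seed=int(child.generate_state(1)[0] % (2**31)),
            **kwargs,
        )
        for i, child in enumerate(children)
    ]


def _jitter_record(rec: VariantRecord, rng: np.random.Generator, profile: ErrorProfile) -> VariantRecord:
    """Perturb an SV's breakpoint and length, keeping the VCF shape valid.

    Allele sequences are regenerated to stay consistent with the
    jittered length; callers downstream use position, length, type and
    genotype, not sequence content.
    """
    if rec.var_class is not VarClass.SV:
        return rec
    dpos = int(round(rng.normal(0.0, profile.breakpoint_jitter_sd))) if profile.breakpoint_jitter_sd else 0
    dlen = int(round(rng.normal(0.0, profile.length_jitter_sd))) if profile.length_jitter_sd else 0
    if dpos == 0 and dlen == 0:
        return rec
    pos = max(1, rec.pos + dpos)
    size = max(50, rec.effective_length + dlen)
    if rec.sv_type is SVType.INS:
        ref = rec.ref[0]
        alt = ref + _random_seq(rng, size)
        return VariantRecord.from_alleles(rec.chrom, pos, ref, alt, sv_type_hint=SVType.INS)
    span = _random_seq(rng, size)
    if rec.sv_type is SVType.DEL:
        return VariantRecord.from_alleles(rec.chrom, pos, span[0] + span, span[0], sv_type_hint=SVType.DEL)
    if rec.sv_type is SVType.INV:
        alt = span.translate(_COMPLEMENT)[::-1]
        return VariantRecord.from_alleles(rec.chrom, pos, span, alt, sv_type_hint=SVType.INV)
    return VariantRecord.from_alleles(rec.chrom, pos, span, span + span, sv_type_hint=SVType.DUP)


def simulate_outputs(
    truth: Sequence[VariantRecord], profiles: Sequence[ErrorProfile]
) -> list[GenotyperOutput]:
    """Emulate one noisy output VCF per error profile."""
    if not profiles:
        raise ValueError("need at least one error profile")
    outputs: list[GenotyperOutput] = []
    for profile in profiles:
        rng = np.random.default_rng(profile.seed)
        records: list[VariantRecord] = []
        for rec in truth:
            if rng.random() < profile.fn_rate:
                continue
            call = _jitter_record(rec, rng, profile)
            if call is rec:
                call = rec.copy(info={})
            correct = rng.random() >= profile.genotype_error_rate
            if correct:
                gt = rec.genotype
                gq_mean = profile.gq_correct_mean
            else:
                others = [g for g in CALLABLE_GENOTYPES if g != rec.genotype]
                gt = others[int(rng.integers(0, len(others)))]
                gq_mean = profile.gq_error_mean
            call.genotype = gt
            call.dp = float(max(1, int(round(rng.normal(profile.depth_mean, profile.depth_sd)))))
            call.gq = float(min(99, max(0, int(round(rng.normal(gq_mean, profile.gq_sd))))))
            call.source = profile.tool
            records.append(call)
        outputs.append(GenotyperOutput(tool=profile.tool, records=records))
    return outputs
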