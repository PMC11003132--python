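"""Benchmarking a call set against a truth set.

Two levels of correctness are scored. *Presence*: the variant was
detected within tolerance — for an SV, both the start and the end
breakpoint lie within 200 bp (inclusive) of the true positions and the
sizes differ by at most 25% of the true size; for an indel, the
position difference is under 10 bp; for a SNP, position and alleles
match exactly. *Genotype*: presence plus unordered equality of the
called and true allele pairs.

Matching is one-to-one — a call can be the true-positive partner of at
most one truth variant and vice versa — greedy nearest-first in
genomic order. Precision = TP/(TP+FP), recall = TP/(TP+FN) and the
F-score is their harmonic mean, reported per variant class (SNP,
indel, DEL, INS, INV, DUP) and per level. Threshold sweeps over GQ
(with DP substituting when GQ is absent) yield precision-recall
curves; strata (signed-length bins or BED region sets) yield nested
reports with conserved marginal counts.
"""

from __future__ import annotations

import enum
from bisect import bisect_left, bisect_right
from collections import defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from intervaltree import IntervalTree

from .core import SVType, VarClass, VariantRecord, genotype_equal

__all__ = [
    "MatchRule",
    "MatchLevel",
    "Counts",
    "ClassReport",
    "EvalReport",
    "match_variant",
    "evaluate_calls",
    "pr_curve",
    "stratified_evaluate",
    "length_bin_strata",
    "read_bed",
    "BedStrata",
]


class MatchLevel(enum.IntEnum):
    NO_MATCH = 0
    PRESENCE = 1
    GENOTYPE = 2


@dataclass(frozen=True)
class MatchRule:
    """Tolerances for call-vs-truth matching.

    SV comparisons are inclusive ("within 200 bp", "at most 25%");
    the indel position rule is strict ("less than 10 bp"). Indel
    matching is position + class only by default; set
    ``indel_size_check`` to additionally demand the clustering-style
    size-ratio agreement.
    """

    sv_bp_tol: int = 200  # bp, inclusive
    sv_size_tol: float = 0.25  # fraction of true size, inclusive
    indel_pos_tol: int = 10  # bp, exclusive
    snp_exact: bool = True
    indel_size_check: bool = False

    def __post_init__(self) -> None:
        if self.sv_bp_tol < 0 or self.indel_pos_tol < 0 or self.sv_size_tol < 0:
            raise ValueError("tolerances must be non-negative")


def _class_key(rec: VariantRecord) -> str:
    if rec.var_class is VarClass.SV:
        return rec.sv_type.value
    return rec.var_class.value


CLASS_KEYS = ("SNP", "INDEL", "DEL", "INS", "INV", "DUP")


def _presence_match(call: VariantRecord, truth: VariantRecord, rule: MatchRule) -> bool:
    if call.chrom != truth.chrom or call.var_class is not truth.var_class:
        return False
    if truth.var_class is VarClass.SV:
        if call.sv_type is not truth.sv_type:
            return False
        if abs(call.pos - truth.pos) > rule.sv_bp_tol:
            return False
        if abs(call.end - truth.end) > rule.sv_bp_tol:
            return False
        true_size = truth.effective_length
        return abs(call.effective_length - true_size) <= rule.sv_size_tol * true_size
    if truth.var_class is VarClass.INDEL:
        if abs(call.pos - truth.pos) >= rule.indel_pos_tol:
            return False
        if rule.indel_size_check:
            denom = abs(truth.length)
            if denom and abs(abs(call.length) - denom) > rule.sv_size_tol * denom:
                return False
        return True
    # SNP
    if call.pos != truth.pos:
        return False
    if rule.snp_exact and (call.ref != truth.ref or call.alt != truth.alt):
        return False
    return True


def match_variant(call: VariantRecord, truth: VariantRecord, rule: MatchRule | None = None) -> MatchLevel:
    """Score one call against one truth variant."""
    rule = rule or MatchRule()
    if not _presence_match(call, truth, rule):
        return MatchLevel.NO_MATCH
    if genotype_equal(call.genotype, truth.genotype):
        return MatchLevel.GENOTYPE
    return MatchLevel.PRESENCE


@dataclass
class Counts:
    tp: int = 0
    fp: int = 0
    fn: int = 0

    @property
    def precision(self) -> float | None:
        return self.tp / (self.tp + self.fp) if (self.tp + self.fp) else None

    @property
    def recall(self) -> float | None:
        return self.tp / (self.tp + self.fn) if (self.tp + self.fn) else None

    @property
    def f_score(self) -> float | None:
        p, r = self.precision, self.recall
        if p is None or r is None or (p + r) == 0:
            return None
        return 2 * p * r / (p + r)

    def __iadd__(self, other: "Counts") -> "Counts":
        self.tp += other.tp
        self.fp += other.fp
        self.fn += other.fn
        return self


@dataclass
class ClassReport:
    presence: Counts = field(default_factory=Counts)
    genotype: Counts = field(default_factory=Counts)


@dataclass
class EvalReport:
    classes: dict[str, ClassReport] = field(default_factory=dict)
    pr_points: list[tuple[float, float, float]] = field(default_factory=list)
    strata: dict[str, "EvalReport"] = field(default_factory=dict)

    def class_report(self, key: str) -> ClassReport:
        return self.classes.setdefault(key, ClassReport())

    def overall(self) -> ClassReport:
        total = ClassReport()
        for rep in self.classes.values():
            total.presence += rep.presence
            total.genotype += rep.genotype
        return total

    def to_dataframe(self) -> pd.DataFrame:
        rows = []

        def emit(stratum: str, report: "EvalReport") -> None:
            items = list(report.classes.items()) + [("ALL", report.overall())]
            for cls, rep in items:
                for level, counts in (("presence", rep.presence), ("genotype", rep.genotype)):
                    rows.append(
                        {
                            "class": cls,
                            "level": level,
                            "stratum": stratum,
                            "tp": counts.tp,
                            "fp": counts.fp,
                            "fn": counts.fn,
                            "precision": counts.precision,
                            "recall": counts.recall,
                            "f_score": counts.f_score,
                        }
                    )

        emit("overall", self)
        for name, sub in self.strata.items():
            emit(name, sub)
        return pd.DataFrame(rows)


@dataclass
class _Pairing:
    """Internal matching outcome: TP pairs and the leftovers."""

    pairs: list[tuple[VariantRecord, VariantRecord, MatchLevel]]
    unmatched_calls: list[VariantRecord]
    unmatched_truth: list[VariantRecord]


def _pos_tolerance(var_class: VarClass, rule: MatchRule) -> int:
    if var_class is VarClass.SV:
        return rule.sv_bp_tol
    if var_class is VarClass.INDEL:
        return rule.indel_pos_tol
    return 0


def _match_all(
    calls: Sequence[VariantRecord], truth: Sequence[VariantRecord], rule: MatchRule
) -> _Pairing:
    """Greedy 1-to-1 pairing, nearest-first within tolerance.

    Calls are visited in genomic order; each takes the nearest (by
    start position, ties to the lower truth position) still-unmatched
    truth variant it presence-matches.
    """
    truth_by_key: dict[tuple, list[tuple[int, int]]] = defaultdict(list)
    for i, t in enumerate(truth):
        truth_by_key[(t.chrom, _class_key(t))].append((t.pos, i))
    for entries in truth_by_key.values():
        entries.sort()

    taken: set[int] = set()
    pairs: list[tuple[VariantRecord, VariantRecord, MatchLevel]] = []
    unmatched_calls: list[VariantRecord] = []

    for call in sorted(calls, key=VariantRecord.sort_key):
        entries = truth_by_key.get((call.chrom, _class_key(call)), [])
        tol = _pos_tolerance(call.var_class, rule)
        positions = [p for p, _ in entries]
        lo = bisect_left(positions, call.pos - tol)
        hi = bisect_right(positions, call.pos + tol)
        best_key: tuple | None = None
        best_idx = -1
        for p, i in entries[lo:hi]:
            if i in taken:
                continue
            if not _presence_match(call, truth[i], rule):
                continue
            key = (abs(call.pos - p), p)
            if best_key is None or key < best_key:
                best_key, best_idx = key, i
        if best_key is None:
            unmatched_calls.append(call)
            continue
        taken.add(best_idx)
        level = (
            MatchLevel.GENOTYPE
            if genotype_equal(call.genotype, truth[best_idx].genotype)
            else MatchLevel.PRESENCE
        )
        pairs.append((call, truth[best_idx], level))

    unmatched_truth = [t for i, t in enumerate(truth) if i not in taken]
    return _Pairing(pairs, unmatched_calls, unmatched_truth)


def _report_from_pairing(pairing: _Pairing) -> EvalReport:
    report = EvalReport()
    for call, truth_rec, level in pairing.pairs:
        rep = report.class_report(_class_key(truth_rec))
        rep.presence.tp += 1
        if level is MatchLevel.GENOTYPE:
            rep.genotype.tp += 1
        else:
            rep.genotype.fp += 1
            rep.genotype.fn += 1
    for call in pairing.unmatched_calls:
        rep = report.class_report(_class_key(call))
        rep.presence.fp += 1
        rep.genotype.fp += 1
    for t in pairing.unmatched_truth:
        rep = report.class_report(_class_key(t))
        rep.presence.fn += 1
        rep.genotype.fn += 1
    return report


def evaluate_calls(
    calls: Sequence[VariantRecord],
    truth: Sequence[VariantRecord],
    rule: MatchRule | None = None,
) -> EvalReport:
    """Match calls to truth and tally TP/FP/FN per class and level.

    Calls matching no truth variant are false positives; unmatched
    truth variants are false negatives. At the genotype level a
    presence-only match counts as both a false positive (wrong call)
    and a false negative (true genotype not recovered).
    """
    rule = rule or MatchRule()
    return _report_from_pairing(_match_all(calls, truth, rule))


def _call_score(call: VariantRecord, score_field: str) -> float | None:
    if score_field == "DP":
        return call.dp
    # GQ with DP substitution when genotype quality is unavailable
    if call.gq is not None:
        return call.gq
    return call.dp


def pr_curve(
    calls: Sequence[VariantRecord],
    truth: Sequence[VariantRecord],
    rule: MatchRule | None = None,
    score_field: str = "GQ",
    level: str = "genotype",
) -> list[tuple[float, float, float]]:
    """Precision-recall sweep over the call-quality threshold.

    For each distinct score value t (ascending thresholds, i.e. from
    the loosest cut to the strictest) the metrics are recomputed on the
    calls with score >= t, pooled over classes. The loosest point
    equals the unfiltered evaluation; recall never increases with t.
    Calls with neither GQ nor DP are dropped from the sweep.
    """
    rule = rule or MatchRule()
    if score_field not in ("GQ", "DP"):
        raise ValueError("score_field must be GQ or DP")
    scored = {id(c): _call_score(c, score_field) for c in calls}
    subset = [c for c in calls if scored[id(c)] is not None]
    if not subset:
        return []
    # match once on all scored calls, then sweep the score threshold over
    # the fixed pairing (the standard ranked PR construction); this keeps
    # recall monotone and makes the loosest point equal the overall metrics
    pairing = _match_all(subset, truth, rule)
    want = MatchLevel.GENOTYPE if level == "genotype" else MatchLevel.PRESENCE
    tp_scores = sorted(scored[id(c)] for c, _, lvl in pairing.pairs if lvl >= want)
    all_scores = sorted(scored[id(c)] for c in subset)
    n_truth = len(truth)
    points: list[tuple[float, float, float]] = []
    for t in sorted(set(all_scores)):
        tp = len(tp_scores) - bisect_left(tp_scores, t)
        n_calls = len(all_scores) - bisect_left(all_scores, t)
        precision = tp / n_calls if n_calls else float("nan")
        recall = tp / n_truth if n_truth else float("nan")
        points.append((float(t), precision, recall))
    return points


# ---------------------------------------------------------------------------
# Stratification


class BedStrata:
    """Ordered, labelled BED region sets; first-listed set wins overlaps."""

    def __init__(self, sets: Sequence[tuple[str, dict[str, IntervalTree]]], fallback: str = "non-repeat"):
        self.sets = list(sets)
        self.fallback = fallback

    def label(self, rec: VariantRecord) -> str:
        start0 = rec.pos - 1  # half-open 0-based interval of the event
        end0 = max(rec.end, rec.pos)
        for name, trees in self.sets:
            tree = trees.get(rec.chrom)
            if tree is not None and tree.overlap(start0, end0):
                return name
        return self.fallback


def read_bed(path: str | Path) -> dict[str, IntervalTree]:
    """Read a plain BED file (0-based half-open) into interval trees."""
    trees: dict[str, IntervalTree] = defaultdict(IntervalTree)
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            chrom, start, end = line.split("\t")[:3]
            trees[chrom].addi(int(start), int(end))
    return dict(trees)


class length_bin_strata:
    """Signed-length bins, half-open [edge_i, edge_{i+1})."""

    def __init__(self, edges: Sequence[float]):
        if len(edges) < 2 or list(edges) != sorted(edges):
            raise ValueError("need at least two sorted bin edges")
        self.edges = list(edges)

    def label(self, rec: VariantRecord) -> str:
        length = rec.length
        for lo, hi in zip(self.edges, self.edges[1:]):
            if lo <= length < hi:
                return f"[{lo:g},{hi:g})"
        return "out-of-range"


def stratified_evaluate(
    calls: Sequence[VariantRecord],
    truth: Sequence[VariantRecord],
    rule: MatchRule | None = None,
    strata: BedStrata | length_bin_strata | None = None,
) -> EvalReport:
    """Overall evaluation plus per-stratum sub-reports.

    The matching is performed once, globally; each TP/FN is then
    booked in its truth variant's stratum and each FP in the stratum
    of the call itself, so per-stratum counts sum exactly to the
    overall report.
    """
    rule = rule or MatchRule()
    pairing = _match_all(calls, truth, rule)
    report = _report_from_pairing(pairing)
    if strata is None:
        return report

    def sub(label: str) -> EvalReport:
        return report.strata.setdefault(label, EvalReport())

    for call, truth_rec, level in pairing.pairs:
        rep = sub(strata.label(truth_rec)).class_report(_class_key(truth_rec))
        rep.presence.tp += 1
        if level is MatchLevel.GENOTYPE:
            rep.genotype.tp += 1
        else:
            rep.genotype.fp += 1
            rep.genotype.fn += 1
    for call in pairing.unmatched_calls:
        rep = sub(strata.label(call)).class_report(_class_key(call))
        rep.presence.fp += 1
        rep.genotype.fp += 1
    for t in pairing.unmatched_truth:
        rep = sub(strata.label(t)).class_report(_class_key(t))
        rep.presence.fn += 1
        rep.genotype.fn += 1
    return report
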