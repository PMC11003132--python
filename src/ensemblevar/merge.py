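"""Multi-genotyper merging: clustering, variant graph, consensus calls.

Different graph genotypers report the same underlying variant at
slightly different coordinates and lengths. Merging therefore anchors
every cluster on one variant of the input (population) set — the
coordinates the outputs "should correspond to" — and assigns each
per-tool call to its nearest admissible anchor of the same class.

Admissibility, per variant class:

* SV (>= 50 bp, or any inversion/duplication): start-position
  difference < 200 bp (default) and length-difference ratio < 0.25 of
  the anchor length, same SV type;
* indel (1-49 bp): position difference < 10 bp, same ratio rule;
* SNP: exact position match.

Read depths are made comparable across tools by per-tool Z-score
normalization, D' = (D - mu) / sigma with sigma the population
standard deviation (divisor N) over all of a tool's calls. The
consensus genotype at each node is the one supported by most
genotypers; small variants with no genotype supported by more than one
tool are skipped, while SV nodes where every genotype has support 1
fall back to the call with the smallest |D'|.
"""

from __future__ import annotations

import math
from bisect import bisect_left, bisect_right
from collections import defaultdict
from dataclasses import dataclass, field
from typing import Iterator, Sequence

import numpy as np

from .core import (
    GenotypeCall,
    GenotyperOutput,
    SVType,
    VarClass,
    VariantRecord,
    genotype_equal,
)

__all__ = [
    "ClusterThresholds",
    "ToolCall",
    "ClusterNode",
    "VariantGraph",
    "DepthStats",
    "SKIPPED",
    "cluster_calls",
    "build_variant_graph",
    "normalize_depths",
    "consensus_small",
    "consensus_sv",
    "merge_genotyper_outputs",
]

#: sentinel returned when a node receives no consensus genotype
SKIPPED = None


@dataclass(frozen=True)
class ClusterThresholds:
    """Position and length tolerances for co-clustering calls.

    Position tolerances are strict upper bounds ("less than"); the SNP
    tolerance of 0 therefore demands exact position identity. The
    length-difference ratio is strict as well, with the anchor's
    length as denominator.
    """

    sv_pos_tol: int = 200  # bp
    sv_len_ratio: float = 0.25
    indel_pos_tol: int = 10  # bp
    snp_pos_tol: int = 0  # bp

    def __post_init__(self) -> None:
        if min(self.sv_pos_tol, self.indel_pos_tol, self.snp_pos_tol) < 0:
            raise ValueError("position tolerances must be non-negative")
        if self.sv_len_ratio < 0:
            raise ValueError("sv_len_ratio must be non-negative")

    def pos_tol(self, var_class: VarClass) -> int:
        if var_class is VarClass.SV:
            return self.sv_pos_tol
        if var_class is VarClass.INDEL:
            return self.indel_pos_tol
        return self.snp_pos_tol


@dataclass(frozen=True)
class ToolCall:
    """One genotyper's call as attached to a cluster node."""

    tool: str
    genotype: GenotypeCall
    dp: float | None
    gq: float | None
    pos: int
    length: int
    normalized_depth: float | None = None
    record: VariantRecord | None = None


@dataclass
class ClusterNode:
    anchor: VariantRecord
    calls: dict[str, ToolCall] = field(default_factory=dict)

    @property
    def branch_key(self) -> tuple[str, int]:
        return (self.anchor.chrom, self.anchor.pos)


def _admissible(anchor: VariantRecord, call: VariantRecord, thr: ClusterThresholds) -> bool:
    if anchor.chrom != call.chrom or anchor.var_class is not call.var_class:
        return False
    if anchor.var_class is VarClass.SV and anchor.sv_type is not call.sv_type:
        return False
    pos_diff = abs(call.pos - anchor.pos)
    if anchor.var_class is VarClass.SNP:
        if pos_diff > thr.snp_pos_tol:
            return False
        return True
    if pos_diff >= thr.pos_tol(anchor.var_class):
        return False
    denom = anchor.effective_length
    if denom == 0:
        return call.effective_length == 0
    return abs(call.effective_length - denom) / denom < thr.sv_len_ratio


def _preference_key(anchor: VariantRecord, call: VariantRecord) -> tuple[int, int, int]:
    """Nearest anchor by position, then smaller length difference, then
    lower anchor position."""
    return (
        abs(call.pos - anchor.pos),
        abs(call.effective_length - anchor.effective_length),
        anchor.pos,
    )


def cluster_calls(
    anchors: Sequence[VariantRecord],
    outputs: Sequence[GenotyperOutput],
    thresholds: ClusterThresholds | None = None,
) -> tuple[list[ClusterNode], list[VariantRecord]]:
    """Assign every genotyper call to at most one anchor variant.

    Returns one ClusterNode per anchor (in input order) plus the list
    of calls that matched no anchor. A tool contributes at most one
    call per node; when two of its calls prefer the same anchor the
    closer one (same preference key) wins and the other goes
    unassigned.
    """
    thr = thresholds or ClusterThresholds()
    nodes = [ClusterNode(anchor=a) for a in anchors]

    # anchors bucketed by (chrom, class, sv_type) and sorted by pos for
    # windowed candidate lookup
    buckets: dict[tuple, list[tuple[int, int]]] = defaultdict(list)  # pos, node idx
    for idx, a in enumerate(anchors):
        buckets[(a.chrom, a.var_class, a.sv_type)].append((a.pos, idx))
    for entries in buckets.values():
        entries.sort()

    unassigned: list[VariantRecord] = []
    # per (node index, tool): winning call so far with its key
    winners: dict[tuple[int, str], tuple[tuple, VariantRecord]] = {}

    for out in outputs:
        for call in out.records:
            key = (call.chrom, call.var_class, call.sv_type)
            entries = buckets.get(key)
            if not entries:
                unassigned.append(call)
                continue
            tol = thr.pos_tol(call.var_class)
            positions = [p for p, _ in entries]
            lo = bisect_left(positions, call.pos - tol)
            hi = bisect_right(positions, call.pos + tol)
            best: tuple | None = None
            best_idx = -1
            for p, idx in entries[lo:hi]:
                anchor = anchors[idx]
                if not _admissible(anchor, call, thr):
                    continue
                k = _preference_key(anchor, call)
                if best is None or k < best:
                    best, best_idx = k, idx
            if best is None:
                unassigned.append(call)
                continue
            wkey = (best_idx, call.source or out.tool)
            prev = winners.get(wkey)
            ckey = (*best, call.pos, call.effective_length)
            if prev is None or ckey < prev[0]:
                if prev is not None:
                    unassigned.append(prev[1])
                winners[wkey] = (ckey, call)
            else:
                unassigned.append(call)

    for (node_idx, tool), (_, call) in winners.items():
        nodes[node_idx].calls[tool] = ToolCall(
            tool=tool,
            genotype=call.genotype,
            dp=call.dp,
            gq=call.gq,
            pos=call.pos,
            length=call.length,
            normalized_depth=call.normalized_depth,
            record=call,
        )
    return nodes, unassigned


class VariantGraph:
    """Cluster nodes keyed by genomic position.

    Nodes sharing a (chrom, pos) — distinct alleles of one site — lie
    on the same branch; iteration yields branches in genomic order.
    """

    def __init__(self, nodes: Sequence[ClusterNode] = ()) -> None:
        self._branches: dict[tuple[str, int], list[ClusterNode]] = {}
        for node in nodes:
            self.add(node)

    def add(self, node: ClusterNode) -> None:
        self._branches.setdefault(node.branch_key, []).append(node)

    def __len__(self) -> int:
        return sum(len(b) for b in self._branches.values())

    @property
    def n_branches(self) -> int:
        return len(self._branches)

    def branches(self) -> Iterator[tuple[tuple[str, int], list[ClusterNode]]]:
        for key in sorted(self._branches):
            yield key, self._branches[key]

    def __iter__(self) -> Iterator[ClusterNode]:
        for _, nodes in self.branches():
            yield from nodes


def build_variant_graph(nodes: Sequence[ClusterNode]) -> VariantGraph:
    return VariantGraph(nodes)


@dataclass(frozen=True)
class DepthStats:
    """Per-genotyper depth moments used for Z-score normalization."""

    tool: str
    mu: float
    sigma: float  # population SD, divisor N
    n: int

    def normalize(self, depth: float) -> float:
        if self.sigma == 0:
            return 0.0
        return (depth - self.mu) / self.sigma


def normalize_depths(outputs: Sequence[GenotyperOutput]) -> dict[str, DepthStats]:
    """Z-score-normalize read depths per tool, in place.

    For each tool, mu and sigma are taken over the depths of all its
    calls that carry DP; each such call's ``normalized_depth`` is set
    to (D - mu) / sigma. Degenerate spread (sigma = 0) maps every D'
    to 0; calls without DP keep ``normalized_depth`` = None. Tools with
    no depth-bearing calls get no stats entry.
    """
    stats: dict[str, DepthStats] = {}
    for out in outputs:
        depths = np.array([r.dp for r in out.records if r.dp is not None], dtype=float)
        if depths.size == 0:
            continue
        mu = float(depths.mean())
        sigma = float(depths.std(ddof=0))
        st = DepthStats(tool=out.tool, mu=mu, sigma=sigma, n=int(depths.size))
        stats[out.tool] = st
        for rec in out.records:
            rec.normalized_depth = st.normalize(rec.dp) if rec.dp is not None else None
    return stats


def _abs_dprime(call: ToolCall) -> float:
    """Depth tie-break score; calls without D' lose to any call with one."""
    if call.normalized_depth is None:
        return math.inf
    return abs(call.normalized_depth)


def _group_by_genotype(node: ClusterNode) -> dict[GenotypeCall, list[ToolCall]]:
    groups: dict[GenotypeCall, list[ToolCall]] = defaultdict(list)
    for call in node.calls.values():
        if not call.genotype.missing:
            groups[call.genotype].append(call)
    return groups


def _pick_by_depth(groups: dict[GenotypeCall, list[ToolCall]]) -> GenotypeCall:
    """Smallest |D'| among the candidate genotypes' supporting calls;
    deterministic lexical fallback on the allele tuple."""
    return min(groups, key=lambda gt: (min(_abs_dprime(c) for c in groups[gt]), gt.alleles))


def consensus_small(node: ClusterNode) -> GenotypeCall | None:
    """Consensus genotype for a SNP/indel node.

    The genotype supported by most genotypers wins, provided that
    support is at least 2; when no genotype is supported by more than
    one tool the variant is skipped. Ties between genotypes with equal
    support >= 2 are resolved by the smallest |D'|.
    """
    if node.anchor.var_class is VarClass.SV:
        raise ValueError("consensus_small expects a SNP or indel node")
    groups = _group_by_genotype(node)
    if not groups:
        return SKIPPED
    top = max(len(calls) for calls in groups.values())
    if top < 2:
        return SKIPPED
    tied = {gt: calls for gt, calls in groups.items() if len(calls) == top}
    return _pick_by_depth(tied)


def consensus_sv(node: ClusterNode) -> GenotypeCall | None:
    """Consensus genotype for an SV node.

    Majority rule as for small variants, but when every distinct
    genotype has support exactly 1 the call with the smallest
    normalized absolute depth |D'| provides the genotype; a node with
    no (non-missing) calls is skipped.
    """
    if node.anchor.var_class is not VarClass.SV:
        raise ValueError("consensus_sv expects an SV node")
    groups = _group_by_genotype(node)
    if not groups:
        return SKIPPED
    top = max(len(calls) for calls in groups.values())
    tied = {gt: calls for gt, calls in groups.items() if len(calls) == top}
    return _pick_by_depth(tied)


def _node_consensus(node: ClusterNode) -> GenotypeCall | None:
    if node.anchor.var_class is VarClass.SV:
        return consensus_sv(node)
    return consensus_small(node)


def merge_genotyper_outputs(
    anchors: Sequence[VariantRecord],
    outputs: Sequence[GenotyperOutput],
    thresholds: ClusterThresholds | None = None,
) -> list[VariantRecord]:
    """End-to-end merge: normalize depths, cluster, call consensus.

    Emits one record per anchor that received a consensus genotype,
    at the anchor's coordinates and alleles, with the consensus GT and
    INFO keys TOOLS (supporting genotypers) and SUPPORT (their count).
    """
    normalize_depths(outputs)
    nodes, _ = cluster_calls(anchors, outputs, thresholds)
    graph = build_variant_graph(nodes)
    merged: list[VariantRecord] = []
    for node in graph:
        consensus = _node_consensus(node)
        if consensus is SKIPPED:
            continue
        supporters = sorted(
            tool
            for tool, call in node.calls.items()
            if genotype_equal(call.genotype, consensus)
        )
        dps = [node.calls[t].dp for t in supporters if node.calls[t].dp is not None]
        gqs = [node.calls[t].gq for t in supporters if node.calls[t].gq is not None]
        rec = node.anchor.copy(
            genotype=consensus,
            source="ensemble",
            dp=float(np.mean(dps)) if dps else None,
            gq=float(np.mean(gqs)) if gqs else None,
            sample_genotypes=None,
            info={"TOOLS": tuple(supporters), "SUPPORT": len(supporters)},
        )
        merged.append(rec)
    merged.sort(key=VariantRecord.sort_key)
    return merged
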