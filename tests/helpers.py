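"""Shared record builders and independent oracles for the test suite."""

from __future__ import annotations

import math
from collections import Counter

import numpy as np

from ensemblevar import (
    ClusterThresholds,
    GenotypeCall,
    GenotyperOutput,
    SVType,
    VarClass,
    VariantRecord,
)


def gt(text: str) -> GenotypeCall:
    return GenotypeCall.from_string(text)


def mk_snp(pos, ref="A", alt="T", chrom="chr1", genotype="0/1", **kw) -> VariantRecord:
    return VariantRecord.from_alleles(chrom, pos, ref, alt, genotype=gt(genotype), **kw)


def mk_indel(pos, signed_len, chrom="chr1", genotype="0/1", **kw) -> VariantRecord:
    assert 1 <= abs(signed_len) <= 49
    if signed_len > 0:
        ref, alt = "A", "A" + "C" * signed_len
    else:
        ref, alt = "A" + "C" * (-signed_len), "A"
    return VariantRecord.from_alleles(chrom, pos, ref, alt, genotype=gt(genotype), **kw)


def mk_sv(pos, sv_type, size, chrom="chr1", genotype="0/1", **kw) -> VariantRecord:
    """Sequence-explicit SV of the given type and unsigned size (bp)."""
    sv_type = SVType(sv_type)
    assert size >= 50 or sv_type in (SVType.INV, SVType.DUP)
    if sv_type is SVType.DEL:
        ref, alt = "A" + "C" * size, "A"
    elif sv_type is SVType.INS:
        ref, alt = "A", "A" + "C" * size
    elif sv_type is SVType.INV:
        ref, alt = "A" * size, "T" * size
    else:  # DUP
        ref, alt = "AC" * (size // 2) + "A" * (size % 2), None
        alt = ref + ref
    return VariantRecord.from_alleles(
        chrom, pos, ref, alt, sv_type_hint=sv_type, genotype=gt(genotype), **kw
    )


# ---------------------------------------------------------------------------
# Brute-force clustering oracle: scores every (anchor, call) pair against
# the thresholds directly, then applies the same nearest-anchor and
# per-tool resolution rules, with no spatial indexing or bucketing.


def _oracle_admissible(anchor, call, thr: ClusterThresholds) -> bool:
    if anchor.chrom != call.chrom or anchor.var_class is not call.var_class:
        return False
    if anchor.var_class is VarClass.SV and anchor.sv_type is not call.sv_type:
        return False
    d = abs(call.pos - anchor.pos)
    if anchor.var_class is VarClass.SNP:
        return d <= thr.snp_pos_tol
    tol = thr.sv_pos_tol if anchor.var_class is VarClass.SV else thr.indel_pos_tol
    if d >= tol:
        return False
    denom = anchor.effective_length
    if denom == 0:
        return call.effective_length == 0
    return abs(call.effective_length - denom) / denom < thr.sv_len_ratio


def brute_force_cluster(anchors, outputs, thr: ClusterThresholds):
    """All-pairs matcher returning {anchor index: {tool: (pos, length)}}
    plus the set of unassigned calls as (tool, pos, length) triples."""
    prefer = {}  # (tool, call serial) -> (key, anchor idx, call)
    unassigned = []
    serial = 0
    for out in outputs:
        for call in out.records:
            best = None
            best_idx = None
            for idx, anchor in enumerate(anchors):
                if not _oracle_admissible(anchor, call, thr):
                    continue
                key = (
                    abs(call.pos - anchor.pos),
                    abs(call.effective_length - anchor.effective_length),
                    anchor.pos,
                )
                if best is None or key < best:
                    best, best_idx = key, idx
            if best is None:
                unassigned.append((out.tool, call.pos, call.effective_length))
            else:
                prefer[(out.tool, serial)] = (best, best_idx, call)
            serial += 1

    assigned = {}  # anchor idx -> {tool: (pos, eff len)}
    winners = {}  # (anchor idx, tool) -> (full key, tool serial)
    for (tool, sid), (key, idx, call) in prefer.items():
        full = (*key, call.pos, call.effective_length)
        wkey = (idx, tool)
        prev = winners.get(wkey)
        if prev is None or full < prev[0]:
            if prev is not None:
                loser = prefer[(tool, prev[1])][2]
                unassigned.append((tool, loser.pos, loser.effective_length))
            winners[wkey] = (full, sid)
        else:
            unassigned.append((tool, call.pos, call.effective_length))
    for (idx, tool), (_, sid) in winners.items():
        call = prefer[(tool, sid)][2]
        assigned.setdefault(idx, {})[tool] = (call.pos, call.effective_length)
    return assigned, Counter(unassigned)


def random_cluster_instance(rng: np.random.Generator, n_anchors=None, n_tools=3):
    """Random anchors with deliberately tight spacing plus jittered,
    spurious and dropped calls, to exercise the tie rules."""
    n_anchors = n_anchors or int(rng.integers(5, 201))
    anchors = []
    pos = 100
    seen = set()
    for _ in range(n_anchors):
        pos += int(rng.integers(1, 400))
        kind = rng.choice(["SNP", "INDEL", "DEL", "INS", "INV", "DUP"])
        if kind == "SNP":
            rec = mk_snp(pos)
        elif kind == "INDEL":
            rec = mk_indel(pos, int(rng.integers(1, 50)) * (1 if rng.random() < 0.5 else -1))
        else:
            rec = mk_sv(pos, kind, int(rng.integers(50, 400)))
        key = (rec.pos, rec.var_class, rec.sv_type, rec.effective_length)
        if key in seen:
            continue
        seen.add(key)
        anchors.append(rec)
    outputs = []
    for t in range(n_tools):
        records = []
        for a in anchors:
            if rng.random() < 0.15:
                continue
            if a.var_class is VarClass.SNP:
                rec = mk_snp(a.pos + (0 if rng.random() < 0.8 else int(rng.integers(-2, 3))))
            elif a.var_class is VarClass.INDEL:
                p = a.pos + int(rng.integers(-12, 13))
                rec = mk_indel(max(1, p), a.length if a.length else 1)
            else:
                p = max(1, a.pos + int(rng.integers(-250, 251)))
                size = max(50, int(a.effective_length * (1 + rng.normal(0, 0.2))))
                rec = mk_sv(p, a.sv_type.value, size)
            rec.dp = float(rng.integers(1, 60))
            records.append(rec)
        # spurious calls far from any anchor
        for _ in range(int(rng.integers(0, 10))):
            records.append(mk_sv(int(rng.integers(500_000, 600_000)), "DEL", int(rng.integers(50, 300))))
        outputs.append(GenotyperOutput(tool=f"tool{t + 1}", records=records))
    return anchors, outputs


# ---------------------------------------------------------------------------
# Independent consensus oracle: a direct transcription of the voting rules.


def consensus_oracle(var_class: VarClass, calls: dict) -> GenotypeCall | None:
    """calls: tool -> (GenotypeCall, normalized depth or None)."""
    support = Counter(g for g, _ in calls.values() if not g.missing)
    if not support:
        return None
    top = max(support.values())
    if var_class is not VarClass.SV and top < 2:
        return None

    def score(g):
        best = math.inf
        for cg, d in calls.values():
            if cg == g and d is not None:
                best = min(best, abs(d))
        return (best, g.alleles)

    tied = [g for g, c in support.items() if c == top]
    return min(tied, key=score)
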