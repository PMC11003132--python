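"""Clustering, Z-score depth normalization and consensus genotyping."""

import itertools
import math

import numpy as np
import pytest

from ensemblevar import (
    ClusterThresholds,
    GenotypeCall,
    GenotyperOutput,
    VarClass,
    build_variant_graph,
    cluster_calls,
    consensus_small,
    consensus_sv,
    evaluate_calls,
    make_profiles,
    merge_genotyper_outputs,
    normalize_depths,
    simulate_outputs,
)
from ensemblevar.merge import ClusterNode, ToolCall

from helpers import (
    brute_force_cluster,
    consensus_oracle,
    gt,
    mk_indel,
    mk_snp,
    mk_sv,
    random_cluster_instance,
)


def _one_tool(*records, tool="toolA"):
    return [GenotyperOutput(tool=tool, records=list(records))]


class TestClustering:
    def test_sv_within_both_tolerances_is_assigned(self):
        anchor = mk_sv(1000, "DEL", 100)
        call = mk_sv(1080, "DEL", 110)
        nodes, unassigned = cluster_calls([anchor], _one_tool(call))
        assert not unassigned
        assert nodes[0].calls["toolA"].pos == 1080

    def test_sv_length_ratio_rule_rejects(self):
        anchor = mk_sv(1000, "DEL", 100)
        call = mk_sv(1000, "DEL", 160)  # ratio 0.60
        nodes, unassigned = cluster_calls([anchor], _one_tool(call))
        assert nodes[0].calls == {} and len(unassigned) == 1

    def test_snp_requires_exact_position(self):
        anchor = mk_snp(500)
        ok, off = mk_snp(500), mk_snp(501)
        nodes, unassigned = cluster_calls([anchor], _one_tool(ok, off))
        assert nodes[0].calls["toolA"].pos == 500
        assert [c.pos for c in unassigned] == [501]

    def test_nearest_anchor_wins(self):
        anchors = [mk_sv(1000, "DEL", 100), mk_sv(1150, "DEL", 100)]
        call = mk_sv(1090, "DEL", 100)  # 90 vs 60 away
        nodes, unassigned = cluster_calls(anchors, _one_tool(call))
        assert not unassigned
        assert nodes[0].calls == {} and nodes[1].calls["toolA"].pos == 1090

    def test_position_tolerances_are_strict(self):
        anchor_sv = mk_sv(1000, "DEL", 100)
        at_200 = mk_sv(1200, "DEL", 100)
        nodes, unassigned = cluster_calls([anchor_sv], _one_tool(at_200))
        assert nodes[0].calls == {} and len(unassigned) == 1  # "less than 200"
        anchor_indel = mk_indel(1000, 5)
        at_10 = mk_indel(1010, 5)
        nodes, unassigned = cluster_calls([anchor_indel], _one_tool(at_10))
        assert nodes[0].calls == {} and len(unassigned) == 1  # "less than 10"

    def test_classes_and_sv_types_never_mix(self):
        anchors = [mk_sv(1000, "DEL", 100), mk_sv(1000, "INV", 100)]
        call_ins = mk_sv(1000, "INS", 100)
        call_inv = mk_sv(1010, "INV", 100)
        nodes, unassigned = cluster_calls(anchors, _one_tool(call_ins, call_inv))
        assert nodes[0].calls == {}
        assert nodes[1].calls["toolA"].pos == 1010
        assert [c.sv_type.value for c in unassigned] == ["INS"]

    def test_one_call_per_tool_per_node(self):
        anchor = mk_sv(1000, "DEL", 100)
        near, far = mk_sv(1010, "DEL", 100), mk_sv(1050, "DEL", 100)
        nodes, unassigned = cluster_calls([anchor], _one_tool(near, far))
        assert nodes[0].calls["toolA"].pos == 1010
        assert [c.pos for c in unassigned] == [1050]

    @pytest.mark.parametrize("seed", range(12))
    def test_matches_brute_force_oracle(self, seed):
        """Windowed clustering equals the all-pairs matcher."""
        from collections import Counter

        rng = np.random.default_rng(1_000 + seed)
        anchors, outputs = random_cluster_instance(rng)
        thr = ClusterThresholds()
        nodes, unassigned = cluster_calls(anchors, outputs, thr)
        expected_assigned, expected_unassigned = brute_force_cluster(anchors, outputs, thr)
        got = {
            idx: {
                tool: (call.pos, call.record.effective_length)
                for tool, call in node.calls.items()
            }
            for idx, node in enumerate(nodes)
            if node.calls
        }
        assert got == expected_assigned
        assert Counter((c.source, c.pos, c.effective_length) for c in unassigned) == expected_unassigned


class TestVariantGraph:
    def test_same_position_shares_a_branch(self):
        a = mk_snp(100, alt="T")
        b = mk_snp(100, alt="G")
        nodes, _ = cluster_calls([a, b], [])
        graph = build_variant_graph(nodes)
        assert graph.n_branches == 1 and len(graph) == 2

    def test_empty_graph(self):
        assert len(build_variant_graph([])) == 0

    def test_iteration_is_genomic_order(self):
        rng = np.random.default_rng(5)
        anchors = []
        for _ in range(100):
            chrom = f"chr{rng.integers(1, 4)}"
            anchors.append(mk_snp(int(rng.integers(1, 10_000)), chrom=chrom))
        nodes, _ = cluster_calls(anchors, [])
        keys = [node.branch_key for node in build_variant_graph(nodes)]
        assert keys == sorted(keys)


class TestDepthNormalization:
    def test_worked_example_matches_printed_equations(self):
        """depths [5, 10, 15]: mu = 10, sigma = sqrt(50/3), D' = +/-1.2247."""
        recs = [mk_snp(p * 100, dp=d) for p, d in zip((1, 2, 3), (5.0, 10.0, 15.0))]
        out = GenotyperOutput(tool="t", records=recs)
        stats = normalize_depths([out])["t"]
        assert stats.mu == pytest.approx(10.0)
        assert stats.sigma == pytest.approx(math.sqrt(50 / 3), abs=1e-12)
        dprimes = [r.normalized_depth for r in out.records]
        assert dprimes == pytest.approx([-1.2247, 0.0, 1.2247], abs=5e-5)

    def test_degenerate_spread_maps_to_zero(self):
        recs = [mk_snp(p, dp=7.0) for p in (100, 200, 300)]
        out = GenotyperOutput(tool="t", records=recs)
        stats = normalize_depths([out])["t"]
        assert stats.sigma == 0.0
        assert all(r.normalized_depth == 0.0 for r in out.records)

    def test_zscore_identity_random_depths(self):
        rng = np.random.default_rng(2)
        recs = [mk_snp(i * 10 + 1, dp=float(rng.integers(1, 80))) for i in range(500)]
        out = GenotyperOutput(tool="t", records=recs)
        normalize_depths([out])
        d = np.array([r.normalized_depth for r in out.records])
        assert abs(d.mean()) < 1e-9
        assert abs(d.std(ddof=0) - 1.0) < 1e-9

    def test_calls_without_dp_have_no_dprime(self):
        with_dp = mk_snp(100, dp=10.0)
        without = mk_snp(200)
        out = GenotyperOutput(tool="t", records=[with_dp, without])
        stats = normalize_depths([out])
        assert stats["t"].n == 1
        assert without.normalized_depth is None

    def test_tool_without_depths_gets_no_stats(self):
        out = GenotyperOutput(tool="t", records=[mk_snp(100)])
        assert normalize_depths([out]) == {}


def _node(anchor, calls):
    """calls: tool -> (genotype string, D')."""
    node = ClusterNode(anchor=anchor)
    for tool, (g, d) in calls.items():
        node.calls[tool] = ToolCall(
            tool=tool, genotype=gt(g), dp=None, gq=None,
            pos=anchor.pos, length=anchor.length, normalized_depth=d,
        )
    return node


class TestConsensus:
    def test_small_majority(self):
        node = _node(mk_snp(100), {"A": ("0/1", 0.1), "B": ("0/1", 0.2), "C": ("1/1", 0.0)})
        assert consensus_small(node) == gt("0/1")

    def test_small_single_support_is_skipped(self):
        node = _node(mk_snp(100), {"A": ("0/1", 0.1)})
        assert consensus_small(node) is None

    def test_small_unordered_identity_counts_as_support(self):
        node = _node(mk_snp(100), {"A": ("0/1", 0.1), "B": ("1/0", 0.2)})
        assert consensus_small(node) == gt("0/1")

    def test_sv_majority_beats_depth(self):
        node = _node(
            mk_sv(100, "DEL", 100),
            {"A": ("0/1", 0.9), "B": ("0/1", -0.1), "C": ("1/1", 0.0)},
        )
        assert consensus_sv(node) == gt("0/1")

    def test_sv_all_single_support_resolved_by_depth(self):
        node = _node(mk_sv(100, "DEL", 100), {"A": ("0/1", 0.5), "B": ("1/1", -0.2)})
        assert consensus_sv(node) == gt("1/1")

    def test_sv_empty_node_is_skipped(self):
        assert consensus_sv(_node(mk_sv(100, "DEL", 100), {})) is None

    def test_missing_genotypes_never_contribute(self):
        node = _node(mk_snp(100), {"A": ("./.", 0.0), "B": ("./.", 0.1), "C": ("0/1", 0.2)})
        assert consensus_small(node) is None

    def test_call_without_dprime_loses_depth_tiebreak(self):
        node = _node(mk_sv(100, "DEL", 100), {"A": ("0/1", None), "B": ("1/1", 2.5)})
        assert consensus_sv(node) == gt("1/1")

    @pytest.mark.parametrize("k", [2, 3, 4])
    def test_exhaustive_truth_table(self, k):
        """All genotype configurations for K tools match the voting rules."""
        genotypes = ["0/0", "0/1", "1/1", "./."]
        dprimes = [0.7, -0.4, 1.1, -0.05]
        snp_anchor = mk_snp(100)
        sv_anchor = mk_sv(100, "DEL", 100)
        for combo in itertools.product(genotypes, repeat=k):
            calls = {f"t{i}": (g, dprimes[i]) for i, g in enumerate(combo)}
            oracle_calls = {t: (gt(g), d) for t, (g, d) in calls.items()}
            assert consensus_small(_node(snp_anchor, calls)) == consensus_oracle(
                VarClass.SNP, oracle_calls
            )
            assert consensus_sv(_node(sv_anchor, calls)) == consensus_oracle(
                VarClass.SV, oracle_calls
            )
            # determinism under tool-order permutation
            rev = dict(reversed(list(calls.items())))
            assert consensus_sv(_node(sv_anchor, rev)) == consensus_sv(_node(sv_anchor, calls))


class TestMergeEndToEnd:
    def test_unanimous_tools_reproduce_input(self, small_truth):
        truth, _, _ = small_truth
        profiles = make_profiles(
            3, 42, fn_rate=0.0, genotype_error_rate=0.0,
            breakpoint_jitter_sd=0.0, length_jitter_sd=0.0,
        )
        outputs = simulate_outputs(truth, profiles)
        merged = merge_genotyper_outputs(truth, outputs)
        assert len(merged) == len(truth)
        for want, got in zip(truth, merged):
            assert (want.chrom, want.pos, want.ref, want.alt) == (got.chrom, got.pos, got.ref, got.alt)
            assert got.genotype == want.genotype
            assert got.info["SUPPORT"] == 3

    def test_single_tool_small_variants_are_skipped(self):
        anchors = [mk_snp(100), mk_sv(5_000, "DEL", 100)]
        calls = [mk_snp(100, dp=10.0), mk_sv(5_000, "DEL", 100, dp=20.0)]
        merged = merge_genotyper_outputs(anchors, _one_tool(*calls))
        assert [r.var_class for r in merged] == [VarClass.SV]

    def test_shifted_deletion_lands_at_anchor_coordinates(self):
        anchor = mk_sv(1000, "DEL", 100, genotype="./.")
        shifted = [
            GenotyperOutput(tool=t, records=[mk_sv(1080, "DEL", 100, genotype="0/1", dp=20.0)])
            for t in ("A", "B")
        ]
        merged = merge_genotyper_outputs([anchor], shifted)
        assert len(merged) == 1
        rec = merged[0]
        assert rec.pos == 1000 and rec.ref == anchor.ref
        assert rec.genotype == gt("0/1") and rec.info["SUPPORT"] == 2

    def test_merge_is_idempotent_for_svs(self, small_truth):
        truth, _, _ = small_truth
        profiles = make_profiles(3, 9, fn_rate=0.05, genotype_error_rate=0.05)
        merged = merge_genotyper_outputs(truth, simulate_outputs(truth, profiles))
        again = merge_genotyper_outputs(
            truth, [GenotyperOutput(tool="merged", records=[r.copy() for r in merged])]
        )
        sv_before = {(r.chrom, r.pos): r.genotype for r in merged if r.var_class is VarClass.SV}
        sv_after = {(r.chrom, r.pos): r.genotype for r in again if r.var_class is VarClass.SV}
        assert sv_after == sv_before
        assert all(r.var_class is VarClass.SV for r in again)  # small variants skip

    def test_strict_majority_dominates_depth(self):
        anchors = [mk_sv(1000, "DEL", 100, genotype="./.")]
        outputs = []
        for tool, g, dp in (("A", "0/1", 500.0), ("B", "0/1", 499.0), ("C", "1/1", 30.0)):
            outputs.append(
                GenotyperOutput(tool=tool, records=[mk_sv(1000, "DEL", 100, genotype=g, dp=dp)])
            )
        merged = merge_genotyper_outputs(anchors, outputs)
        assert merged[0].genotype == gt("0/1")

    @pytest.mark.parametrize("error_rate", [0.1, 0.3])
    def test_ensemble_gain_over_independent_errors(self, error_rate):
        """Majority voting over 3 independent tools beats each tool's
        genotype-error rate (binomial: 3e^2(1-e)+e^3 < e for e < 0.5)."""
        rng = np.random.default_rng(77)
        n = 1000
        truth = []
        pos = 100
        for i in range(n):
            pos += 300
            truth.append(mk_sv(pos, "DEL", 100, genotype="0/1" if i % 2 else "1/1"))
        profiles = make_profiles(
            3, 123, fn_rate=0.0, genotype_error_rate=error_rate,
            breakpoint_jitter_sd=0.0, length_jitter_sd=0.0,
        )
        outputs = simulate_outputs(truth, profiles)
        merged = merge_genotyper_outputs(truth, outputs)
        by_pos = {r.pos: r.genotype for r in merged}
        errors = sum(
            1 for t in truth if by_pos.get(t.pos) is None or by_pos[t.pos] != t.genotype
        )
        assert errors / n < error_rate
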