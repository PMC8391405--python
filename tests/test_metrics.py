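"""Unit tests for the rate / index / entropy / capacity metrics.

Frozen expected values were computed with the brute-force literal-sum
oracles in ``oracles.py`` before the implementation was written.
"""

import math

import numpy as np
import pytest

import oracles

from passnet import (
    SyntheticSpec,
    ValidationError,
    WeightedDigraph,
    capacity_in,
    capacity_index_in,
    capacity_index_out,
    capacity_out,
    full_report,
    generate,
    network_index_out,
    network_rate_in,
    network_rate_out,
    node_index_in,
    node_index_out,
    node_rate_in,
    node_rate_out,
    total_entropy_in,
    total_entropy_out,
)

UC4_RATE = 0.396240625180289  # log2(3)/4, node rate on the uniform complete 4-graph


class TestNodeRates:
    def test_uniform_complete_4_out(self, fixtures):
        G = fixtures["uniform_complete_4"]
        for i in range(4):
            assert node_rate_out(G, i) == pytest.approx(UC4_RATE, abs=1e-12)

    def test_uniform_complete_4_in_both_variants(self, fixtures):
        G = fixtures["uniform_complete_4"]
        for variant in ("literal", "conditional"):
            assert node_rate_in(G, 0, variant) == pytest.approx(UC4_RATE, abs=1e-12)

    def test_deterministic_row_has_zero_rate(self, fixtures):
        assert node_rate_out(fixtures["single_arc"], 0) == 0.0

    def test_zero_out_strength_node_has_zero_rate(self, fixtures):
        assert node_rate_out(fixtures["single_arc"], 1) == 0.0

    def test_two_cycle_literal_reception_is_zero(self, fixtures):
        assert node_rate_in(fixtures["two_cycle"], 0, "literal") == 0.0

    def test_reception_variants_against_frozen_oracle_values(self):
        G = WeightedDigraph(("1", "2", "3"), np.array([[0, 2, 1], [1, 0, 0], [0, 1, 0]], float))
        # frozen from oracles.rate_in_literal / rate_in_conditional
        assert node_rate_in(G, 1, "literal") == pytest.approx(0.23398500028846247, abs=1e-12)
        assert node_rate_in(G, 1, "conditional") == pytest.approx(0.5509775004326938, abs=1e-12)

    def test_index_is_rate_over_log2n(self, fixtures):
        G = fixtures["uniform_complete_4"]
        assert node_index_out(G, 0) == pytest.approx(UC4_RATE / 2, abs=1e-15)
        assert node_index_out(G, 2) * math.log2(G.n) == pytest.approx(
            node_rate_out(G, 2), abs=0
        )
        assert node_index_in(G, 1, "conditional") == pytest.approx(UC4_RATE / 2, abs=1e-12)

    def test_index_out_of_range(self, fixtures):
        with pytest.raises(ValidationError):
            node_rate_out(fixtures["two_cycle"], 2)
        with pytest.raises(ValidationError):
            node_rate_in(fixtures["two_cycle"], 0, "bogus")


class TestNetworkMetrics:
    def test_uniform_complete_closed_forms(self, fixtures):
        for n in (3, 4, 8, 16):
            G = fixtures[f"uniform_complete_{n}"]
            assert network_rate_out(G) == pytest.approx(math.log2(n - 1), abs=1e-12)
            assert network_index_out(G) == pytest.approx(
                math.log2(n - 1) / math.log2(n), abs=1e-12
            )
            assert total_entropy_out(G) == pytest.approx(math.log2(n), abs=1e-12)
            for variant in ("literal", "conditional"):
                assert capacity_out(G, variant) == pytest.approx(
                    math.log2(n) - math.log2(n - 1), abs=1e-12
                )

    def test_network_index_increases_with_n(self, fixtures):
        vals = [network_index_out(fixtures[f"uniform_complete_{n}"]) for n in (4, 8, 16)]
        assert vals == sorted(vals)
        assert vals[-1] < 1.0

    def test_two_cycle_degenerate_values(self, fixtures):
        G = fixtures["two_cycle"]
        assert network_rate_out(G) == 0.0
        assert total_entropy_out(G) == pytest.approx(1.0, abs=1e-15)
        assert capacity_out(G, "literal") == pytest.approx(1.0, abs=1e-15)
        assert capacity_index_out(G, "literal") == pytest.approx(1.0, abs=1e-15)

    def test_single_arc_all_zero(self, fixtures):
        G = fixtures["single_arc"]
        report = full_report(G)
        nw = report.network
        for k in ("RN_out", "RN_in", "EN_out", "EN_in", "CN_out", "CN_in",
                  "IndCN_out", "IndCN_in"):
            assert getattr(nw, k) == 0.0

    def test_star_out_entropies(self, fixtures):
        G = fixtures["star_out_5"]
        assert total_entropy_out(G) == 0.0  # single sender
        # leaves never send, so the transposed chain is deterministic
        assert network_rate_in(G, "conditional") == 0.0
        # literal reading sums column entries of M: four leaves at q=1/4, 0.5 each
        assert network_rate_in(G, "literal") == pytest.approx(0.5, abs=1e-12)
        assert total_entropy_in(G) == pytest.approx(2.0, abs=1e-12)

    def test_marginal_entropy_against_oracle(self):
        W = [[0, 3, 1], [2, 0, 2], [1, 1, 0]]
        G = WeightedDigraph(("1", "2", "3"), np.array(W, float))
        assert total_entropy_out(G) == pytest.approx(oracles.entropy_out(W), abs=1e-12)
        assert total_entropy_in(G) == pytest.approx(oracles.entropy_in(W), abs=1e-12)

    def test_capacity_identities_exact(self):
        G = generate(SyntheticSpec(n=11, total_passes=450, seed=3))
        for variant in ("literal", "conditional"):
            assert capacity_out(G, variant) == total_entropy_out(G) - network_rate_in(G, variant)
            assert capacity_in(G, variant) == total_entropy_in(G) - network_rate_out(G)
            assert capacity_index_out(G, variant) == abs(capacity_out(G, variant)) / math.log2(G.n)

    def test_conditional_capacity_is_mutual_information(self):
        G = generate(SyntheticSpec(n=9, total_passes=400, seed=11))
        mi = oracles.mutual_information(G.W.tolist())
        assert capacity_out(G, "conditional") == pytest.approx(mi, abs=1e-12)
        assert capacity_in(G, "conditional") == pytest.approx(mi, abs=1e-12)
        assert mi >= -1e-12


class TestFullReport:
    def test_internal_consistency(self):
        G = generate(SyntheticSpec(n=14, total_passes=500, seed=42))
        report = full_report(G, variant="literal")
        nw = report.network
        assert len(report.per_node) == G.n
        assert [nm.label for nm in report.per_node] == list(G.labels)
        assert nw.RN_out == sum(nm.R_out for nm in report.per_node)
        assert nw.RN_in == sum(nm.R_in for nm in report.per_node)
        assert nw.CN_out == nw.EN_out - nw.RN_in
        assert nw.CN_in == nw.EN_in - nw.RN_out
        assert nw.IndCN_out == abs(nw.CN_out) / math.log2(G.n)
        assert nw.L == G.total_weight
        assert report.meta["n"] == 14

    def test_scale_invariance_of_full_report(self):
        G = generate(SyntheticSpec(n=10, total_passes=350, seed=8))
        a = full_report(G, "literal")
        b = full_report(G.scaled(7.3), "literal")
        for na, nb in zip(a.per_node, b.per_node):
            assert na.R_out == pytest.approx(nb.R_out, abs=1e-12)
            assert na.R_in == pytest.approx(nb.R_in, abs=1e-12)
        assert a.network.CN_out == pytest.approx(b.network.CN_out, abs=1e-12)

    def test_literal_capacity_can_be_negative(self):
        # a dominant deterministic sender keeps EN_out small while the
        # minor senders' split rows drive the literal RN_in above it
        W = np.array([
            [0, 100, 0, 0, 0],
            [0, 0, 0, 0, 0],
            [0, 1, 0, 0, 1],
            [0, 1, 0, 0, 1],
            [0, 1, 1, 0, 0],
        ], float)
        G = WeightedDigraph(tuple("abcde"), W)
        assert capacity_out(G, "literal") < 0
        assert capacity_index_out(G, "literal") > 0
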