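"""Likelihood weighting and the exact enumeration oracle."""

import numpy as np
import pandas as pd
import pytest

from droughtbn import (
    Network,
    Query,
    WeightedSampleSet,
    exact_query,
    lw_estimate,
    lw_sample,
    lw_sample_batch,
    query_lw,
)

from conftest import brute_force_conditional, make_cpts


class TestLwSample:
    def test_no_evidence_weight_is_one(self, example_net, example_cpts):
        rng = np.random.default_rng(0)
        for _ in range(10):
            _, w = lw_sample(example_net, example_cpts, {}, rng)
            assert w == 1.0

    def test_evidence_factor_matches_parent_draw(self, example_net, example_cpts):
        # clamp B=1: the weight must be P(B=1|A) of the drawn A, i.e. 0.9 or 0.3
        rng = np.random.default_rng(1)
        seen = set()
        for _ in range(50):
            state, w = lw_sample(example_net, example_cpts, {"B": 1}, rng)
            expected = 0.9 if state["A"] == 1 else 0.3
            assert w == pytest.approx(expected)
            seen.add(state["A"])
        assert seen == {0, 1}

    def test_root_evidence_fixed_weight(self, example_net, example_cpts):
        rng = np.random.default_rng(2)
        for _ in range(10):
            _, w = lw_sample(example_net, example_cpts, {"A": 1}, rng)
            assert w == pytest.approx(0.6)  # theta_A regardless of other draws


class TestWorkedExample:
    """The five hand-weighted samples for the four-gene network, clamped B=1."""

    def test_printed_estimates(self, worked_samples_path):
        ss = WeightedSampleSet.from_csv(worked_samples_path, evidence={"B": 1})
        assert round(lw_estimate(ss, Query("D", 1)), 6) == 0.636364  # 2.1/3.3
        assert round(lw_estimate(ss, Query("D", 0)), 6) == 0.363636  # 1.2/3.3

    def test_evidence_column_constant(self, worked_samples_path):
        ss = WeightedSampleSet.from_csv(worked_samples_path, evidence={"B": 1})
        assert (ss.samples["B"] == 1).all()

    def test_csv_round_trip(self, worked_samples_path, tmp_path):
        ss = WeightedSampleSet.from_csv(worked_samples_path, evidence={"B": 1})
        ss.to_csv(tmp_path / "samples.csv")
        again = WeightedSampleSet.from_csv(tmp_path / "samples.csv", evidence={"B": 1})
        pd.testing.assert_frame_equal(ss.samples, again.samples)
        np.testing.assert_allclose(ss.weights, again.weights)


class TestLwEstimate:
    def test_all_match_gives_one(self):
        ss = WeightedSampleSet(
            samples=pd.DataFrame({"X": [1, 1, 1]}),
            weights=np.array([0.2, 0.2, 0.2]), evidence={})
        assert lw_estimate(ss, Query("X", 1)) == 1.0

    def test_complement_closure_exact(self, example_net, example_cpts):
        ss = lw_sample_batch(example_net, example_cpts, {"B": 1}, 500, 7)
        p1 = lw_estimate(ss, Query("D", 1))
        p0 = lw_estimate(ss, Query("D", 0))
        assert p1 + p0 == pytest.approx(1.0, abs=0)

    def test_query_on_evidence_node_rejected(self, example_net, example_cpts):
        ss = lw_sample_batch(example_net, example_cpts, {"B": 1}, 10, 0)
        with pytest.raises(ValueError, match="evidence"):
            lw_estimate(ss, Query("B", 1))


class TestQueryLw:
    def test_deterministic_given_seed(self, example_net, example_cpts):
        a = query_lw(example_net, example_cpts, Query("D", 1), {"B": 1}, M=5_000, seed=42)
        b = query_lw(example_net, example_cpts, Query("D", 1), {"B": 1}, M=5_000, seed=42)
        assert a.estimate == b.estimate and a.weight_sum == b.weight_sum

    def test_no_evidence_recovers_root_theta(self, example_net, example_cpts):
        res = query_lw(example_net, example_cpts, Query("A", 1), {}, M=100_000, seed=3)
        assert abs(res.estimate - 0.6) <= 3 * res.se

    def test_no_evidence_weights_all_one(self, example_net, example_cpts):
        ss = lw_sample_batch(example_net, example_cpts, {}, 1_000, 4)
        assert (ss.weights == 1.0).all()

    def test_matches_exact_within_three_se(self, example_net, example_cpts):
        exact = exact_query(example_net, example_cpts, Query("D", 1), {"B": 1})
        res = query_lw(example_net, example_cpts, Query("D", 1), {"B": 1},
                       M=100_000, seed=9)
        assert abs(res.estimate - exact) <= 3 * res.se

    def test_error_shrinks_with_m(self, example_net, example_cpts):
        exact = exact_query(example_net, example_cpts, Query("D", 1), {"A": 0})
        errs = []
        for M in (1_000, 100_000):
            res = query_lw(example_net, example_cpts, Query("D", 1), {"A": 0},
                           M=M, seed=13)
            errs.append(abs(res.estimate - exact))
        assert errs[1] < errs[0]


class TestExactQuery:
    def test_chain_closed_form(self):
        net = Network(nodes=("A", "B"), edges=(("A", "B"),))
        cpts = make_cpts(net, {"A": 0.6, "B": {(1,): 0.9, (0,): 0.2}})
        # total probability: 0.6*0.9 + 0.4*0.2
        assert exact_query(net, cpts, Query("B", 1), {}) == pytest.approx(0.62)

    def test_query_in_evidence_rejected(self, example_net, example_cpts):
        with pytest.raises(ValueError, match="evidence"):
            exact_query(example_net, example_cpts, Query("B", 1), {"B": 1})

    def test_sums_to_one_over_query_states(self, example_net, example_cpts):
        p1 = exact_query(example_net, example_cpts, Query("D", 1), {"C": 1})
        p0 = exact_query(example_net, example_cpts, Query("D", 0), {"C": 1})
        assert p1 + p0 == pytest.approx(1.0)

    @pytest.mark.parametrize("seed", range(4))
    def test_agrees_with_naive_brute_force(self, example_net, seed):
        # independent oracle: explicit joint table over all 2^N states
        rng = np.random.default_rng(seed)
        cpts = make_cpts(example_net, {
            "A": rng.uniform(0.1, 0.9),
            "B": {(0,): rng.uniform(0.1, 0.9), (1,): rng.uniform(0.1, 0.9)},
            "C": {(0,): rng.uniform(0.1, 0.9), (1,): rng.uniform(0.1, 0.9)},
            "D": {k: rng.uniform(0.1, 0.9)
                  for k in [(0, 0), (0, 1), (1, 0), (1, 1)]},
        })
        ours = exact_query(example_net, cpts, Query("D", 1), {"A": 1, "C": 0})
        naive = brute_force_conditional(example_net, cpts, "D", 1, {"A": 1, "C": 0})
        assert ours == pytest.approx(naive, abs=1e-12)

    def test_guard_on_large_networks(self, drought_net):
        from droughtbn import random_cpts
        cpts = random_cpts(drought_net, seed=0)
        with pytest.raises(ValueError, match="too large"):
            exact_query(drought_net, cpts, Query("RD29A", 1), {}, max_nodes=10)

    def test_pruning_drops_barren_nodes(self, drought_net):
        # ERD1's conditional ignores the MAP cascade entirely
        from droughtbn import random_cpts
        cpts = random_cpts(drought_net, seed=1)
        p = exact_query(drought_net, cpts, Query("ERD1", 1), {"MYC2": 1})
        assert 0.0 < p < 1.0
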