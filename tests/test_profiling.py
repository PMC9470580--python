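"""Tornado sensitivity, dynamic profiling, optimization tree, segment
profiles and target evaluation."""

import itertools

import numpy as np
import pandas as pd
import pytest

from glcmbayes import TreeBayesNet, TreeNetwork
from glcmbayes.bayesnet import fit_cpts, model_marginal, posterior
from glcmbayes.profiling import (bayes_factor, bayes_rule_posterior, best_two_group,
                                 classification_report, dynamic_profile,
                                 evaluate_target, generalized_bayes_factor,
                                 optimization_tree, segment_profile, tornado)

from conftest import random_tree_network


class TestTornado:
    def test_independent_node_has_zero_delta(self):
        cpts = {"t": np.array([[0.4, 0.6]]),
                "o": np.array([[0.5, 0.5], [0.5, 0.5]])}
        net = TreeNetwork(("t", "o"), {"t": ["0", "1"], "o": ["0", "1"]},
                          {"t": None, "o": "t"}, cpts=cpts)
        table = tornado(net, "t", 0)
        assert np.allclose(table["delta"], 0.0, atol=1e-12)

    def test_deterministic_copy_reaches_certainty(self):
        cpts = {"t": np.array([[0.5, 0.5]]),
                "o": np.array([[1.0, 0.0], [0.0, 1.0]])}
        net = TreeNetwork(("t", "o"), {"t": ["0", "1"], "o": ["0", "1"]},
                          {"t": None, "o": "t"}, cpts=cpts)
        table = tornado(net, "t", 0)
        assert table["posterior"].max() == pytest.approx(1.0)

    @pytest.mark.parametrize("seed", [71, 72])
    def test_entries_replay_through_posterior(self, seed):
        net = random_tree_network(seed, 4, concentration=2.0)
        target = net.nodes[0]
        table = tornado(net, target, 0)
        prior = model_marginal(net, target)[0]
        for _, row in table.iterrows():
            state = net.states[row["node"]].index(row["state"])
            direct = posterior(net, {row["node"]: state}, target)[0]
            assert row["posterior"] == pytest.approx(direct, abs=1e-12)
            assert row["delta"] == pytest.approx(direct - prior, abs=1e-12)
        assert (np.diff(table["delta"].abs()) <= 1e-12).all()


class TestDynamicProfile:
    def test_bayes_rule_helpers(self):
        # posterior from printed-style likelihood/prior/marginal percentages
        assert bayes_rule_posterior(81.81, 37.77, 31.71) == pytest.approx(97.45, abs=0.01)
        assert bayes_factor(53.03, 18.08) == pytest.approx(2.93, abs=0.005)
        assert generalized_bayes_factor(0.5, 0.5) == pytest.approx(1.0)
        assert generalized_bayes_factor(1.0, 0.5) == np.inf

    @pytest.mark.parametrize("seed", [80, 81, 82])
    def test_step_identities_and_monotonicity(self, seed):
        net = random_tree_network(seed, 5, concentration=2.0)
        target = net.nodes[0]
        steps = dynamic_profile(net, target, 0)
        prior = steps[0].posterior_prob
        assert steps[0].bayes_factor == pytest.approx(1.0)
        assert steps[0].marginal_likelihood == pytest.approx(1.0)
        posts = [s.posterior_prob for s in steps]
        assert all(b >= a - 1e-12 for a, b in zip(posts, posts[1:]))
        for s in steps[1:]:
            # Bayes rule: P(s|H) P(H) = P(H|s) P(s)
            assert s.posterior_prob * s.marginal_likelihood == pytest.approx(
                s.likelihood * prior, abs=1e-9)
            assert s.bayes_factor == pytest.approx(s.posterior_prob / prior, abs=1e-12)

    def test_greedy_first_step_is_exhaustive_best_single_evidence(self):
        net = random_tree_network(90, 2, concentration=2.0)
        target = net.nodes[0]
        other = net.nodes[1]
        steps = dynamic_profile(net, target, 0, max_steps=1)
        best = max(posterior(net, {other: s}, target)[0]
                   for s in range(net.n_states(other)))
        if len(steps) > 1:
            assert steps[1].posterior_prob == pytest.approx(best, abs=1e-12)
        else:
            assert best <= steps[0].posterior_prob + 1e-12

    def test_posterior_means_are_state_weighted_conditional_means(self, fitted_tree_study):
        spec, data, _ = fitted_tree_study
        from glcmbayes.discretize import DiscreteTable
        cont = data.astype(float) + 0.5
        states = data.copy()
        disc = DiscreteTable(
            states=states,
            labels={v: [str(s) for s in range(spec.n_states)] for v in spec.nodes},
            conditional_means={v: np.array([cont[v][data[v] == s].mean()
                                            for s in range(spec.n_states)])
                               for v in spec.nodes})
        results = TreeBayesNet(disc, target="X0").fit()
        steps = dynamic_profile(results.network, "X0", 0, discrete=disc, max_steps=2)
        last = steps[-1]
        for v, mean in last.means.items():
            if v in last.evidence:
                assert mean == pytest.approx(
                    disc.conditional_means[v][last.evidence[v]])
            else:
                ev = {k: s for k, s in last.evidence.items()}
                dist = posterior(results.network, ev, v)
                assert mean == pytest.approx(float(dist @ disc.conditional_means[v]),
                                             abs=1e-12)


class TestOptimizationTree:
    def test_zero_threshold_includes_prior_path(self):
        net = random_tree_network(91, 3)
        paths = optimization_tree(net, net.nodes[0], 0, threshold=0.0, max_depth=1)
        assert any(p.evidence == () for p in paths)

    def test_unreachable_threshold_gives_empty_set(self):
        net = random_tree_network(92, 3, concentration=5.0)
        paths = optimization_tree(net, net.nodes[0], 0, threshold=1.0, max_depth=2)
        assert paths == []

    def test_matches_exhaustive_enumeration_on_three_nodes(self):
        net = random_tree_network(93, 3, concentration=1.0)
        target = net.nodes[0]
        threshold = 0.5
        got = {(p.evidence, round(p.posterior_prob, 12))
               for p in optimization_tree(net, target, 0, threshold, max_depth=2)}
        expected = set()
        others = sorted(v for v in net.nodes if v != target)
        subsets = [()] + [(v,) for v in others] + [tuple(others)]
        for subset in subsets:
            for states in itertools.product(*[range(net.n_states(v)) for v in subset]):
                ev = dict(zip(subset, states))
                try:
                    post = posterior(net, ev, target)[0]
                except ValueError:
                    continue
                if post >= threshold:
                    expected.add((tuple(sorted(ev.items())), round(float(post), 12)))
        assert got == expected


class TestSegmentProfile:
    def test_shifted_state_flags_both_tests(self):
        rng = np.random.default_rng(20)
        n = 200
        states = np.repeat([0, 1], n // 2)
        x = rng.standard_normal(n)
        x[states == 1] += 5.0  # five pooled-sd separation
        feats = pd.DataFrame({"f": x})
        out = segment_profile(feats, states, ["s0", "s1"], seed=3, best_samples=4000)
        assert out["t_test_significant"].all()
        assert out["best_significant"].all()

    def test_identical_groups_stay_non_significant(self):
        rng = np.random.default_rng(21)
        x = rng.standard_normal(300)
        states = np.tile([0, 1], 150)   # interleaved: same distribution
        feats = pd.DataFrame({"f": x})
        out = segment_profile(feats, states, ["s0", "s1"], seed=4, best_samples=4000)
        assert not out["t_test_significant"].any()
        assert not out["best_significant"].any()

    def test_normalized_means_hit_endpoints(self):
        # state 0 carries the global minimum values, state 2 the maximum
        feats = pd.DataFrame({"f": [0.0, 0.0, 5.0, 5.0, 10.0, 10.0]})
        states = np.array([0, 0, 1, 1, 2, 2])
        out = segment_profile(feats, states, ["lo", "mid", "hi"], best_samples=500)
        by_state = out.set_index("state")["normalized_mean"]
        assert by_state["lo"] == pytest.approx(0.0)
        assert by_state["mid"] == pytest.approx(0.5)
        assert by_state["hi"] == pytest.approx(1.0)

    def test_tiny_state_skips_tests_with_flag(self):
        feats = pd.DataFrame({"f": [1.0, 2.0, 3.0, 9.0]})
        states = np.array([0, 0, 0, 1])
        with pytest.warns(UserWarning, match="<2 rows"):
            out = segment_profile(feats, states, ["a", "b"], best_samples=500)
        assert not out[out["state"] == "b"]["tested"].iloc[0]

    def test_best_sampler_is_deterministic_and_detects_shift(self):
        rng = np.random.default_rng(22)
        y1 = rng.standard_normal(80) + 2.0
        y2 = rng.standard_normal(80)
        a = best_two_group(y1, y2, seed=5, n_samples=6000)
        b = best_two_group(y1, y2, seed=5, n_samples=6000)
        assert a == b
        assert a["significant"]
        assert a["hdi"][0] > 0.5
        assert 0.05 < a["acceptance_rate"] < 0.9


class TestEvaluateTarget:
    def test_reliability_precision_from_constructed_counts(self):
        # 31 rows of the top state, 30 predicted correctly, 1 sent elsewhere
        actual = np.array([1] * 31 + [0] * 10)
        predicted = np.array([1] * 30 + [0] + [0] * 10)
        table = classification_report(actual, predicted, ["low", "high"])
        high = table.set_index("state").loc["high"]
        assert high["occurrence"] == 31
        assert high["reliability_pct"] == pytest.approx(100 * 30 / 31)
        assert high["precision_pct"] == pytest.approx(100.0)
        assert high["purity_pct"] == high["reliability_pct"]
        assert high["neighborhood"] == ["low"]

    def test_perfect_predictor_metrics(self):
        rng = np.random.default_rng(30)
        x = rng.integers(0, 3, 400)
        data = pd.DataFrame({"t": x, "c": x})
        cont = pd.DataFrame({"t": x.astype(float), "c": x.astype(float)})
        from glcmbayes.discretize import DiscreteTable
        disc = DiscreteTable(states=data,
                             labels={v: ["0", "1", "2"] for v in data},
                             conditional_means={v: np.array([0.0, 1.0, 2.0])
                                                for v in data})
        results = TreeBayesNet(disc, features=cont, target="t").fit(prior_count=0.0)
        report = evaluate_target(results, "t")
        assert np.allclose(report.per_state["reliability_pct"], 100.0)
        assert np.allclose(report.per_state["precision_pct"], 100.0)
        assert report.rmse == pytest.approx(0.0, abs=1e-12)
        assert report.r == pytest.approx(1.0)
        assert report.r2 == pytest.approx(report.r ** 2, abs=1e-9)

    def test_informative_network_beats_chance(self, fitted_tree_study):
        _, _, results = fitted_tree_study
        report = evaluate_target(results, "X0")
        assert report.per_state["reliability_pct"].mean() > 40.0
        assert report.r2 == pytest.approx(report.r ** 2, abs=1e-9)
        assert 0 < report.nrmse < 1
        assert (report.per_state["roc_index_pct"] > 60).all()
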