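"""Structure learning, CPT fitting, exact inference, MDL scoring."""

import itertools

import numpy as np
import pandas as pd
import pytest

from glcmbayes import (TreeBayesNet, TreeNetwork, evidence_probability, fit_cpts,
                       learn_chow_liu, mdl_score, mutual_information, posterior)
from glcmbayes.bayesnet import model_marginal, pair_joint, sample

from conftest import (oracle_evidence_probability, oracle_posterior,
                      random_tree_network)


class TestLearnChowLiu:
    def test_three_variable_chain_beats_all_other_trees(self):
        rng = np.random.default_rng(0)
        n = 5000
        a = rng.integers(0, 2, n)
        b = np.where(rng.random(n) < 0.9, a, 1 - a)
        c = np.where(rng.random(n) < 0.9, b, 1 - b)
        data = pd.DataFrame({"A": a, "B": b, "C": c})
        net = learn_chow_liu(data, root="A")
        edges = {frozenset(arc) for arc in net.arcs}
        assert edges == {frozenset({"A", "B"}), frozenset({"B", "C"})}
        # exhaustive check: the chosen tree carries the largest MI weight
        mis = {frozenset({u, v}): mutual_information(data[u], data[v])
               for u, v in itertools.combinations("ABC", 2)}
        weights = {}
        for pair in itertools.combinations(mis, 2):
            weights[pair] = mis[pair[0]] + mis[pair[1]]
        best = max(weights.values())
        assert sum(mis[e] for e in edges) == pytest.approx(best)

    def test_two_nodes_yield_single_arc_from_root(self):
        data = pd.DataFrame({"p": [0, 1, 0, 1], "q": [0, 1, 0, 0]})
        net = learn_chow_liu(data, root="q")
        assert net.arcs == [("q", "p")]

    def test_independent_nodes_have_small_mi(self):
        rng = np.random.default_rng(1)
        data = pd.DataFrame({f"v{i}": rng.integers(0, 2, 10_000) for i in range(4)})
        for u, v in itertools.combinations(data.columns, 2):
            assert mutual_information(data[u], data[v]) < 0.01

    def test_constant_columns_give_isolated_forest(self):
        data = pd.DataFrame({"a": [0] * 6, "b": [1] * 6, "c": [0] * 6})
        with pytest.warns(UserWarning, match="isolated"):
            net = learn_chow_liu(data)
        assert net.arcs == []

    def test_learning_is_deterministic(self):
        rng = np.random.default_rng(2)
        data = pd.DataFrame({f"v{i}": rng.integers(0, 3, 400) for i in range(5)})
        first = learn_chow_liu(data, root="v0")
        second = learn_chow_liu(data.copy(), root="v0")
        assert first.parent == second.parent

    def test_tree_weight_beats_random_spanning_trees(self):
        rng = np.random.default_rng(3)
        n = 2000
        cols = {}
        cols["a"] = rng.integers(0, 3, n)
        cols["b"] = np.where(rng.random(n) < 0.7, cols["a"], rng.integers(0, 3, n))
        cols["c"] = np.where(rng.random(n) < 0.6, cols["b"], rng.integers(0, 3, n))
        cols["d"] = np.where(rng.random(n) < 0.5, cols["a"], rng.integers(0, 3, n))
        cols["e"] = rng.integers(0, 3, n)
        data = pd.DataFrame(cols)
        mis = {frozenset({u, v}): mutual_information(data[u], data[v])
               for u, v in itertools.combinations(data.columns, 2)}
        net = learn_chow_liu(data, root="a")
        learned = sum(mis[frozenset(arc)] for arc in net.arcs)
        nodes = list(data.columns)
        for rep in range(100):
            perm = list(np.random.default_rng(rep).permutation(nodes))
            tree_weight = 0.0
            attach_rng = np.random.default_rng(1000 + rep)
            for i in range(1, len(perm)):
                j = int(attach_rng.integers(0, i))
                tree_weight += mis[frozenset({perm[i], perm[j]})]
            assert learned >= tree_weight - 1e-12


class TestFitCpts:
    def test_mle_without_prior(self):
        data = pd.DataFrame({"x": [0, 0, 0, 1]})
        net = TreeNetwork(("x",), {"x": ["0", "1"]}, {"x": None})
        fitted = fit_cpts(net, data, prior_count=0.0)
        assert np.allclose(fitted.cpts["x"], [[0.75, 0.25]])

    def test_unseen_parent_configuration_is_uniform_under_prior(self):
        data = pd.DataFrame({"p": [0, 0, 0], "c": [0, 1, 0]})
        net = TreeNetwork(("p", "c"), {"p": ["0", "1"], "c": ["0", "1"]},
                          {"p": None, "c": "p"})
        fitted = fit_cpts(net, data, prior_count=1.0)
        assert np.allclose(fitted.cpts["c"][1], [0.5, 0.5])

    def test_uniform_root_recovered_within_sampling_error(self):
        rng = np.random.default_rng(4)
        n = 4000
        data = pd.DataFrame({"r": rng.integers(0, 4, n)})
        net = TreeNetwork(("r",), {"r": list("0123")}, {"r": None})
        fitted = fit_cpts(net, data, prior_count=1.0)
        se = np.sqrt(0.25 * 0.75 / n)
        assert np.all(np.abs(fitted.cpts["r"][0] - 0.25) < 3 * se)


class TestInference:
    def test_empty_evidence_gives_marginal(self):
        net = random_tree_network(10, 4)
        post = posterior(net, {}, "n2")
        assert np.allclose(post, oracle_posterior(net, {}, "n2"), atol=1e-12)
        assert post.sum() == pytest.approx(1.0)

    def test_two_node_network_is_direct_bayes(self):
        cpt_root = np.array([[0.3, 0.7]])
        cpt_child = np.array([[0.9, 0.1], [0.2, 0.8]])
        net = TreeNetwork(("a", "b"), {"a": ["0", "1"], "b": ["0", "1"]},
                          {"a": None, "b": "a"},
                          cpts={"a": cpt_root, "b": cpt_child})
        # child given parent: the CPT row itself
        assert np.allclose(posterior(net, {"a": 1}, "b"), cpt_child[1])
        # parent given child: Bayes inversion
        joint0 = cpt_root[0] * cpt_child[:, 0]
        assert np.allclose(posterior(net, {"b": 0}, "a"), joint0 / joint0.sum())

    @pytest.mark.parametrize("seed", range(10))
    def test_posterior_matches_enumeration_on_random_trees(self, seed):
        rng = np.random.default_rng(seed)
        net = random_tree_network(rng, n_nodes=5)
        ev_nodes = rng.choice(net.nodes, size=2, replace=False)
        evidence = {v: int(rng.integers(0, net.n_states(v))) for v in ev_nodes}
        query = next(v for v in net.nodes if v not in evidence)
        if oracle_evidence_probability(net, evidence) == 0:
            return
        assert np.allclose(posterior(net, evidence, query),
                           oracle_posterior(net, evidence, query), atol=1e-10)

    def test_evidence_probability_examples(self):
        net = random_tree_network(21, 5)
        assert evidence_probability(net, {}) == pytest.approx(1.0)
        full = {v: 0 for v in net.nodes}
        expected = 1.0
        for v in net.nodes:
            par = net.parent.get(v)
            row = 0 if par is None else full[par]
            expected *= net.cpts[v][row, 0]
        assert evidence_probability(net, full) == pytest.approx(expected, abs=1e-12)
        partial = {net.nodes[1]: 0, net.nodes[3]: 0}
        assert evidence_probability(net, partial) == pytest.approx(
            oracle_evidence_probability(net, partial), abs=1e-12)

    def test_contradictory_evidence_raises_with_context(self):
        cpts = {"a": np.array([[1.0, 0.0]]),
                "b": np.array([[1.0, 0.0], [0.0, 1.0]])}
        net = TreeNetwork(("a", "b"), {"a": ["0", "1"], "b": ["0", "1"]},
                          {"a": None, "b": "a"}, cpts=cpts)
        with pytest.raises(ValueError, match="zero probability"):
            posterior(net, {"b": 1}, "a")

    def test_query_in_evidence_rejected(self):
        net = random_tree_network(0, 3)
        with pytest.raises(ValueError):
            posterior(net, {"n0": 0}, "n0")


class TestMdl:
    def test_single_node_hand_arithmetic(self):
        data = pd.DataFrame({"x": [0, 1, 0, 1]})
        net = TreeNetwork(("x",), {"x": ["0", "1"]}, {"x": None})
        fitted = fit_cpts(net, data, prior_count=1.0)
        score = mdl_score(fitted, data)
        assert score.data_bits == pytest.approx(4.0)
        assert score.structure_bits == pytest.approx(1.0)
        assert score.total == pytest.approx(5.0)

    def test_arc_wins_for_dependent_pair(self):
        rng = np.random.default_rng(5)
        n = 1000
        a = rng.integers(0, 2, n)
        b = np.where(rng.random(n) < 0.95, a, 1 - a)
        data = pd.DataFrame({"a": a, "b": b})
        with_arc = fit_cpts(TreeNetwork(("a", "b"), {"a": ["0", "1"], "b": ["0", "1"]},
                                        {"a": None, "b": "a"}), data)
        without = fit_cpts(TreeNetwork(("a", "b"), {"a": ["0", "1"], "b": ["0", "1"]},
                                       {"a": None, "b": None}), data)
        assert mdl_score(with_arc, data).total < mdl_score(without, data).total

    def test_empty_structure_wins_for_independent_pair(self):
        rng = np.random.default_rng(6)
        n = 5000
        data = pd.DataFrame({"a": rng.integers(0, 2, n), "b": rng.integers(0, 2, n)})
        with_arc = fit_cpts(TreeNetwork(("a", "b"), {"a": ["0", "1"], "b": ["0", "1"]},
                                        {"a": None, "b": "a"}), data)
        without = fit_cpts(TreeNetwork(("a", "b"), {"a": ["0", "1"], "b": ["0", "1"]},
                                       {"a": None, "b": None}), data)
        assert mdl_score(without, data).total < mdl_score(with_arc, data).total


class TestModelResults:
    def test_fit_returns_consistent_results(self, fitted_tree_study):
        spec, data, results = fitted_tree_study
        assert set(results.network.nodes) == set(spec.nodes)
        recovered = {frozenset(arc) for arc in results.network.arcs}
        assert recovered == {frozenset(e) for e in spec.edges}
        # every CPT row normalised
        for cpt in results.network.cpts.values():
            assert np.allclose(cpt.sum(axis=1), 1.0)
        marg = results.marginal("X0")
        assert marg.sum() == pytest.approx(1.0)
        assert "Arc strengths" in results.summary()

    def test_pair_joint_matches_enumeration(self):
        net = random_tree_network(33, 4)
        pj = pair_joint(net, "n1", "n3")
        for i in range(net.n_states("n1")):
            for j in range(net.n_states("n3")):
                assert pj[i, j] == pytest.approx(
                    oracle_evidence_probability(net, {"n1": i, "n3": j}), abs=1e-12)

    def test_sampling_recovers_marginals(self):
        net = random_tree_network(12, 4, concentration=5.0)
        draws = sample(net, 20_000, rng=1)
        for v in net.nodes:
            freq = np.bincount(draws[v], minlength=net.n_states(v)) / len(draws)
            assert np.allclose(freq, model_marginal(net, v), atol=0.02)
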