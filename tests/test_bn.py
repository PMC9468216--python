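import itertools

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from mmdbn.bn import (
    CPT,
    AcyclicityError,
    BayesianNetwork,
    EstimationError,
    InferenceError,
    fit_mle,
    topological_order,
)
from mmdbn.simulate import dataset_from_table1

from .conftest import brute_posterior


def _dag(edges, nodes=()):
    g = nx.DiGraph()
    g.add_nodes_from(nodes)
    g.add_edges_from(edges)
    return g


def two_coin_network():
    return BayesianNetwork(
        [
            CPT("A", (), np.array([0.5, 0.5])),
            CPT("B", (), np.array([0.5, 0.5])),
        ],
        {"A": (0, 1), "B": (0, 1)},
    )


def chain_ab(p_a1=0.6, p_b1_a1=0.5, p_b1_a0=0.5):
    return BayesianNetwork(
        [
            CPT("A", (), np.array([1 - p_a1, p_a1])),
            CPT("B", ("A",), np.array([[1 - p_b1_a0, p_b1_a0], [1 - p_b1_a1, p_b1_a1]])),
        ],
        {"A": (0, 1), "B": (0, 1)},
    )


class TestTopologicalOrder:
    def test_parents_precede_children(self):
        assert topological_order(_dag([("A", "B"), ("B", "C")])) == ["A", "B", "C"]

    def test_lexicographic_tie_break(self):
        assert topological_order(_dag([], nodes=["B", "A"])) == ["A", "B"]

    def test_cycle_is_named(self):
        with pytest.raises(AcyclicityError, match="A"):
            topological_order(_dag([("A", "B"), ("B", "A")]))


class TestInvariants:
    def test_cpt_rows_must_normalize(self):
        with pytest.raises(ValueError, match="sum to 1"):
            CPT("X", (), np.array([0.5, 0.6]))

    def test_cpt_shape_must_match_declared_states(self):
        with pytest.raises(ValueError, match="shape"):
            BayesianNetwork(
                [
                    # 3 parent rows although B has only 2 states
                    CPT("A", ("B",), np.array([[0.5, 0.5]] * 3)),
                    CPT("B", (), np.array([0.5, 0.5])),
                ],
                {"A": (0, 1), "B": (0, 1)},
            )

    def test_states_and_cpts_must_cover_same_nodes(self):
        with pytest.raises(ValueError, match="same node set"):
            BayesianNetwork(
                [CPT("A", (), np.array([0.5, 0.5]))], {"A": (0, 1), "B": (0, 1)}
            )

    def test_joint_mass_is_one(self, benchmarks, study_network):
        for bn in [*benchmarks.values(), study_network]:
            assert bn.enumerate_joint().values.sum() == pytest.approx(1.0, abs=1e-9)


class TestJointProbability:
    def test_independent_fair_coins(self):
        bn = two_coin_network()
        for a, b in itertools.product((0, 1), repeat=2):
            assert bn.joint_probability({"A": a, "B": b}) == pytest.approx(0.25)

    def test_chain_product(self):
        bn = chain_ab(p_a1=0.6, p_b1_a1=0.5)
        assert bn.joint_probability({"A": 1, "B": 1}) == pytest.approx(0.30)

    def test_partial_assignment_rejected(self):
        with pytest.raises(ValueError, match="cover all nodes"):
            two_coin_network().joint_probability({"A": 1})

    def test_matches_enumerated_cell_on_study_network(self, study_network):
        joint = study_network.enumerate_joint()
        assignment = {n: study_network.states[n][0] for n in study_network.nodes}
        assert study_network.joint_probability(assignment) == pytest.approx(
            float(joint.values[(0,) * len(joint.scope)]), rel=1e-12
        )


class TestEnumerateJoint:
    def test_single_binary_node(self):
        bn = BayesianNetwork([CPT("A", (), np.array([0.4, 0.6]))], {"A": (0, 1)})
        assert np.allclose(bn.enumerate_joint().values, [0.4, 0.6])

    def test_cap_refusal_reports_size(self, benchmarks):
        with pytest.raises(InferenceError, match="exceeds"):
            benchmarks["sprinkler"].enumerate_joint(cap=10)


class TestEliminateQuery:
    def test_empty_evidence_is_the_prior(self, benchmarks):
        bn = benchmarks["chain"]
        post = bn.eliminate_query("C")
        assert np.allclose(post.probabilities, brute_posterior(bn, "C", {}))

    def test_bayes_rule_by_hand(self):
        bn = chain_ab(p_a1=0.5, p_b1_a1=0.9, p_b1_a0=0.1)
        # P(A=1|B=1) = 0.5*0.9 / (0.5*0.9 + 0.5*0.1) = 0.9
        assert bn.eliminate_query("A", {"B": 1})[1] == pytest.approx(0.9)

    def test_zero_probability_evidence_raises(self):
        bn = chain_ab(p_a1=1.0)
        with pytest.raises(InferenceError, match="zero probability"):
            bn.eliminate_query("B", {"A": 0})

    def test_target_in_evidence_rejected(self, benchmarks):
        with pytest.raises(ValueError):
            benchmarks["chain"].eliminate_query("A", {"A": 0})

    @pytest.mark.parametrize("name", ["chain", "fork", "collider", "sprinkler"])
    def test_matches_enumeration_oracle_everywhere(self, benchmarks, name):
        bn = benchmarks[name]
        nodes = bn.nodes
        for target in nodes:
            others = [n for n in nodes if n != target]
            for r in range(len(others) + 1):
                for ev_nodes in itertools.combinations(others, r):
                    for codes in itertools.product(*[bn.states[n] for n in ev_nodes]):
                        ev = dict(zip(ev_nodes, codes))
                        try:
                            post = bn.eliminate_query(target, ev)
                        except InferenceError:
                            continue  # zero-mass evidence
                        oracle = brute_posterior(bn, target, ev)
                        assert np.max(np.abs(post.probabilities - oracle)) < 1e-10

    def test_d_separated_evidence_leaves_posterior_unchanged(self, benchmarks):
        # in A -> C <- B, B is d-separated from A given no evidence on C
        bn = benchmarks["collider"]
        base = bn.eliminate_query("A")
        with_b = bn.eliminate_query("A", {"B": 1})
        assert np.allclose(base.probabilities, with_b.probabilities, atol=1e-12)
        # conditioning on the collider C opens the path
        opened = bn.eliminate_query("A", {"B": 1, "C": 1})
        assert not np.allclose(base.probabilities, opened.probabilities, atol=1e-3)


class TestPriorMarginals:
    def test_parentless_node_marginal_equals_cpt_row(self, benchmarks):
        bn = benchmarks["collider"]
        marg = bn.prior_marginals()
        assert np.allclose(marg["A"].probabilities, bn.cpts["A"].table)

    def test_degenerate_node_gives_point_mass(self):
        bn = BayesianNetwork(
            [
                CPT("A", (), np.array([0.0, 1.0])),
                CPT("B", ("A",), np.array([[1.0, 0.0], [0.0, 1.0]])),
            ],
            {"A": (0, 1), "B": (0, 1)},
        )
        assert np.allclose(bn.prior_marginals()["B"].probabilities, [0.0, 1.0])

    def test_every_marginal_normalizes(self, study_network):
        for post in study_network.prior_marginals().values():
            assert post.probabilities.sum() == pytest.approx(1.0, abs=1e-9)


class TestFitMLE:
    def test_counting_example_one_binary_parent(self):
        data = pd.DataFrame({"A": [1, 1, 1, 1, 0, 0], "B": [1, 1, 1, 0, 0, 0]})
        bn = fit_mle(_dag([("A", "B")]), data)
        assert np.allclose(bn.cpts["B"].table[1], [0.25, 0.75])

    def test_laplace_fills_unseen_rows_uniformly(self):
        data = pd.DataFrame({"A": [0, 0], "B": [0, 1]})
        bn = fit_mle(
            _dag([("A", "B")]), data, states={"A": (0, 1), "B": (0, 1)}, pseudo_count=1
        )
        assert np.allclose(bn.cpts["B"].table[1], [0.5, 0.5])

    def test_unseen_rows_uniform_under_pure_mle(self):
        data = pd.DataFrame({"A": [0, 0, 0], "B": [0, 1, 0]})
        bn = fit_mle(_dag([("A", "B")]), data, states={"A": (0, 1), "B": (0, 1)})
        assert np.allclose(bn.cpts["B"].table[1], [0.5, 0.5])

    def test_empty_and_incomplete_data_rejected(self):
        with pytest.raises(EstimationError):
            fit_mle(_dag([], nodes=["A"]), pd.DataFrame({"A": []}))
        with pytest.raises(EstimationError):
            fit_mle(_dag([], nodes=["A"]), pd.DataFrame({"A": [0, np.nan]}))

    def test_parentless_mmd_prior_from_published_counts(self):
        # 10,623 of 19,752 subjects carry two or more conditions
        data = dataset_from_table1()
        g = nx.DiGraph()
        g.add_nodes_from(data.columns)
        bn = fit_mle(g, data)
        assert bn.cpts["mmd"].table[1] == pytest.approx(0.538, abs=5e-4)

    def test_recovers_cpts_from_samples(self, benchmarks):
        from mmdbn.simulate import ancestral_sample

        truth = benchmarks["sprinkler"]
        data = ancestral_sample(truth, 100_000, seed=3)
        fitted = fit_mle(truth.dag, data, states=truth.states)
        for node in truth.nodes:
            assert np.max(np.abs(fitted.cpts[node].table - truth.cpts[node].table)) < 0.01
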