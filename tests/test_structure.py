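import itertools

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from mmdbn.simulate import ancestral_sample
from mmdbn.structure import (
    CPDAG,
    bic_score,
    cpdag,
    hill_climb,
    max_min_heuristic,
    mmhc,
    mmpc,
    shd,
    skeleton_f1,
    Skeleton,
    trace_to_frame,
)


def _dag(edges, nodes=()):
    g = nx.DiGraph()
    g.add_nodes_from(nodes)
    g.add_edges_from(edges)
    return g


def independent_frame(rng, n=5000, cols=4):
    return pd.DataFrame({f"v{i}": rng.integers(0, 2, n) for i in range(cols)})


class TestMaxMinHeuristic:
    def test_chain_prefers_the_direct_neighbour(self, benchmarks):
        data = ancestral_sample(benchmarks["chain"], 10_000, seed=1)
        best, p = max_min_heuristic(data, "C", cpc=[], candidates=["A", "B"])
        assert best == "B"
        assert p < 0.05

    def test_single_candidate_is_returned(self, benchmarks):
        data = ancestral_sample(benchmarks["chain"], 2_000, seed=1)
        best, _ = max_min_heuristic(data, "C", cpc=[], candidates=["A"])
        assert best == "A"

    def test_empty_candidate_set_gives_sentinel(self, benchmarks):
        data = ancestral_sample(benchmarks["chain"], 500, seed=1)
        best, p = max_min_heuristic(data, "C", cpc=[], candidates=[])
        assert best is None and p == 1.0

    def test_independent_candidates_exceed_alpha(self, rng):
        data = independent_frame(rng)
        _, p = max_min_heuristic(data, "v0", cpc=[], candidates=["v1", "v2", "v3"])
        assert p > 0.05

    def test_candidate_overlap_rejected(self, benchmarks):
        data = ancestral_sample(benchmarks["chain"], 500, seed=1)
        with pytest.raises(ValueError):
            max_min_heuristic(data, "C", cpc=["A"], candidates=["A", "B"])


class TestMMPC:
    def test_independent_columns_give_empty_adjacency(self, rng):
        skel = mmpc(independent_frame(rng))
        assert skel.edges == set()

    def test_collider_adjacency_exact(self, benchmarks):
        data = ancestral_sample(benchmarks["collider"], 20_000, seed=2)
        skel = mmpc(data)
        assert skel.edges == {frozenset("AC"), frozenset("BC")}

    def test_fork_conditioning_removes_spouse_link(self, benchmarks):
        data = ancestral_sample(benchmarks["fork"], 20_000, seed=2)
        skel = mmpc(data)
        assert skel.edges == {frozenset("CA"), frozenset("CB")}

    def test_adjacency_is_symmetric(self, study_sample_20k):
        skel = mmpc(study_sample_20k)
        for edge in skel.edges:
            u, v = tuple(edge)
            assert u in skel.cpc[v] and v in skel.cpc[u]

    def test_incomplete_or_noncategorical_data_rejected(self, rng):
        df = independent_frame(rng, n=100)
        with pytest.raises(ValueError):
            mmpc(df.astype(float))
        df2 = df.copy().astype("Int64")
        df2.iloc[0, 0] = pd.NA
        with pytest.raises(ValueError):
            mmpc(df2)
        with pytest.raises(ValueError):
            mmpc(df, alpha=1.5)


class TestBICScore:
    def test_closed_form_single_binary_column(self):
        # counts (5,5), n=10: 10 ln 0.5 - (ln 10)/2 = -8.08
        data = pd.DataFrame({"A": [0] * 5 + [1] * 5})
        score = bic_score(_dag([], nodes=["A"]), data)
        assert score == pytest.approx(10 * np.log(0.5) - np.log(10) / 2, rel=1e-12)
        assert score == pytest.approx(-8.08, abs=5e-3)

    def test_edge_from_independent_column_lowers_score(self, rng):
        data = independent_frame(rng, n=5000, cols=2)
        empty = bic_score(_dag([], nodes=["v0", "v1"]), data)
        with_edge = bic_score(_dag([("v0", "v1")]), data)
        assert with_edge < empty

    def test_edge_from_dependent_column_raises_score(self, benchmarks):
        data = ancestral_sample(benchmarks["chain"], 5000, seed=4)
        empty = bic_score(_dag([], nodes=["A", "B", "C"]), data)
        with_edge = bic_score(_dag([("A", "B")], nodes=["C"]), data)
        assert with_edge > empty

    def test_decomposes_over_families(self, benchmarks):
        data = ancestral_sample(benchmarks["sprinkler"], 2000, seed=5)
        dag = benchmarks["sprinkler"].dag
        total = bic_score(dag, data)
        # decomposability: stripping one node's in-edges changes the total by
        # exactly that node's family-score delta
        for node in dag.nodes:
            stripped = dag.copy()
            stripped.remove_edges_from(list(dag.in_edges(node)))
            delta = total - bic_score(stripped, data)
            fam_full = bic_score(
                _dag([(p, node) for p in dag.predecessors(node)], nodes=[node]),
                data[[*dag.predecessors(node), node]],
            )
            fam_empty = bic_score(_dag([], nodes=[node]), data[[node]])
            # parent families contribute identically in both graphs
            assert delta == pytest.approx(
                fam_full
                - fam_empty
                - sum(
                    bic_score(_dag([], nodes=[p]), data[[p]])
                    for p in dag.predecessors(node)
                ),
                abs=1e-8,
            )


class TestHillClimb:
    def test_empty_skeleton_yields_empty_dag(self, rng):
        data = independent_frame(rng, n=500, cols=3)
        skel = Skeleton(nodes=tuple(data.columns), edges=set())
        dag, trace = hill_climb(data, skel)
        assert dag.number_of_edges() == 0 and trace == []

    def test_single_dependent_pair_gets_one_edge(self, rng):
        a = rng.integers(0, 2, 10_000)
        b = np.where(rng.random(10_000) < 0.9, a, 1 - a)
        data = pd.DataFrame({"A": a, "B": b})
        skel = Skeleton(nodes=("A", "B"), edges={frozenset("AB")})
        dag, _ = hill_climb(data, skel)
        assert dag.number_of_edges() == 1
        # verify against exhaustive scoring of the three candidate graphs
        scores = {
            "empty": bic_score(_dag([], nodes=["A", "B"]), data),
            "a->b": bic_score(_dag([("A", "B")]), data),
            "b->a": bic_score(_dag([("B", "A")]), data),
        }
        assert bic_score(dag, data) == pytest.approx(max(scores.values()))

    def test_moves_improve_and_respect_skeleton(self, study_sample_20k):
        skel = mmpc(study_sample_20k)
        dag, trace = hill_climb(study_sample_20k, skel)
        assert all(m.delta > 0 for m in trace)
        assert nx.is_directed_acyclic_graph(dag)
        for u, v in dag.edges:
            assert skel.adjacent(u, v)
        empty = _dag([], nodes=list(study_sample_20k.columns))
        assert bic_score(dag, study_sample_20k) >= bic_score(empty, study_sample_20k)

    def test_trace_frame_layout(self, benchmarks):
        data = ancestral_sample(benchmarks["chain"], 5000, seed=6)
        dag, trace = mmhc(data)[0], mmhc(data)[2]
        frame = trace_to_frame(trace)
        assert list(frame.columns) == ["iteration", "operator", "edge", "delta"]
        assert len(frame) == len(trace)


class TestMMHC:
    def test_chain_equivalence_class_recovered(self, benchmarks):
        data = ancestral_sample(benchmarks["chain"], 20_000, seed=7)
        dag, skel, _ = mmhc(data)
        assert skel.edges == {frozenset("AB"), frozenset("BC")}
        assert cpdag(dag) == cpdag(benchmarks["chain"].dag)

    def test_node_count_matches_columns(self, study_sample_20k):
        dag, _, _ = mmhc(study_sample_20k)
        assert set(dag.nodes) == set(study_sample_20k.columns)
        assert len(dag.nodes) == 11

    def test_deterministic_across_runs(self, benchmarks):
        data = ancestral_sample(benchmarks["sprinkler"], 5000, seed=8)
        first = mmhc(data)
        second = mmhc(data)
        assert set(first[0].edges) == set(second[0].edges)
        assert first[1].edges == second[1].edges


class TestCPDAG:
    def test_chain_is_fully_undirected(self):
        pat = cpdag(_dag([("A", "B"), ("B", "C")]))
        assert pat.directed == frozenset()
        assert pat.undirected == {frozenset("AB"), frozenset("BC")}

    def test_collider_stays_directed(self):
        pat = cpdag(_dag([("A", "C"), ("B", "C")]))
        assert pat.directed == {("A", "C"), ("B", "C")}
        assert pat.undirected == frozenset()

    def test_single_edge_undirected(self):
        pat = cpdag(_dag([("A", "B")]))
        assert pat.undirected == {frozenset("AB")}

    def test_meek_rule_propagates_orientation(self):
        # A -> C <- B plus C - D: R1 orients C -> D (else a new v-structure)
        pat = cpdag(_dag([("A", "C"), ("B", "C"), ("C", "D")]))
        assert ("C", "D") in pat.directed

    def test_markov_equivalence_iff_equal_patterns(self):
        chain1 = _dag([("A", "B"), ("B", "C")])
        chain2 = _dag([("C", "B"), ("B", "A")])  # same class
        collider = _dag([("A", "B"), ("C", "B")])
        assert cpdag(chain1) == cpdag(chain2)
        assert cpdag(chain1) != cpdag(collider)


class TestSHD:
    def test_identical_graphs_distance_zero(self):
        g = _dag([("A", "B"), ("B", "C")])
        assert shd(g, g.copy()) == 0

    def test_one_extra_edge_costs_one(self):
        g = _dag([("A", "B")], nodes=["C"])
        h = _dag([("A", "B"), ("B", "C")])
        assert shd(g, h) == 1

    def test_flipped_edge_costs_one(self):
        assert shd(_dag([("A", "B")]), _dag([("B", "A")])) == 1

    def test_cpdag_comparison(self):
        assert shd(cpdag(_dag([("A", "B")])), cpdag(_dag([("B", "A")]))) == 0

    def test_node_mismatch_rejected(self):
        with pytest.raises(ValueError):
            shd(_dag([], nodes=["A"]), _dag([], nodes=["B"]))


class TestSkeletonF1:
    def test_perfect_recovery_is_one(self, benchmarks):
        dag = benchmarks["sprinkler"].dag
        skel = Skeleton(
            nodes=tuple(dag.nodes), edges={frozenset(e) for e in dag.edges}
        )
        assert skeleton_f1(skel, dag) == 1.0

    def test_no_overlap_is_zero(self):
        truth = _dag([("A", "B")], nodes=["C"])
        skel = Skeleton(nodes=("A", "B", "C"), edges={frozenset("BC")})
        assert skeleton_f1(skel, truth) == 0.0
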