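"""G² testing, PC structure learning, CPDAG conversion and DAG extension."""

import itertools

import networkx as nx
import numpy as np
import pytest

from causalbn import (
    BayesianNetwork,
    ConstraintSet,
    SurveyTable,
    VariableSchema,
    cpdag_of_dag,
    dag_extension,
    demographics_prior,
    forward_sample,
    g2_test,
    pc_learn,
)
from causalbn.pc import CPDAG

from conftest import make_schemas, make_table


class TestG2:
    def test_perfect_dependence_rejects(self):
        x = np.tile([0, 1], 50)
        t = make_table(np.column_stack([x, x]), names=["X", "Y"], levels=("a", "b"))
        res = g2_test(t, "X", "Y")
        assert res.p_value < 1e-6
        assert res.statistic > 0 and res.df == 1

    def test_conditional_independence_given_common_cause(self):
        rng = np.random.default_rng(0)
        z = rng.integers(0, 2, 5000)
        y = z.copy()  # deterministic copy of the conditioning variable
        x = rng.integers(0, 2, 5000)
        t = make_table(np.column_stack([x, y, z]), names=["X", "Y", "Z"], levels=("a", "b"))
        res = g2_test(t, "X", "Y", ["Z"])
        assert res.p_value > 0.05
        assert res.cond == ("Z",)

    def test_constant_variable_is_independent(self):
        t = make_table(
            np.column_stack([np.zeros(50, int), np.tile([0, 1], 25)]),
            names=["X", "Y"],
            levels=("a", "b"),
        )
        assert g2_test(t, "X", "Y").p_value == 1.0

    def test_weight_scale_invariance(self):
        rng = np.random.default_rng(5)
        codes = rng.integers(0, 2, size=(400, 2))
        w = rng.random(400) + 0.5
        t1 = make_table(codes, names=["X", "Y"], levels=("a", "b"), weights=w)
        t2 = make_table(codes, names=["X", "Y"], levels=("a", "b"), weights=w * 7.0)
        r1, r2 = g2_test(t1, "X", "Y"), g2_test(t2, "X", "Y")
        assert r1.statistic == pytest.approx(r2.statistic, rel=1e-12)
        assert r1.n_eff == pytest.approx(r2.n_eff, rel=1e-12)

    def test_type_one_error_calibrated(self):
        rng = np.random.default_rng(100)
        sch = make_schemas(["X", "Y"], levels=("a", "b"))
        rej = 0
        reps = 200
        for _ in range(reps):
            t = SurveyTable(sch, rng.integers(0, 2, size=(2000, 2)))
            rej += g2_test(t, "X", "Y").p_value < 0.05
        assert 0.02 <= rej / reps <= 0.08

    def test_rejects_overlapping_roles(self):
        t = make_table(np.zeros((5, 2), int), names=["X", "Y"])
        with pytest.raises(ValueError):
            g2_test(t, "X", "X")
        with pytest.raises(ValueError):
            g2_test(t, "X", "Y", ["Y"])


def _collider_bn(strength=2.0):
    sch = make_schemas(["A", "B", "C"], levels=("a", "b"))
    g = nx.DiGraph([("A", "C"), ("B", "C")])
    t = np.array([-0.5, 0.5])
    cpt = np.zeros((2, 2, 2))
    for i, j in itertools.product(range(2), repeat=2):
        logits = strength * (t[i] + t[j]) * t
        e = np.exp(logits)
        cpt[i, j] = e / e.sum()
    return BayesianNetwork(g, sch, {"A": np.full(2, 0.5), "B": np.full(2, 0.5), "C": cpt})


class TestPCLearn:
    def test_recovers_collider(self):
        t = forward_sample(_collider_bn(), 20_000, seed=3)
        cp = pc_learn(t)
        assert ("A", "C") in cp.directed and ("B", "C") in cp.directed
        assert not cp.undirected

    def test_chain_stays_undirected(self):
        sch = make_schemas(["A", "B", "C"], levels=("a", "b"))
        g = nx.DiGraph([("A", "B"), ("B", "C")])
        cpts = {
            "A": np.array([0.5, 0.5]),
            "B": np.array([[0.85, 0.15], [0.15, 0.85]]),
            "C": np.array([[0.8, 0.2], [0.2, 0.8]]),
        }
        t = forward_sample(BayesianNetwork(g, sch, cpts), 20_000, seed=4)
        cp = pc_learn(t)
        assert not cp.directed
        assert cp.undirected == frozenset({("A", "B"), ("B", "C")})

    def test_independent_data_gives_near_empty_graph(self):
        # false-positive edges occur at roughly the alpha rate; at alpha=0.01
        # with 6 pairs the skeleton is almost always empty
        empties = 0
        for seed in range(5):
            rng = np.random.default_rng(80 + seed)
            t = make_table(rng.integers(0, 3, size=(5000, 4)))
            empties += pc_learn(t, alpha=0.01).n_edges == 0
        assert empties >= 4

    def test_column_order_invariance(self):
        t = forward_sample(_collider_bn(), 10_000, seed=6)
        perm = [2, 0, 1]
        t2 = SurveyTable([t.schemas[i] for i in perm], t.codes[:, perm])
        c1, c2 = pc_learn(t), pc_learn(t2)
        assert c1.directed == c2.directed and c1.undirected == c2.undirected

    def test_alpha_monotone_skeleton(self):
        bn = _collider_bn(1.0)
        t = forward_sample(bn, 2000, seed=9)
        small = pc_learn(t, alpha=0.01)
        large = pc_learn(t, alpha=0.2)
        assert small.skeleton() <= large.skeleton()

    def test_constraints_respected(self):
        t = forward_sample(_collider_bn(), 5000, seed=10)
        cons = ConstraintSet(
            forbidden=frozenset({("A", "C"), ("C", "A")}),
            required=frozenset({("B", "C")}),
        )
        cp = pc_learn(t, constraints=cons)
        assert ("B", "C") in cp.directed
        assert not cp.adjacent("A", "C")


class TestCpdagOfDag:
    def test_compelled_and_reversible_patterns(self):
        collider = nx.DiGraph([("A", "C"), ("B", "C")])
        cp = cpdag_of_dag(collider)
        assert cp.directed == frozenset({("A", "C"), ("B", "C")})
        chain = nx.DiGraph([("A", "B"), ("B", "C")])
        cp2 = cpdag_of_dag(chain)
        assert not cp2.directed and len(cp2.undirected) == 2
        single = nx.DiGraph([("A", "B")])
        assert not cpdag_of_dag(single).directed

    def test_characterises_markov_equivalence(self, three_node_dags):
        """cpdag_of_dag(g) == cpdag_of_dag(g') iff same skeleton + colliders."""
        for g1, g2 in itertools.combinations(three_node_dags, 2):
            same_class = (
                {tuple(sorted(e)) for e in g1.edges} == {tuple(sorted(e)) for e in g2.edges}
                and _colliders(g1) == _colliders(g2)
            )
            c1, c2 = cpdag_of_dag(g1), cpdag_of_dag(g2)
            same_cpdag = c1.directed == c2.directed and c1.undirected == c2.undirected
            assert same_class == same_cpdag


def _colliders(g):
    out = set()
    for c in g.nodes:
        for a, b in itertools.combinations(sorted(g.predecessors(c)), 2):
            if not (g.has_edge(a, b) or g.has_edge(b, a)):
                out.add((a, b, c))
    return out


class TestDagExtension:
    def test_fully_directed_returns_itself(self):
        g = nx.DiGraph([("A", "C"), ("B", "C")])
        cp = cpdag_of_dag(g)
        ext = dag_extension(cp)
        assert set(ext.edges) == set(g.edges)

    def test_chain_extensions_never_create_collider(self):
        cp = CPDAG(("A", "B", "C"), frozenset(), frozenset({("A", "B"), ("B", "C")}))
        seen = set()
        for seed in range(20):
            ext = dag_extension(cp, seed=seed)
            assert nx.is_directed_acyclic_graph(ext)
            assert not _colliders(ext)
            seen.add(frozenset(ext.edges))
        allowed = {
            frozenset({("A", "B"), ("B", "C")}),
            frozenset({("C", "B"), ("B", "A")}),
            frozenset({("B", "A"), ("B", "C")}),
        }
        assert seen <= allowed

    def test_forbidden_direction_forces_the_other(self):
        cp = CPDAG(("A", "B"), frozenset(), frozenset({("A", "B")}))
        cons = ConstraintSet(forbidden=frozenset({("A", "B")}))
        ext = dag_extension(cp, cons)
        assert set(ext.edges) == {("B", "A")}

    def test_contradictory_constraints_raise(self):
        cp = CPDAG(("A", "B"), frozenset({("A", "B")}), frozenset())
        cons = ConstraintSet(forbidden=frozenset({("A", "B")}))
        with pytest.raises(ValueError):
            dag_extension(cp, cons)


class TestConstraintSet:
    def test_tiers_forbid_backward_edges(self):
        cons = ConstraintSet(tiers=(("D1", "D2"), ("B1",)))
        assert cons.is_forbidden("B1", "D1")
        assert not cons.is_forbidden("D1", "B1")
        assert not cons.is_forbidden("D1", "D2")

    def test_json_round_trip(self, tmp_path):
        cons = ConstraintSet(
            forbidden=frozenset({("X", "Y")}),
            required=frozenset({("Y", "Z")}),
            tiers=(("X",), ("Y", "Z")),
        )
        cons.to_json(tmp_path / "c.json")
        back = ConstraintSet.from_json(tmp_path / "c.json")
        assert back == cons

    def test_required_and_forbidden_clash(self):
        with pytest.raises(ValueError):
            ConstraintSet(forbidden=frozenset({("A", "B")}), required=frozenset({("A", "B")}))

    def test_demographics_prior(self):
        schemas = [
            VariableSchema("Age", ("a", "b"), "demographics"),
            VariableSchema("Worry", ("a", "b"), "emotions"),
        ]
        cons = demographics_prior(schemas)
        assert cons.is_forbidden("Worry", "Age")
        assert not cons.is_forbidden("Age", "Worry")
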