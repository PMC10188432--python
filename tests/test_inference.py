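"""CPT fitting, do-calculus surgery, interventional ORs and bootstrap."""

import networkx as nx
import numpy as np
import pytest

from causalbn import (
    BayesianNetwork,
    GeneratorConfig,
    InterventionQuery,
    VariableSchema,
    bootstrap_result,
    causal_factor_scan,
    do_distribution,
    fit_cpts,
    forward_sample,
    generate,
    interventional_or,
)

from conftest import make_schemas, make_table


class TestFitCpts:
    def test_unsmoothed_mle(self):
        codes = np.array([[0]] * 30 + [[1]] * 70)
        t = make_table(codes, names=["X"], levels=("a", "b"))
        g = nx.DiGraph()
        g.add_node("X")
        bn = fit_cpts(t, g, pseudo_count=0.0)
        assert np.allclose(bn.cpts["X"], [0.3, 0.7])

    def test_unseen_parent_config_is_uniform(self):
        codes = np.array([[0, 0], [0, 1], [0, 1]])
        t = make_table(codes, names=["P", "X"], levels=("a", "b"))
        bn = fit_cpts(t, nx.DiGraph([("P", "X")]), pseudo_count=1.0)
        assert np.allclose(bn.cpts["X"][1], [0.5, 0.5])  # P=1 never observed

    def test_recovers_truth_at_large_n(self, fixture_bn):
        """Fitted conditionals converge to the truth on parent configurations
        that are actually visited often enough to estimate."""
        t = forward_sample(fixture_bn, 50_000, seed=42)
        fit = fit_cpts(t, fixture_bn.dag, pseudo_count=1.0)
        worst = 0.0
        checked = 0
        for v in fixture_bn.dag.nodes:
            pa = fixture_bn.parents[v]
            counts = np.zeros(fit.cpts[v].shape[:-1])
            if pa:
                idx = tuple(t.column(p) for p in pa)
                np.add.at(counts, idx, 1)
            else:
                counts[()] = t.n_rows
            well_observed = counts >= 2000
            if well_observed.any():
                dev = np.abs(fit.cpts[v] - fixture_bn.cpts[v]).max(axis=-1)
                worst = max(worst, float(dev[well_observed].max()))
                checked += int(well_observed.sum())
        assert checked > 100  # the check has real coverage
        assert worst < 0.02


def _brute_force_do(bn, do, target):
    surgered = bn.dag.copy()
    cpts = dict(bn.cpts)
    parents = dict(bn.parents)
    for x, lvl in do.items():
        surgered.remove_edges_from(list(surgered.in_edges(x)))
        cpts[x] = np.eye(bn.card(x))[lvl]
        parents[x] = ()
    joint = BayesianNetwork(surgered, bn.schemas, cpts, parents).joint()
    ax = bn.names.index(target)
    return joint.sum(axis=tuple(a for a in range(joint.ndim) if a != ax))


class TestDoDistribution:
    def test_root_intervention_equals_conditioning(self):
        sch = make_schemas(["X", "Y"], levels=("a", "b"))
        g = nx.DiGraph([("X", "Y")])
        cpts = {"X": np.array([0.3, 0.7]), "Y": np.array([[0.9, 0.1], [0.2, 0.8]])}
        bn = BayesianNetwork(g, sch, cpts)
        assert np.allclose(do_distribution(bn, {"X": "b"}, "Y"), cpts["Y"][1])

    def test_confounder_only_structure_is_unmoved(self):
        # X <- Z -> Y: intervening on X cannot move Y
        sch = make_schemas(["X", "Y", "Z"], levels=("a", "b"))
        g = nx.DiGraph([("Z", "X"), ("Z", "Y")])
        cpts = {
            "Z": np.array([0.4, 0.6]),
            "X": np.array([[0.9, 0.1], [0.2, 0.8]]),
            "Y": np.array([[0.7, 0.3], [0.1, 0.9]]),
        }
        bn = BayesianNetwork(g, sch, cpts)
        base = 0.4 * cpts["Y"][0] + 0.6 * cpts["Y"][1]
        for lvl in ("a", "b"):
            assert np.allclose(do_distribution(bn, {"X": lvl}, "Y"), base, atol=1e-12)

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_brute_force_on_random_networks(self, seed):
        rng = np.random.default_rng(seed)
        cfg = GeneratorConfig(n_vars=4, levels_per_var=3, edge_prob=0.6, seed=seed, effect_strength=1.5)
        bn = generate(cfg)
        x, target = rng.choice(bn.names, size=2, replace=False)
        lvl = int(rng.integers(bn.card(x)))
        got = do_distribution(bn, {x: lvl}, target)
        want = _brute_force_do(bn, {x: lvl}, target)
        assert np.abs(got - want).max() < 1e-10

    def test_target_cannot_be_intervened(self):
        bn = generate(GeneratorConfig(n_vars=3, seed=0))
        with pytest.raises(ValueError):
            do_distribution(bn, {"X0": 0}, "X0")


def _worked_example_bn():
    sx = VariableSchema("X", ("a", "b"), "beliefs and perceptions")
    sy = VariableSchema("Y", ("lo", "mid", "hi"), "dependent variable")
    g = nx.DiGraph([("X", "Y")])
    cpts = {
        "X": np.array([0.5, 0.5]),
        "Y": np.array([[0.5, 0.3, 0.2], [0.2, 0.2, 0.6]]),
    }
    return BayesianNetwork(g, [sx, sy], cpts)


class TestInterventionalOR:
    def test_worked_two_node_example(self):
        bn = _worked_example_bn()
        q = InterventionQuery("X", "a", "b", "Y", ("lo", "hi"))
        assert interventional_or(bn, q) == pytest.approx(7.5, abs=1e-12)

    def test_inversion_symmetry(self):
        bn = _worked_example_bn()
        q = InterventionQuery("X", "a", "b", "Y", ("lo", "hi"))
        assert interventional_or(bn, q) * interventional_or(bn, q.swapped()) == pytest.approx(
            1.0, abs=1e-12
        )

    def test_disconnected_evidence_gives_unit_or(self):
        sch = make_schemas(["X", "Y"], levels=("a", "b"))
        g = nx.DiGraph()
        g.add_nodes_from(["X", "Y"])
        bn = BayesianNetwork(g, sch, {"X": np.array([0.5, 0.5]), "Y": np.array([0.3, 0.7])})
        q = InterventionQuery("X", "a", "b", "Y", ("a", "b"))
        assert interventional_or(bn, q) == pytest.approx(1.0, abs=1e-12)

    def test_degenerate_query_rejected(self):
        with pytest.raises(ValueError):
            InterventionQuery("X", "a", "a", "Y", ("lo", "hi"))


class TestBootstrap:
    def test_deterministic_given_seed(self):
        bn = _worked_example_bn()
        t = forward_sample(bn, 500, seed=1)
        q = InterventionQuery("X", "a", "b", "Y", ("lo", "hi"))
        r1 = bootstrap_result(t, bn.dag, q, B=100, seed=9)
        r2 = bootstrap_result(t, bn.dag, q, B=100, seed=9)
        assert (r1.ci_low, r1.ci_high, r1.p_value) == (r2.ci_low, r2.ci_high, r2.p_value)

    def test_strong_effect_reaches_minimal_p(self):
        # near-deterministic X -> Y: every replicate's log-OR on the same side of 0
        rng = np.random.default_rng(3)
        x = rng.integers(0, 2, 800)
        y = x.copy()
        flip = rng.random(800) < 0.02
        y[flip] = 1 - y[flip]
        t = make_table(np.column_stack([x, y]), names=["X", "Y"], levels=("a", "b"))
        q = InterventionQuery("X", "a", "b", "Y", ("a", "b"))
        B = 199
        r = bootstrap_result(t, nx.DiGraph([("X", "Y")]), q, B=B, seed=5)
        assert r.p_value == pytest.approx(2 / (B + 1))
        assert r.significant and r.ci_low > 1

    def test_significance_flag_tracks_p(self):
        bn = _worked_example_bn()
        t = forward_sample(bn, 60, seed=2)
        q = InterventionQuery("X", "a", "b", "Y", ("lo", "hi"))
        r = bootstrap_result(t, bn.dag, q, B=200, seed=3)
        assert r.significant == (r.p_value < 0.05)
        assert r.ci_low <= r.ci_high

    def test_weighted_resampling_used(self):
        # all weight on X=a rows: replicates never contain an X=b row, so the
        # refitted conditional at X=b is uniform and every replicate's OR is
        # the same constant: (0.5/0.5) / ((1/102)/(101/102)) = 101
        codes = np.array([[0, 0]] * 50 + [[1, 1]] * 50)
        w = np.array([1.0] * 50 + [0.0] * 50)
        t = make_table(codes, names=["X", "Y"], levels=("a", "b"), weights=w)
        q = InterventionQuery("X", "a", "b", "Y", ("a", "b"))
        r = bootstrap_result(t, nx.DiGraph([("X", "Y")]), q, B=50, seed=1)
        assert r.ci_low == r.ci_high == pytest.approx(101.0)


class TestCausalFactorScan:
    def test_chain_and_causes_of_cause(self):
        sch = make_schemas(["A", "B", "C"], levels=("a", "b"))
        g = nx.DiGraph([("A", "B"), ("B", "C")])
        rng = np.random.default_rng(0)
        a = rng.integers(0, 2, 400)
        b = np.where(rng.random(400) < 0.8, a, 1 - a)
        c = np.where(rng.random(400) < 0.8, b, 1 - b)
        t = make_table(np.column_stack([a, b, c]), names=["A", "B", "C"], levels=("a", "b"))
        rep = causal_factor_scan(t, g, "C", B=50, seed=1)
        assert {r.query.evidence for r in rep.results} == {"A", "B"}
        assert rep.non_causal == ()
        rep_b = causal_factor_scan(t, g, "B", B=50, seed=1)
        assert {r.query.evidence for r in rep_b.results} == {"A"}
        assert rep_b.non_causal == ("C",)

    def test_rootless_target_scans_nothing(self):
        sch = make_schemas(["A", "B"], levels=("a", "b"))
        g = nx.DiGraph()
        g.add_nodes_from(["A", "B"])
        t = make_table(np.random.default_rng(1).integers(0, 2, (100, 2)), names=["A", "B"], levels=("a", "b"))
        rep = causal_factor_scan(t, g, "A", B=10, seed=0)
        assert rep.results == () and rep.non_causal == ("B",)

    def test_fixture_scan_covers_exactly_the_ancestors(self, fixture_bn):
        t = forward_sample(fixture_bn, 1500, seed=8)
        rep = causal_factor_scan(
            t, fixture_bn.dag, "Vaccine intention", B=1, seed=0, contrasts=[("Low", "High")]
        )
        scanned = {r.query.evidence for r in rep.results}
        assert scanned == nx.ancestors(fixture_bn.dag, "Vaccine intention")
        assert set(rep.non_causal) == (
            set(fixture_bn.names) - scanned - {"Vaccine intention"}
        )
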