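"""Strong-extension bounds, conditioning, interventions and the impact statistic."""

import numpy as np
import pytest

from conftest import (
    brute_force_bounds,
    cpts_from_choice,
    oracle_posterior,
    random_network,
    table_rows,
)
from credalpod.core import CredalNetwork, CredalSetSpec, IntervalDistribution, StateSpace
from credalpod.exceptions import ConditioningError, StructuralError
from credalpod.inference import bayesian_posterior, impact, posterior_bounds


class TestBayesianPosterior:
    def test_chain_closed_form(self, point_chain):
        # P(a1|b1) = 0.5*0.8 / (0.5*0.8 + 0.5*0.2)
        assert bayesian_posterior(point_chain, "A", "a1", {"B": "b1"}) == pytest.approx(0.8)

    def test_empty_evidence_gives_root_marginal(self, point_chain):
        assert bayesian_posterior(point_chain, "A", "a1") == pytest.approx(0.5)

    def test_evidence_on_target_itself(self, point_chain):
        assert bayesian_posterior(point_chain, "A", "a1", {"A": "a1"}) == 1.0
        assert bayesian_posterior(point_chain, "A", "a2", {"A": "a1"}) == 0.0

    def test_zero_probability_evidence_rejected(self):
        A = StateSpace("A", ("a1", "a2"))
        B = StateSpace("B", ("b1", "b2"))
        net = CredalNetwork(
            [A, B],
            {"B": ("A",)},
            {
                ("A", ()): CredalSetSpec.from_point([1.0, 0.0]),
                ("B", ("a1",)): CredalSetSpec.from_point([1.0, 0.0]),
                ("B", ("a2",)): CredalSetSpec.from_point([0.0, 1.0]),
            },
        )
        with pytest.raises(ConditioningError):
            bayesian_posterior(net, "A", "a1", {"B": "b2"})

    def test_requires_point_valued_network(self, toy_net):
        with pytest.raises(StructuralError):
            bayesian_posterior(toy_net, "B", "b1")

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_full_joint_oracle(self, seed):
        rng = np.random.default_rng(4000 + seed)
        net = random_network(rng, n_nodes=5, point_only=True)
        cpts = cpts_from_choice(
            net, {k: net.tables[k].base.lower for k in table_rows(net)}
        )
        target = net.variables[-1]
        ev_var = net.variables[0]
        ev = {ev_var: net.states(ev_var)[0]}
        expected = oracle_posterior(net, cpts, target, net.states(target)[0], ev)
        if expected is None:
            return
        got = bayesian_posterior(net, target, net.states(target)[0], ev)
        assert got == pytest.approx(expected, abs=1e-12)


class TestPosteriorBounds:
    def test_toy_marginal(self, toy_net):
        res = posterior_bounds(toy_net, "B", "b1")
        assert res.exact
        assert res.lower == pytest.approx(0.34, abs=1e-12)
        assert res.upper == pytest.approx(0.66, abs=1e-12)

    def test_toy_posterior(self, toy_net):
        res = posterior_bounds(toy_net, "A", "a1", {"B": "b1"})
        assert res.lower == pytest.approx(0.6087, abs=5e-5)
        assert res.upper == pytest.approx(0.9310, abs=5e-5)

    def test_toy_intervention_keeps_mutilated_row(self, toy_net):
        res = posterior_bounds(toy_net, "B", "b1", do={"A": "a1"})
        assert (res.lower, res.upper) == (pytest.approx(0.7), pytest.approx(0.9))

    def test_point_network_reduces_to_bayes(self, point_chain):
        res = posterior_bounds(point_chain, "A", "a1", {"B": "b1"})
        assert res.exact
        assert res.lower == pytest.approx(0.8, abs=1e-12)
        assert res.upper == pytest.approx(0.8, abs=1e-12)

    def test_evidence_and_do_overlap_rejected(self, toy_net):
        with pytest.raises(StructuralError):
            posterior_bounds(toy_net, "B", "b1", {"A": "a1"}, {"A": "a2"})

    def test_impossible_evidence_rejected(self):
        A = StateSpace("A", ("a1", "a2"))
        net = CredalNetwork(
            [A], {}, {("A", ()): CredalSetSpec.from_point([1.0, 0.0])}
        )
        with pytest.raises(ConditioningError):
            posterior_bounds(net, "A", "a1", {"A": "a2"})

    def test_regular_extension_flagged(self):
        # P(a1) in [0, 0.5]: one vertex kills the evidence A=a1 entirely.
        A = StateSpace("A", ("a1", "a2"))
        B = StateSpace("B", ("b1", "b2"))
        net = CredalNetwork(
            [A, B],
            {"B": ("A",)},
            {
                ("A", ()): CredalSetSpec(IntervalDistribution([0.0, 0.5], [0.5, 1.0])),
                ("B", ("a1",)): CredalSetSpec.from_point([0.9, 0.1]),
                ("B", ("a2",)): CredalSetSpec.from_point([0.2, 0.8]),
            },
        )
        res = posterior_bounds(net, "B", "b1", {"A": "a1"})
        assert res.regular_extension
        assert res.lower == pytest.approx(0.9)
        assert res.upper == pytest.approx(0.9)

    def test_local_search_is_inner_approximation(self, toy_net):
        exact = posterior_bounds(toy_net, "A", "a1", {"B": "b1"})
        approx = posterior_bounds(
            toy_net, "A", "a1", {"B": "b1"}, budget=0, restarts=4, seed=5
        )
        assert not approx.exact
        assert approx.method == "local-search"
        assert approx.lower >= exact.lower - 1e-12
        assert approx.upper <= exact.upper + 1e-12
        # the toy problem is small enough that the search still lands exactly
        assert approx.lower == pytest.approx(exact.lower, abs=1e-9)
        assert approx.upper == pytest.approx(exact.upper, abs=1e-9)

    def test_local_search_deterministic(self, toy_net):
        a = posterior_bounds(toy_net, "B", "b1", budget=0, seed=11)
        b = posterior_bounds(toy_net, "B", "b1", budget=0, seed=11)
        assert (a.lower, a.upper) == (b.lower, b.upper)

    @pytest.mark.parametrize("seed", range(10))
    def test_exact_bounds_match_brute_force(self, seed):
        rng = np.random.default_rng(5000 + seed)
        net = random_network(rng, n_nodes=4, max_interval_rows=4)
        target = net.variables[-1]
        t_state = net.states(target)[0]
        ev_var = net.variables[0]
        ev = {ev_var: net.states(ev_var)[-1]} if seed % 2 else None
        res = posterior_bounds(net, target, t_state, ev)
        assert res.exact
        lo, hi = brute_force_bounds(net, target, t_state, ev)
        assert res.lower == pytest.approx(lo, abs=1e-10)
        assert res.upper == pytest.approx(hi, abs=1e-10)

    @pytest.mark.parametrize("seed", range(5))
    def test_widening_tables_never_narrows_bounds(self, seed):
        rng = np.random.default_rng(6000 + seed)
        net = random_network(rng, n_nodes=3, max_interval_rows=3)
        target = net.variables[-1]
        t_state = net.states(target)[0]
        res = posterior_bounds(net, target, t_state)

        wide = net.copy()
        for key, spec in wide.tables.items():
            l = np.clip(spec.base.lower - 0.05, 0, 1)
            u = np.clip(spec.base.upper + 0.05, 0, 1)
            wide.tables[key] = CredalSetSpec(IntervalDistribution(l, u))
        res_w = posterior_bounds(wide, target, t_state)
        assert res_w.lower <= res.lower + 1e-10
        assert res_w.upper >= res.upper - 1e-10


class TestInterventions:
    @pytest.mark.parametrize("seed", range(10))
    def test_do_equals_observe_on_roots(self, seed):
        rng = np.random.default_rng(7000 + seed)
        net = random_network(rng, n_nodes=4, point_only=True)
        roots = [v for v in net.variables if not net.parents[v]]
        root = roots[0]
        target = net.variables[-1]
        if target == root:
            return
        state = net.states(root)[0]
        t_state = net.states(target)[0]
        try:
            obs = posterior_bounds(net, target, t_state, evidence={root: state})
        except ConditioningError:
            return
        act = posterior_bounds(net, target, t_state, do={root: state})
        assert act.lower == pytest.approx(obs.lower, abs=1e-12)
        assert act.upper == pytest.approx(obs.upper, abs=1e-12)

    def test_do_breaks_confounding_observe_does_not(self):
        # A -> B, A -> C: observing B tells us about C; doing B must not.
        A = StateSpace("A", ("a1", "a2"))
        B = StateSpace("B", ("b1", "b2"))
        C = StateSpace("C", ("c1", "c2"))
        net = CredalNetwork(
            [A, B, C],
            {"B": ("A",), "C": ("A",)},
            {
                ("A", ()): CredalSetSpec.from_point([0.3, 0.7]),
                ("B", ("a1",)): CredalSetSpec.from_point([0.9, 0.1]),
                ("B", ("a2",)): CredalSetSpec.from_point([0.1, 0.9]),
                ("C", ("a1",)): CredalSetSpec.from_point([0.8, 0.2]),
                ("C", ("a2",)): CredalSetSpec.from_point([0.2, 0.8]),
            },
        )
        marginal = posterior_bounds(net, "C", "c1")
        seen = posterior_bounds(net, "C", "c1", evidence={"B": "b1"})
        done = posterior_bounds(net, "C", "c1", do={"B": "b1"})
        assert done.lower == pytest.approx(marginal.lower, abs=1e-12)
        assert seen.lower > marginal.lower + 0.05


class TestImpact:
    def test_toy_do_impact_sixty_points(self, toy_net):
        res = impact(toy_net, "B", "b1", "A", mode="do")
        assert res.lowers["a1"] == pytest.approx(0.7)
        assert res.lowers["a2"] == pytest.approx(0.1)
        assert res.points == pytest.approx(60.0, abs=1e-9)
        assert res.display_points == 60
        assert set(res.pairs.columns) == {"state_a", "state_b", "difference"}

    def test_disconnected_variable_zero_impact(self, toy_net):
        C = StateSpace("C", ("c1", "c2"))
        net = CredalNetwork(
            list(toy_net.state_spaces.values()) + [C],
            {**toy_net.parents, "C": ()},
            {**toy_net.tables, ("C", ()): CredalSetSpec.from_point([0.5, 0.5])},
        )
        res = impact(net, "B", "b1", "C", mode="do")
        assert res.points == pytest.approx(0.0, abs=1e-12)

    def test_point_network_impact_is_posterior_difference(self, point_chain):
        res = impact(point_chain, "B", "b1", "A", mode="observe")
        d = abs(
            bayesian_posterior(point_chain, "B", "b1", {"A": "a1"})
            - bayesian_posterior(point_chain, "B", "b1", {"A": "a2"})
        )
        assert res.points == pytest.approx(100 * d, abs=1e-12)

    def test_manipulating_the_target_rejected(self, toy_net):
        with pytest.raises(StructuralError):
            impact(toy_net, "B", "b1", "B", mode="do")


class TestStrongExtensionSoundness:
    @pytest.mark.parametrize("seed", range(5))
    def test_random_vertex_posteriors_inside_bounds(self, seed):
        rng = np.random.default_rng(8000 + seed)
        net = random_network(rng, n_nodes=4, max_interval_rows=4)
        target = net.variables[-1]
        t_state = net.states(target)[0]
        res = posterior_bounds(net, target, t_state)
        keys = list(table_rows(net))
        verts = {k: net.tables[k].vertices() for k in keys}
        for _ in range(200):
            choice = {k: verts[k][rng.integers(len(verts[k]))] for k in keys}
            val = oracle_posterior(
                net, cpts_from_choice(net, choice), target, t_state, {}
            )
            assert res.lower - 1e-9 <= val <= res.upper + 1e-9
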