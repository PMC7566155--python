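"""Credal-set geometry: coherence, reachability, vertex enumeration."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.optimize import linprog

from credalpod.core import (
    CredalNetwork,
    CredalSetSpec,
    IntervalDistribution,
    StateSpace,
    check_coherence,
    enumerate_vertices,
    normalize_reachable,
    validate_network,
)
from credalpod.exceptions import (
    CoherenceError,
    FeasibilityError,
    SizeGuardError,
    StructuralError,
)


def lp_extreme(spec: CredalSetSpec, i: int, sense: str) -> float:
    """Independent per-coordinate LP min/max over the polytope."""
    k = spec.k
    c = np.zeros(k)
    c[i] = 1.0 if sense == "min" else -1.0
    A_ub, b_ub = None, None
    if spec.orderings:
        A_ub = np.zeros((len(spec.orderings), k))
        for r, (a, b) in enumerate(spec.orderings):
            A_ub[r, a], A_ub[r, b] = -1.0, 1.0
        b_ub = np.zeros(len(spec.orderings))
    res = linprog(
        c, A_ub=A_ub, b_ub=b_ub, A_eq=np.ones((1, k)), b_eq=[1.0],
        bounds=list(zip(spec.base.lower, spec.base.upper)), method="highs",
    )
    assert res.status == 0
    return float(res.x[i])


class TestCoherence:
    @pytest.mark.parametrize(
        "l,u,ok",
        [
            ((0.2, 0.3), (0.5, 0.6), True),
            ((0.6, 0.5), (0.7, 0.6), False),  # sum of lowers exceeds one
            ((0.0, 0.0), (0.3, 0.5), False),  # uppers cannot reach one
        ],
    )
    def test_sum_constraints(self, l, u, ok):
        report = check_coherence(IntervalDistribution(l, u))
        assert report.ok is ok
        assert bool(report.violations) is (not ok)

    def test_structural_errors(self):
        with pytest.raises(StructuralError):
            IntervalDistribution([0.1, 0.2], [0.3])
        with pytest.raises(StructuralError):
            IntervalDistribution([0.5, 0.2], [0.3, 0.4])  # l > u
        with pytest.raises(StructuralError):
            IntervalDistribution([0.5], [0.5])  # single state


class TestNormalizeReachable:
    def test_worked_example(self):
        out = normalize_reachable(IntervalDistribution([0.3, 0.2], [0.9, 0.6]))
        np.testing.assert_allclose(out.lower, [0.4, 0.2])
        np.testing.assert_allclose(out.upper, [0.8, 0.6])

    def test_three_state_upper_tightening(self):
        out = normalize_reachable(
            IntervalDistribution([0.1, 0.1, 0.1], [0.9, 0.9, 0.9])
        )
        np.testing.assert_allclose(out.lower, [0.1, 0.1, 0.1])
        np.testing.assert_allclose(out.upper, [0.8, 0.8, 0.8])

    def test_point_distribution_unchanged(self):
        out = normalize_reachable(IntervalDistribution([0.3, 0.7], [0.3, 0.7]))
        np.testing.assert_allclose(out.lower, [0.3, 0.7], atol=1e-15)
        np.testing.assert_allclose(out.upper, [0.3, 0.7], atol=1e-15)

    def test_incoherent_rejected(self):
        with pytest.raises(CoherenceError):
            normalize_reachable(IntervalDistribution([0.6, 0.5], [0.7, 0.6]))

    @pytest.mark.parametrize("seed", range(30))
    def test_equals_lp_minmax_and_idempotent(self, seed):
        rng = np.random.default_rng(1000 + seed)
        k = int(rng.integers(2, 5))
        p = rng.dirichlet(np.ones(k))
        half = rng.uniform(0, 0.3, size=k)
        dist = IntervalDistribution(
            np.clip(p - half, 0, 1), np.clip(p + half, 0, 1)
        )
        out = normalize_reachable(dist)
        spec = CredalSetSpec(dist)
        for i in range(k):
            assert out.lower[i] == pytest.approx(lp_extreme(spec, i, "min"), abs=1e-9)
            assert out.upper[i] == pytest.approx(lp_extreme(spec, i, "max"), abs=1e-9)
        again = normalize_reachable(out)
        np.testing.assert_allclose(again.lower, out.lower, atol=1e-12)
        np.testing.assert_allclose(again.upper, out.upper, atol=1e-12)
        assert (out.lower >= dist.lower - 1e-12).all()
        assert (out.upper <= dist.upper + 1e-12).all()


class TestEnumerateVertices:
    def test_binary_endpoints(self):
        spec = CredalSetSpec(IntervalDistribution([0.2, 0.4], [0.6, 0.8]))
        verts = enumerate_vertices(spec)
        np.testing.assert_allclose(verts, [[0.2, 0.8], [0.6, 0.4]])

    def test_three_state_example(self):
        spec = CredalSetSpec(IntervalDistribution([0.1, 0.2, 0.3], [0.5, 0.5, 0.5]))
        verts = enumerate_vertices(spec)
        expected = {
            (0.1, 0.4, 0.5),
            (0.1, 0.5, 0.4),
            (0.2, 0.5, 0.3),
            (0.3, 0.2, 0.5),
            (0.5, 0.2, 0.3),
        }
        got = {tuple(np.round(v, 9)) for v in verts}
        assert got == expected

    def test_ordering_constraint(self):
        spec = CredalSetSpec(
            IntervalDistribution([0.2, 0.4], [0.6, 0.8]), orderings=((0, 1),)
        )
        verts = enumerate_vertices(spec)
        np.testing.assert_allclose(verts, [[0.5, 0.5], [0.6, 0.4]])

    def test_point_set_single_vertex(self):
        spec = CredalSetSpec.from_point([0.3, 0.7])
        verts = enumerate_vertices(spec)
        np.testing.assert_allclose(verts, [[0.3, 0.7]])

    def test_infeasible_is_error_not_empty(self):
        spec = CredalSetSpec(IntervalDistribution([0.0, 0.0], [0.4, 0.4]))
        with pytest.raises(FeasibilityError):
            enumerate_vertices(spec)

    def test_size_guard(self):
        k = 7
        spec = CredalSetSpec(IntervalDistribution([0.0] * k, [1.0] * k))
        with pytest.raises(SizeGuardError):
            enumerate_vertices(spec)

    @pytest.mark.parametrize("seed", range(25))
    def test_vertices_valid_and_convex(self, seed):
        rng = np.random.default_rng(2000 + seed)
        k = int(rng.integers(2, 5))
        p = rng.dirichlet(np.ones(k))
        half = rng.uniform(0.02, 0.25, size=k)
        spec = CredalSetSpec(
            IntervalDistribution(np.clip(p - half, 0, 1), np.clip(p + half, 0, 1))
        )
        verts = enumerate_vertices(spec)
        assert len(verts) >= 1
        for v in verts:
            assert v.sum() == pytest.approx(1.0, abs=1e-9)
            assert spec.contains(v)
        # midpoints of vertex pairs stay inside (convexity sanity)
        for i in range(len(verts)):
            for j in range(i + 1, len(verts)):
                assert spec.contains((verts[i] + verts[j]) / 2)


@given(st.integers(min_value=0, max_value=10_000))
@settings(max_examples=40, deadline=None, derandomize=True)
def test_degenerate_point_specs_have_one_vertex(seed):
    rng = np.random.default_rng(seed)
    k = int(rng.integers(2, 6))
    p = rng.dirichlet(np.ones(k))
    verts = enumerate_vertices(CredalSetSpec.from_point(p))
    assert verts.shape == (1, k)
    np.testing.assert_allclose(verts[0], p, atol=1e-9)


class TestValidateNetwork:
    def _chain(self):
        A = StateSpace("A", ("a1", "a2"))
        B = StateSpace("B", ("b1", "b2"))
        tables = {
            ("A", ()): CredalSetSpec.from_point([0.5, 0.5]),
            ("B", ("a1",)): CredalSetSpec.from_point([0.8, 0.2]),
            ("B", ("a2",)): CredalSetSpec.from_point([0.2, 0.8]),
        }
        return [A, B], {"B": ("A",)}, tables

    def test_valid_chain(self):
        spaces, parents, tables = self._chain()
        assert validate_network(CredalNetwork(spaces, parents, tables)).ok

    def test_cycle_reported(self):
        spaces, parents, tables = self._chain()
        parents = {"B": ("A",), "A": ("B",)}
        tables = {
            ("A", ("b1",)): CredalSetSpec.from_point([0.5, 0.5]),
            ("A", ("b2",)): CredalSetSpec.from_point([0.5, 0.5]),
            ("B", ("a1",)): CredalSetSpec.from_point([0.8, 0.2]),
            ("B", ("a2",)): CredalSetSpec.from_point([0.2, 0.8]),
        }
        report = validate_network(CredalNetwork(spaces, parents, tables))
        assert not report.ok
        assert any("cycle" in p for p in report.problems)

    def test_missing_table_reported(self):
        spaces, parents, tables = self._chain()
        del tables[("B", ("a2",))]
        report = validate_network(CredalNetwork(spaces, parents, tables))
        assert not report.ok
        assert any("missing table" in p and "a2" in p for p in report.problems)

    def test_incoherent_table_reported(self):
        spaces, parents, tables = self._chain()
        tables[("B", ("a1",))] = CredalSetSpec(
            IntervalDistribution([0.0, 0.0], [0.3, 0.5])
        )
        report = validate_network(CredalNetwork(spaces, parents, tables))
        assert not report.ok
        assert any("'B'" in p for p in report.problems)
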