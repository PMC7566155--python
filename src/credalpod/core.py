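"""Discrete credal sets and credal networks.

A *credal set* over a variable with states ``s_1 .. s_k`` is, in this
package, the polytope of probability vectors ``p`` on the simplex that
satisfy per-state interval bounds ``l_i <= p_i <= u_i`` and optional
pairwise ordering constraints ``p_a >= p_b``.  A credal network attaches
one such set to every (variable, parent configuration) pair of a DAG; a
Bayesian network is the degenerate case ``l = u`` everywhere.

Geometry conventions
--------------------
* State order as declared is canonical: every probability vector is
  indexed by it, and ties anywhere in the package break in its favour.
* Vertex enumeration caps the number of states per set (default 6)
  because the candidate count grows combinatorially; exceeding the cap
  raises :class:`~credalpod.exceptions.SizeGuardError` rather than
  silently truncating.
* Vertices are deduplicated at absolute tolerance ``1e-9`` (double
  precision is ample for k <= 6) and returned in lexicographic order.
* Feasibility is always established by linear programming before any
  enumeration; an empty polytope is an error, never an empty vertex list.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping, Sequence

import networkx as nx
import numpy as np
from scipy.optimize import linprog

from .exceptions import (
    CoherenceError,
    FeasibilityError,
    SizeGuardError,
    StructuralError,
)

#: Absolute tolerance for vertex deduplication and constraint satisfaction.
VERTEX_TOL = 1e-9
#: Default cap on the number of states per credal set for enumeration.
MAX_ENUM_STATES = 6


@dataclass(frozen=True)
class StateSpace:
    """A named discrete variable with an ordered set of state labels."""

    name: str
    states: tuple[str, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "states", tuple(self.states))
        if len(self.states) < 2:
            raise StructuralError(f"variable {self.name!r} needs >=2 states")
        if len(set(self.states)) != len(self.states):
            raise StructuralError(f"variable {self.name!r} has duplicate state labels")

    @property
    def cardinality(self) -> int:
        return len(self.states)

    def index(self, state: str) -> int:
        try:
            return self.states.index(state)
        except ValueError:
            raise StructuralError(
                f"{state!r} is not a state of {self.name!r} (states: {list(self.states)})"
            ) from None


class IntervalDistribution:
    """Per-state probability intervals ``[l_i, u_i]`` over one variable.

    The constructor enforces only structural sanity (equal lengths, values
    in ``[0, 1]``, ``l_i <= u_i``); whether the intervals admit a
    probability distribution at all is reported by :func:`check_coherence`.
    """

    __slots__ = ("lower", "upper")

    def __init__(self, lower: Sequence[float], upper: Sequence[float]) -> None:
        l = np.asarray(lower, dtype=float)
        u = np.asarray(upper, dtype=float)
        if l.ndim != 1 or l.shape != u.shape:
            raise StructuralError("lower and upper must be equal-length vectors")
        if l.size < 2:
            raise StructuralError("an interval distribution needs >=2 states")
        if not (np.isfinite(l).all() and np.isfinite(u).all()):
            raise StructuralError("interval bounds must be finite")
        if (l < -VERTEX_TOL).any() or (u > 1 + VERTEX_TOL).any():
            raise StructuralError("interval bounds must lie in [0, 1]")
        if (l > u + VERTEX_TOL).any():
            raise StructuralError("lower bound exceeds upper bound for some state")
        self.lower = np.clip(l, 0.0, 1.0)
        self.upper = np.clip(u, 0.0, 1.0)

    @classmethod
    def point(cls, probs: Sequence[float]) -> "IntervalDistribution":
        """Degenerate ``l = u`` distribution (Bayesian special case)."""
        return cls(probs, probs)

    @property
    def k(self) -> int:
        return int(self.lower.size)

    @property
    def is_point(self) -> bool:
        return bool(np.allclose(self.lower, self.upper, atol=1e-12, rtol=0.0))

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, IntervalDistribution):
            return NotImplemented
        return bool(
            np.array_equal(self.lower, other.lower)
            and np.array_equal(self.upper, other.upper)
        )

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        pairs = ", ".join(
            f"[{l:.3g},{u:.3g}]" for l, u in zip(self.lower, self.upper)
        )
        return f"IntervalDistribution({pairs})"


@dataclass(frozen=True)
class CoherenceReport:
    ok: bool
    violations: tuple[str, ...]


def check_coherence(dist: IntervalDistribution, tol: float = VERTEX_TOL) -> CoherenceReport:
    """Check that the intervals admit at least one probability distribution.

    Coherence requires ``sum(l) <= 1 <= sum(u)`` on top of the elementwise
    ``0 <= l_i <= u_i <= 1`` the constructor already enforces.
    """
    violations: list[str] = []
    sl, su = float(dist.lower.sum()), float(dist.upper.sum())
    if sl > 1 + tol:
        violations.append(f"sum of lower bounds {sl:.6g} > 1")
    if su < 1 - tol:
        violations.append(f"sum of upper bounds {su:.6g} < 1")
    return CoherenceReport(ok=not violations, violations=tuple(violations))


def normalize_reachable(dist: IntervalDistribution) -> IntervalDistribution:
    """Tighten intervals to their reachable (tight) form.

    The credal set is unchanged; each bound becomes attainable:
    ``l_i' = max(l_i, 1 - sum_{j!=i} u_j)`` and
    ``u_i' = min(u_i, 1 - sum_{j!=i} l_j)``.  Idempotent.
    """
    report = check_coherence(dist)
    if not report.ok:
        raise CoherenceError("; ".join(report.violations))
    l, u = dist.lower, dist.upper
    su, sl = u.sum(), l.sum()
    new_l = np.maximum(l, 1.0 - (su - u))
    new_u = np.minimum(u, 1.0 - (sl - l))
    return IntervalDistribution(np.clip(new_l, 0.0, 1.0), np.clip(new_u, 0.0, 1.0))


@dataclass
class CredalSetSpec:
    """A credal set given by interval bounds plus pairwise orderings.

    ``orderings`` is a tuple of index pairs ``(a, b)`` meaning
    ``p[a] >= p[b]`` (state indices into the canonical order).
    """

    base: IntervalDistribution
    orderings: tuple[tuple[int, int], ...] = ()
    _vertices: np.ndarray | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        k = self.base.k
        cleaned = []
        for a, b in self.orderings:
            a, b = int(a), int(b)
            if not (0 <= a < k and 0 <= b < k) or a == b:
                raise StructuralError(f"ordering ({a},{b}) references invalid states")
            cleaned.append((a, b))
        self.orderings = tuple(cleaned)

    @classmethod
    def from_point(cls, probs: Sequence[float]) -> "CredalSetSpec":
        return cls(IntervalDistribution.point(probs))

    @property
    def k(self) -> int:
        return self.base.k

    @property
    def is_point(self) -> bool:
        return self.base.is_point

    def is_feasible(self, tol: float = VERTEX_TOL) -> bool:
        """LP feasibility of {p in simplex : l <= p <= u, orderings}."""
        k = self.k
        A_ub, b_ub = _ordering_rows(self.orderings, k)
        res = linprog(
            c=np.zeros(k),
            A_ub=A_ub,
            b_ub=b_ub,
            A_eq=np.ones((1, k)),
            b_eq=[1.0],
            bounds=list(zip(self.base.lower - tol, self.base.upper + tol)),
            method="highs",
        )
        return bool(res.status == 0)

    def vertices(self) -> np.ndarray:
        """Cached :func:`enumerate_vertices` of this set."""
        if self._vertices is None:
            self._vertices = enumerate_vertices(self)
        return self._vertices

    def contains(self, p: Sequence[float], tol: float = 1e-7) -> bool:
        p = np.asarray(p, dtype=float)
        if abs(p.sum() - 1.0) > tol:
            return False
        if (p < self.base.lower - tol).any() or (p > self.base.upper + tol).any():
            return False
        return all(p[a] >= p[b] - tol for a, b in self.orderings)


def _ordering_rows(orderings: Sequence[tuple[int, int]], k: int):
    """Orderings p_a >= p_b as A_ub p <= b_ub rows (p_b - p_a <= 0)."""
    if not orderings:
        return None, None
    A = np.zeros((len(orderings), k))
    for i, (a, b) in enumerate(orderings):
        A[i, a] = -1.0
        A[i, b] = 1.0
    return A, np.zeros(len(orderings))


def enumerate_vertices(
    spec: CredalSetSpec, max_states: int = MAX_ENUM_STATES, tol: float = VERTEX_TOL
) -> np.ndarray:
    """Exact extreme points of the credal-set polytope.

    Enumerates candidate basic solutions: every choice of ``k - 1``
    inequality constraints (bounds and orderings) made active alongside
    the simplex equality, solved and filtered for feasibility, then
    deduplicated at ``tol``.  Returns an ``(m, k)`` array in lexicographic
    order; each row sums to one and satisfies every constraint.
    """
    k = spec.k
    if k > max_states:
        raise SizeGuardError(
            f"vertex enumeration capped at {max_states} states, got {k}"
        )
    if not spec.is_feasible():
        raise FeasibilityError("credal set is empty (intervals/orderings infeasible)")

    l, u = spec.base.lower, spec.base.upper
    # Constraint normals a.p = b when active.
    normals: list[np.ndarray] = []
    offsets: list[float] = []
    for i in range(k):
        e = np.zeros(k)
        e[i] = 1.0
        normals.append(e.copy())
        offsets.append(float(l[i]))
        normals.append(e)
        offsets.append(float(u[i]))
    for a, b in spec.orderings:
        row = np.zeros(k)
        row[a], row[b] = 1.0, -1.0
        normals.append(row)
        offsets.append(0.0)

    ones = np.ones(k)
    found: list[np.ndarray] = []
    for combo in itertools.combinations(range(len(normals)), k - 1):
        M = np.vstack([ones] + [normals[i] for i in combo])
        rhs = np.array([1.0] + [offsets[i] for i in combo])
        try:
            p = np.linalg.solve(M, rhs)
        except np.linalg.LinAlgError:
            continue
        if not np.isfinite(p).all():
            continue
        if (p < l - tol).any() or (p > u + tol).any():
            continue
        if any(p[a] < p[b] - tol for a, b in spec.orderings):
            continue
        if not any(np.max(np.abs(p - q)) <= 10 * tol for q in found):
            found.append(np.clip(p, 0.0, 1.0))
    verts = np.array(sorted(found, key=tuple))
    verts.setflags(write=False)
    return verts


ParentConfig = tuple[str, ...]
TableKey = tuple[str, ParentConfig]


class CredalNetwork:
    """A DAG of discrete variables with one credal set per CPT row.

    ``tables`` maps ``(variable, parent_config)`` to a
    :class:`CredalSetSpec`, where ``parent_config`` is the tuple of parent
    states in the declared parent order (``()`` for roots).
    """

    def __init__(
        self,
        variables: Sequence[StateSpace],
        parents: Mapping[str, Sequence[str]],
        tables: Mapping[TableKey, CredalSetSpec],
        name: str = "",
        table_meta: Mapping[TableKey, Mapping[str, str]] | None = None,
    ) -> None:
        self.name = name
        self.state_spaces: dict[str, StateSpace] = {}
        for ss in variables:
            if ss.name in self.state_spaces:
                raise StructuralError(f"duplicate variable {ss.name!r}")
            self.state_spaces[ss.name] = ss
        self.parents: dict[str, tuple[str, ...]] = {
            v: tuple(parents.get(v, ())) for v in self.state_spaces
        }
        for v, ps in self.parents.items():
            for p in ps:
                if p not in self.state_spaces:
                    raise StructuralError(f"unknown parent {p!r} of {v!r}")
            if len(set(ps)) != len(ps):
                raise StructuralError(f"duplicate parent of {v!r}")
        self.tables: dict[TableKey, CredalSetSpec] = {
            (v, tuple(cfg)): spec for (v, cfg), spec in tables.items()
        }
        self.table_meta: dict[TableKey, dict[str, str]] = {
            (v, tuple(cfg)): dict(m) for (v, cfg), m in (table_meta or {}).items()
        }

    # -- structure ---------------------------------------------------------

    @property
    def variables(self) -> tuple[str, ...]:
        return tuple(self.state_spaces)

    def states(self, var: str) -> tuple[str, ...]:
        if var not in self.state_spaces:
            raise StructuralError(f"unknown variable {var!r}")
        return self.state_spaces[var].states

    def graph(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(self.variables)
        for v, ps in self.parents.items():
            g.add_edges_from((p, v) for p in ps)
        return g

    def parent_configs(self, var: str) -> Iterator[ParentConfig]:
        spaces = [self.state_spaces[p].states for p in self.parents[var]]
        return itertools.product(*spaces)

    def topological_order(self) -> list[str]:
        order = list(nx.lexicographical_topological_sort(self.graph()))
        return order

    @property
    def is_point_valued(self) -> bool:
        return all(spec.is_point for spec in self.tables.values())

    # -- editing -----------------------------------------------------------

    def copy(self) -> "CredalNetwork":
        return CredalNetwork(
            list(self.state_spaces.values()),
            dict(self.parents),
            dict(self.tables),
            name=self.name,
            table_meta=self.table_meta,
        )

    def mutilate(self, do: Mapping[str, str]) -> "CredalNetwork":
        """Graph surgery for interventions.

        Each do-variable loses its incoming arcs and its credal sets are
        replaced by a single point mass on the imposed state.
        """
        net = self.copy()
        for var, state in do.items():
            ss = net.state_spaces[var]
            idx = ss.index(state)
            for cfg in list(net.parent_configs(var)):
                net.tables.pop((var, cfg), None)
                net.table_meta.pop((var, cfg), None)
            net.parents[var] = ()
            point = np.zeros(ss.cardinality)
            point[idx] = 1.0
            net.tables[(var, ())] = CredalSetSpec.from_point(point)
        return net

    def restrict_to(self, keep: Iterable[str]) -> "CredalNetwork":
        """Sub-network on an ancestrally closed variable subset."""
        keep_set = set(keep)
        for v in keep_set:
            missing = set(self.parents[v]) - keep_set
            if missing:
                raise StructuralError(
                    f"cannot restrict: {v!r} keeps parents {sorted(missing)} outside the subset"
                )
        variables = [self.state_spaces[v] for v in self.variables if v in keep_set]
        parents = {v: self.parents[v] for v in keep_set}
        tables = {k: s for k, s in self.tables.items() if k[0] in keep_set}
        meta = {k: m for k, m in self.table_meta.items() if k[0] in keep_set}
        return CredalNetwork(variables, parents, tables, name=self.name, table_meta=meta)


@dataclass(frozen=True)
class ValidationReport:
    ok: bool
    problems: tuple[str, ...]

    def __str__(self) -> str:
        if self.ok:
            return "network valid"
        return "network invalid:\n" + "\n".join(f"  - {p}" for p in self.problems)


def validate_network(net: CredalNetwork) -> ValidationReport:
    """Full structural and probabilistic validation; never raises.

    Checks acyclicity, table completeness (exactly one credal set per
    (variable, parent configuration)), interval coherence and polytope
    feasibility, reporting every failure with its table address.
    """
    problems: list[str] = []
    g = net.graph()
    if not nx.is_directed_acyclic_graph(g):
        cycle = nx.find_cycle(g)
        problems.append(
            "cycle: " + " -> ".join([edge[0] for edge in cycle] + [cycle[0][0]])
        )

    expected = {(v, cfg) for v in net.variables for cfg in net.parent_configs(v)}
    present = set(net.tables)
    for v, cfg in sorted(expected - present):
        problems.append(f"missing table for {v!r} given {cfg!r}")
    for v, cfg in sorted(present - expected):
        problems.append(f"unexpected table address {v!r} given {cfg!r}")

    for (v, cfg) in sorted(expected & present):
        spec = net.tables[(v, cfg)]
        k = net.state_spaces[v].cardinality
        if spec.k != k:
            problems.append(
                f"table {v!r}|{cfg!r}: {spec.k} entries for {k} states"
            )
            continue
        rep = check_coherence(spec.base)
        if not rep.ok:
            problems.append(f"table {v!r}|{cfg!r}: " + "; ".join(rep.violations))
        elif not spec.is_feasible():
            problems.append(f"table {v!r}|{cfg!r}: empty credal set")
    return ValidationReport(ok=not problems, problems=tuple(problems))
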