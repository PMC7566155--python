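"""Exact and bounded inference on credal networks.

Queries
-------
* :func:`bayesian_posterior` — exact posterior on a point-valued network
  (``l = u`` everywhere) by variable elimination; the oracle every credal
  query degenerates to.
* :func:`posterior_bounds` — lower/upper posterior probability under the
  *strong extension*: the min/max of the Bayesian posterior over every
  combination of one extreme point per (variable, parent-configuration)
  credal set.  Interventions (``do``) are handled by graph mutilation
  before optimisation.
* :func:`impact` — the study's effect statistic: differences of *lower*
  posteriors of the target across states of a manipulated variable,
  reported in percentage points.

The posterior is a ratio of forms that are multilinear in the per-row
distribution choices, so its extrema over the strong extension are
attained at extreme points; optimising over vertex combinations is
therefore exact.  When the combination count exceeds the configured
budget, a seeded multi-restart steepest-descent over single-vertex swaps
is used instead and the result is flagged ``exact=False`` (an inner
approximation: never wider than the true interval).

Evidence with zero probability: if *every* admissible distribution gives
the evidence probability zero the query fails with
:class:`~credalpod.exceptions.ConditioningError`; if only some do, the
optimisation runs over the remaining combinations (regular-extension
behaviour) and the result is flagged ``regular_extension=True``.
"""

from __future__ import annotations

import itertools
import math
import string
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .core import CredalNetwork, ParentConfig
from .exceptions import ConditioningError, StructuralError

#: Default cap on exact strong-extension enumeration (vertex combinations).
DEFAULT_EXACT_BUDGET = 20_000
#: Default number of seeded restarts for the local-search fallback.
DEFAULT_RESTARTS = 8

_EPS_IMPROVE = 1e-14


def _check_assignment(net: CredalNetwork, assignment: Mapping[str, str]) -> dict[str, str]:
    out: dict[str, str] = {}
    for var, state in (assignment or {}).items():
        net.states(var)  # raises for unknown variables
        net.state_spaces[var].index(state)
        out[var] = state
    return out


# ---------------------------------------------------------------------------
# Variable elimination engine (compiled once per query shape, cheap to re-run)
# ---------------------------------------------------------------------------

class _Engine:
    """Compiled sum-product schedule for one (network, evidence, target).

    ``target=None`` computes the evidence probability P(e) instead of the
    joint vector P(target, e).
    """

    def __init__(
        self,
        order: Sequence[str],
        cards: Mapping[str, int],
        parents: Mapping[str, tuple[str, ...]],
        evidence_idx: Mapping[str, int],
        target: str | None,
    ) -> None:
        self.order = tuple(order)
        self.dims = {v: parents[v] + (v,) for v in order}
        self.evidence_idx = dict(evidence_idx)
        self.target = target
        letters = {v: string.ascii_letters[i] for i, v in enumerate(order)}

        scopes: dict[int, tuple[str, ...]] = {}
        for slot, v in enumerate(order):
            scopes[slot] = tuple(d for d in self.dims[v] if d not in evidence_idx)

        elim = [v for v in order if v not in evidence_idx and v != target]
        # Greedy min-weight elimination order, alphabetical tie-break.
        elim_order: list[str] = []
        remaining = set(elim)
        live = dict(scopes)
        while remaining:
            best_v, best_w = None, None
            for v in sorted(remaining):
                scope_union: set[str] = set()
                for s in live.values():
                    if v in s:
                        scope_union |= set(s)
                w = math.prod(cards[x] for x in scope_union)
                if best_w is None or w < best_w:
                    best_v, best_w = v, w
            elim_order.append(best_v)
            remaining.discard(best_v)
            merged: set[str] = set()
            for slot in [s for s, sc in live.items() if best_v in sc]:
                merged |= set(live.pop(slot))
            live[-len(elim_order)] = tuple(x for x in merged if x != best_v)

        # Re-simulate to record einsum steps with concrete slot ids.
        self.steps: list[tuple[tuple[int, ...], str, int]] = []
        pool = dict(scopes)
        next_slot = len(order)
        for v in elim_order:
            group = tuple(sorted(s for s, sc in pool.items() if v in sc))
            union: list[str] = []
            for s in group:
                for x in pool[s]:
                    if x not in union:
                        union.append(x)
            out_scope = tuple(x for x in union if x != v)
            expr = (
                ",".join("".join(letters[x] for x in pool[s]) for s in group)
                + "->"
                + "".join(letters[x] for x in out_scope)
            )
            for s in group:
                del pool[s]
            pool[next_slot] = out_scope
            self.steps.append((group, expr, next_slot))
            next_slot += 1

        # Final combination of every remaining factor.
        final_slots = tuple(sorted(pool))
        out_scope = (target,) if target is not None else ()
        expr = (
            ",".join("".join(letters[x] for x in pool[s]) for s in final_slots)
            + "->"
            + "".join(letters[x] for x in out_scope)
        )
        self.final = (final_slots, expr)

    def slice_cpts(self, cpts: Mapping[str, np.ndarray]) -> list[np.ndarray]:
        """Instantiate evidence once, yielding one factor per variable slot."""
        factors = []
        for v in self.order:
            idx = tuple(
                self.evidence_idx[d] if d in self.evidence_idx else slice(None)
                for d in self.dims[v]
            )
            factors.append(np.array(cpts[v][idx]))  # copy; keeps 0-d shape
        return factors

    def eval(self, cpts: Mapping[str, np.ndarray]) -> np.ndarray | float:
        return self.eval_factors(self.slice_cpts(cpts))

    def eval_factors(self, factors: Sequence[np.ndarray]) -> np.ndarray | float:
        slots: dict[int, np.ndarray] = dict(enumerate(factors))
        for group, expr, out in self.steps:
            slots[out] = np.einsum(expr, *(slots[s] for s in group))
            for s in group:
                del slots[s]
        group, expr = self.final
        return np.einsum(expr, *(slots[s] for s in group))


def _ancestral_closure(net: CredalNetwork, roots: set[str]) -> set[str]:
    g = net.graph()
    keep = set(roots)
    for v in roots:
        keep |= nx.ancestors(g, v)
    return keep


def _point_cpts(net: CredalNetwork) -> dict[str, np.ndarray]:
    """CPT arrays (parents..., child) using each set's single distribution."""
    cpts: dict[str, np.ndarray] = {}
    for v in net.variables:
        shape = tuple(net.state_spaces[p].cardinality for p in net.parents[v]) + (
            net.state_spaces[v].cardinality,
        )
        arr = np.empty(shape)
        for cfg in net.parent_configs(v):
            idx = tuple(
                net.state_spaces[p].index(s) for p, s in zip(net.parents[v], cfg)
            )
            spec = net.tables[(v, cfg)]
            arr[idx] = (spec.base.lower + spec.base.upper) / 2.0
        cpts[v] = arr
    return cpts


def bayesian_posterior(
    net: CredalNetwork,
    target_var: str,
    target_state: str,
    evidence: Mapping[str, str] | None = None,
) -> float:
    """Exact posterior P(target_state | evidence) on a point-valued network."""
    if not net.is_point_valued:
        raise StructuralError(
            "bayesian_posterior requires a point-valued (l = u) network; "
            "use posterior_bounds for credal tables"
        )
    evidence = _check_assignment(net, evidence or {})
    t_idx = net.state_spaces[target_var].index(target_state)

    keep = _ancestral_closure(net, {target_var, *evidence})
    sub = net.restrict_to(keep)
    order = sub.topological_order()
    cards = {v: sub.state_spaces[v].cardinality for v in order}
    ev_idx = {v: sub.state_spaces[v].index(s) for v, s in evidence.items()}
    cpts = _point_cpts(sub)

    if target_var in evidence:
        engine = _Engine(order, cards, sub.parents, ev_idx, None)
        p_e = float(engine.eval(cpts))
        if p_e <= 0.0:
            raise ConditioningError("evidence has probability zero")
        return 1.0 if evidence[target_var] == target_state else 0.0

    engine = _Engine(order, cards, sub.parents, ev_idx, target_var)
    vec = np.asarray(engine.eval(cpts))
    p_e = float(vec.sum())
    if p_e <= 0.0:
        raise ConditioningError("evidence has probability zero")
    return float(vec[t_idx] / p_e)


# ---------------------------------------------------------------------------
# Strong-extension bounds
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BoundResult:
    """An interval-valued posterior [lower, upper] with provenance flags."""

    lower: float
    upper: float
    exact: bool
    n_extreme_combinations: float
    regular_extension: bool = False
    method: str = "enumeration"

    def __post_init__(self) -> None:
        if not (-1e-9 <= self.lower <= self.upper <= 1 + 1e-9):
            raise StructuralError(
                f"invalid bounds [{self.lower}, {self.upper}]"
            )

    def __str__(self) -> str:
        flag = "" if self.exact else " (inner approximation)"
        reg = " [regular extension]" if self.regular_extension else ""
        return f"[{self.lower:.4f}, {self.upper:.4f}]{flag}{reg}"


@dataclass
class _ChoiceRow:
    var: str
    slot: int
    write_idx: tuple[int, ...]
    values: list  # one payload (state vector, or scalar if the child is observed) per vertex


class _BoundsProblem:
    """One strong-extension optimisation: shared setup for both bounds."""

    def __init__(
        self,
        net: CredalNetwork,
        target_var: str,
        target_state: str,
        evidence: Mapping[str, str],
        do: Mapping[str, str],
    ) -> None:
        overlap = set(evidence) & set(do)
        if overlap:
            raise StructuralError(
                f"variables {sorted(overlap)} appear in both evidence and do"
            )
        mutilated = net.mutilate(do)
        ev_all = {**evidence, **do}
        keep = _ancestral_closure(mutilated, {target_var, *ev_all})
        sub = mutilated.restrict_to(keep)
        ev_all = {v: s for v, s in ev_all.items() if v in keep}

        self.sub = sub
        self.target_var = target_var
        self.t_idx = sub.state_spaces[target_var].index(target_state)
        self.target_observed = target_var in ev_all
        self.trivial_value = (
            None
            if not self.target_observed
            else (1.0 if ev_all[target_var] == target_state else 0.0)
        )

        order = sub.topological_order()
        cards = {v: sub.state_spaces[v].cardinality for v in order}
        ev_idx = {v: sub.state_spaces[v].index(s) for v, s in ev_all.items()}
        self.engine = _Engine(
            order, cards, sub.parents, ev_idx,
            None if self.target_observed else target_var,
        )

        # Base CPTs (every row at its first vertex), instantiated against the
        # evidence once; vertex swaps then write into the sliced factors.
        cpts: dict[str, np.ndarray] = {}
        pending: list[tuple[str, tuple[int, ...], np.ndarray]] = []
        do_vars = set(do)
        for v in order:
            shape = tuple(cards[p] for p in sub.parents[v]) + (cards[v],)
            arr = np.empty(shape)
            for cfg in sub.parent_configs(v):
                idx = tuple(
                    sub.state_spaces[p].index(s)
                    for p, s in zip(sub.parents[v], cfg)
                )
                spec = sub.tables[(v, cfg)]
                if spec.is_point:
                    arr[idx] = spec.base.lower
                    continue
                verts = spec.vertices()
                arr[idx] = verts[0]
                if v in do_vars:
                    continue
                # Rows contradicting observed parent states never enter the
                # sliced factors; they are not optimisation choices.
                consistent = all(
                    s == ev_all[p]
                    for p, s in zip(sub.parents[v], cfg)
                    if p in ev_all
                )
                if consistent and len(verts) > 1:
                    pending.append((v, idx, verts))
            cpts[v] = arr
        self.factors = self.engine.slice_cpts(cpts)

        # The target's own rows are separable when the target is unobserved
        # and childless in the pruned graph: the posterior is a mixture over
        # parent configurations whose weights do not involve those rows, so
        # each row independently takes its extreme value per side.
        self.separable = (not self.target_observed) and not any(
            target_var in sub.parents[v] for v in order
        )

        slot_of = {v: i for i, v in enumerate(order)}
        self.rows: list[_ChoiceRow] = []
        self.target_rows: list[_ChoiceRow] = []
        for v, idx, verts in pending:
            unobserved = [
                i for i, p in enumerate(sub.parents[v]) if p not in ev_all
            ]
            write_idx = tuple(idx[i] for i in unobserved)
            if v in ev_all:
                # Only the observed state's probability enters the factor;
                # vertices agreeing there are one and the same choice.
                e = sub.state_spaces[v].index(ev_all[v])
                values: list = []
                for vert in verts:
                    val = float(vert[e])
                    if not any(abs(val - x) <= 1e-12 for x in values):
                        values.append(val)
            else:
                values = [vert.copy() for vert in verts]
            if len(values) > 1:
                row = _ChoiceRow(v, slot_of[v], write_idx, values)
                if self.separable and v == target_var:
                    self.target_rows.append(row)
                else:
                    self.rows.append(row)

        self.n_search = float(math.prod(len(r.values) for r in self.rows))
        self.n_comb = self.n_search * float(
            math.prod(len(r.values) for r in self.target_rows)
        )
        self.saw_zero_evidence = False

    # -- evaluation --------------------------------------------------------

    def _eval(self) -> float | None:
        """Posterior at the current vertex choice; None if P(e) = 0."""
        out = self.engine.eval_factors(self.factors)
        if self.target_observed:
            p_e = float(out)
            if p_e <= 0.0:
                return None
            return self.trivial_value
        vec = np.asarray(out)
        p_e = float(vec.sum())
        if p_e <= 0.0:
            return None
        return float(vec[self.t_idx] / p_e)

    def _set(self, row: _ChoiceRow, vertex_index: int) -> None:
        self.factors[row.slot][row.write_idx] = row.values[vertex_index]

    def _preset_target_rows(self, sense: str) -> None:
        pick = np.argmin if sense == "min" else np.argmax
        for row in self.target_rows:
            scores = [v[self.t_idx] for v in row.values]
            self._set(row, int(pick(scores)))

    # -- exact enumeration -------------------------------------------------

    def _enumerate_side(self, sense: str) -> float:
        self._preset_target_rows(sense)
        best = np.inf if sense == "min" else -np.inf
        ranges = [range(len(r.values)) for r in self.rows]
        for choice in itertools.product(*ranges):
            for row, ci in zip(self.rows, choice):
                self._set(row, ci)
            val = self._eval()
            if val is None:
                self.saw_zero_evidence = True
                continue
            best = min(best, val) if sense == "min" else max(best, val)
        if not np.isfinite(best):
            raise ConditioningError(
                "evidence has probability zero for every admissible distribution"
            )
        return float(best)

    def enumerate_bounds(self) -> tuple[float, float]:
        return self._enumerate_side("min"), self._enumerate_side("max")

    # -- local search ------------------------------------------------------

    def search_bound(self, sense: str, restarts: int, rng: np.random.Generator) -> float:
        """Steepest-descent over single-vertex swaps, multi-restart.

        ``sense`` is "min" or "max".  Deterministic given the generator
        state: rows and vertices are scanned in fixed order and ties keep
        the first-found neighbour.
        """
        sign = 1.0 if sense == "min" else -1.0
        self._preset_target_rows(sense)
        best_overall = np.inf
        for _ in range(restarts):
            choice = [int(rng.integers(len(r.values))) for r in self.rows]
            for row, ci in zip(self.rows, choice):
                self._set(row, ci)
            val = self._eval()
            tries = 0
            while val is None and tries < 50:
                self.saw_zero_evidence = True
                choice = [int(rng.integers(len(r.values))) for r in self.rows]
                for row, ci in zip(self.rows, choice):
                    self._set(row, ci)
                val = self._eval()
                tries += 1
            if val is None:
                continue
            current = sign * val
            improved = True
            while improved:
                improved = False
                best_move: tuple[int, int, float] | None = None
                for ri, row in enumerate(self.rows):
                    for vi in range(len(row.values)):
                        if vi == choice[ri]:
                            continue
                        self._set(row, vi)
                        cand = self._eval()
                        self._set(row, choice[ri])
                        if cand is None:
                            self.saw_zero_evidence = True
                            continue
                        cand_obj = sign * cand
                        if cand_obj < current - _EPS_IMPROVE and (
                            best_move is None or cand_obj < best_move[2]
                        ):
                            best_move = (ri, vi, cand_obj)
                if best_move is not None:
                    ri, vi, cand_obj = best_move
                    choice[ri] = vi
                    self._set(self.rows[ri], vi)
                    current = cand_obj
                    improved = True
            best_overall = min(best_overall, current)
        if not np.isfinite(best_overall):
            raise ConditioningError(
                "local search found no vertex combination giving the evidence "
                "positive probability"
            )
        return float(sign * best_overall)


def posterior_bounds(
    net: CredalNetwork,
    target_var: str,
    target_state: str,
    evidence: Mapping[str, str] | None = None,
    do: Mapping[str, str] | None = None,
    *,
    budget: int = DEFAULT_EXACT_BUDGET,
    restarts: int = DEFAULT_RESTARTS,
    seed: int = 0,
) -> BoundResult:
    """Lower/upper posterior P(target | evidence, do) under the strong extension."""
    evidence = _check_assignment(net, evidence or {})
    do = _check_assignment(net, do or {})
    net.state_spaces[target_var].index(target_state)

    prob = _BoundsProblem(net, target_var, target_state, evidence, do)
    if prob.n_search <= budget:
        lo, hi = prob.enumerate_bounds()
        return BoundResult(
            lower=lo,
            upper=hi,
            exact=True,
            n_extreme_combinations=prob.n_comb,
            regular_extension=prob.saw_zero_evidence,
            method="enumeration",
        )
    ss = np.random.SeedSequence(seed)
    rng_lo, rng_hi = (np.random.default_rng(c) for c in ss.spawn(2))
    lo = prob.search_bound("min", restarts, rng_lo)
    hi = prob.search_bound("max", restarts, rng_hi)
    return BoundResult(
        lower=min(lo, hi),
        upper=max(lo, hi),
        exact=False,
        n_extreme_combinations=prob.n_comb,
        regular_extension=prob.saw_zero_evidence,
        method="local-search",
    )


def lower_posterior(
    net: CredalNetwork,
    target_var: str,
    target_state: str,
    evidence: Mapping[str, str] | None = None,
    do: Mapping[str, str] | None = None,
    *,
    budget: int = DEFAULT_EXACT_BUDGET,
    restarts: int = DEFAULT_RESTARTS,
    seed: int = 0,
) -> tuple[float, bool]:
    """Lower bound only (half the work of :func:`posterior_bounds`).

    Returns ``(lower, exact)``.
    """
    evidence = _check_assignment(net, evidence or {})
    do = _check_assignment(net, do or {})
    prob = _BoundsProblem(net, target_var, target_state, evidence, do)
    if prob.n_search <= budget:
        lo = prob._enumerate_side("min")
        return lo, True
    rng = np.random.default_rng(np.random.SeedSequence(seed).spawn(1)[0])
    return prob.search_bound("min", restarts, rng), False


# ---------------------------------------------------------------------------
# Impact statistic
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ImpactResult:
    """Differences in lower posterior probability across manipulated states.

    ``points`` is the headline impact — the maximum absolute pairwise
    difference of lower bounds, in percentage points; ``display_points``
    rounds it to the nearest whole point (reporting style), while the raw
    value keeps full precision.
    """

    target_var: str
    target_state: str
    variable: str
    mode: str
    lowers: Mapping[str, float]
    pairs: pd.DataFrame = field(repr=False)
    points: float = 0.0
    exact: bool = True

    @property
    def display_points(self) -> int:
        return int(math.floor(self.points + 0.5))


def impact(
    net: CredalNetwork,
    target_var: str,
    target_state: str,
    variable: str,
    mode: str = "observe",
    evidence: Mapping[str, str] | None = None,
    *,
    budget: int = DEFAULT_EXACT_BUDGET,
    restarts: int = DEFAULT_RESTARTS,
    seed: int = 0,
) -> ImpactResult:
    """Impact of a manipulated variable on the lower posterior of the target.

    For every ordered pair of states (a, a') of ``variable`` computes
    ``lower P(target | A=a) - lower P(target | A=a')`` (conditioning in
    "observe" mode, graph mutilation in "do" mode), on top of any shared
    background ``evidence``.  The headline figure is the maximum absolute
    difference, scaled to percentage points.
    """
    if mode not in ("observe", "do"):
        raise StructuralError(f"impact mode must be 'observe' or 'do', got {mode!r}")
    if variable == target_var:
        raise StructuralError("manipulated variable cannot be the target")
    evidence = _check_assignment(net, evidence or {})
    if variable in evidence:
        raise StructuralError(
            f"manipulated variable {variable!r} already fixed by evidence"
        )

    lowers: dict[str, float] = {}
    all_exact = True
    for i, state in enumerate(net.states(variable)):
        if mode == "do":
            lo, ex = lower_posterior(
                net, target_var, target_state, evidence, {variable: state},
                budget=budget, restarts=restarts, seed=seed + i,
            )
        else:
            ev = {**evidence, variable: state}
            lo, ex = lower_posterior(
                net, target_var, target_state, ev, None,
                budget=budget, restarts=restarts, seed=seed + i,
            )
        lowers[state] = lo
        all_exact &= ex

    records = [
        {"state_a": a, "state_b": b, "difference": lowers[a] - lowers[b]}
        for a in lowers
        for b in lowers
        if a != b
    ]
    pairs = pd.DataFrame(records, columns=["state_a", "state_b", "difference"])
    headline = 100.0 * (max(abs(r["difference"]) for r in records) if records else 0.0)
    return ImpactResult(
        target_var=target_var,
        target_state=target_state,
        variable=variable,
        mode=mode,
        lowers=lowers,
        pairs=pairs,
        points=headline,
        exact=all_exact,
    )
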