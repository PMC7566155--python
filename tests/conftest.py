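"""Shared fixtures and independent oracles.

The oracles here deliberately avoid the package's own inference paths:
joint probabilities come from a full tensor product over every variable
(no elimination), and credal bounds from explicit enumeration of vertex
combinations against that joint.
"""

from __future__ import annotations

import itertools
import math
import string

import numpy as np
import pytest

from credalpod.core import (
    CredalNetwork,
    CredalSetSpec,
    IntervalDistribution,
    StateSpace,
)


def interval_net(tables: dict, parents: dict, spaces: list[StateSpace]) -> CredalNetwork:
    return CredalNetwork(spaces, parents, tables)


@pytest.fixture(scope="session")
def toy_net() -> CredalNetwork:
    """Two-node chain A -> B with interval tables.

    P(a1) in [0.4, 0.6], P(b1|a1) in [0.7, 0.9], P(b1|a2) in [0.1, 0.3].
    """
    A = StateSpace("A", ("a1", "a2"))
    B = StateSpace("B", ("b1", "b2"))
    iv = lambda l, u: CredalSetSpec(IntervalDistribution(l, u))
    return CredalNetwork(
        [A, B],
        {"B": ("A",)},
        {
            ("A", ()): iv([0.4, 0.4], [0.6, 0.6]),
            ("B", ("a1",)): iv([0.7, 0.1], [0.9, 0.3]),
            ("B", ("a2",)): iv([0.1, 0.7], [0.3, 0.9]),
        },
    )


@pytest.fixture(scope="session")
def point_chain() -> CredalNetwork:
    """Point-valued chain: P(a1)=0.5, P(b1|a1)=0.8, P(b1|a2)=0.2."""
    A = StateSpace("A", ("a1", "a2"))
    B = StateSpace("B", ("b1", "b2"))
    return CredalNetwork(
        [A, B],
        {"B": ("A",)},
        {
            ("A", ()): CredalSetSpec.from_point([0.5, 0.5]),
            ("B", ("a1",)): CredalSetSpec.from_point([0.8, 0.2]),
            ("B", ("a2",)): CredalSetSpec.from_point([0.2, 0.8]),
        },
    )


@pytest.fixture(scope="session")
def reference_model():
    from credalpod.pod_model import load_reference_model

    return load_reference_model()


@pytest.fixture(scope="session")
def summary_cohort():
    from credalpod.cohort import generate_marginal_cohort

    return generate_marginal_cohort(seed=20)


# ---------------------------------------------------------------------------
# Oracles
# ---------------------------------------------------------------------------

def full_joint(net: CredalNetwork, cpts: dict[str, np.ndarray]) -> np.ndarray:
    """Joint array over all variables via one big tensor product (no VE)."""
    order = list(net.variables)
    letters = {v: string.ascii_letters[i] for i, v in enumerate(order)}
    inputs = []
    for v in order:
        dims = net.parents[v] + (v,)
        inputs.append("".join(letters[d] for d in dims))
    expr = ",".join(inputs) + "->" + "".join(letters[v] for v in order)
    return np.einsum(expr, *(cpts[v] for v in order))


def oracle_posterior(
    net: CredalNetwork,
    cpts: dict[str, np.ndarray],
    target_var: str,
    target_state: str,
    evidence: dict[str, str] | None = None,
) -> float | None:
    """Posterior from the full joint; None when P(evidence) = 0."""
    evidence = evidence or {}
    joint = full_joint(net, cpts)
    order = list(net.variables)
    idx = [slice(None)] * len(order)
    for var, state in evidence.items():
        idx[order.index(var)] = net.state_spaces[var].index(state)
    cond = joint[tuple(idx)]
    axes_left = [v for v in order if v not in evidence]
    p_e = float(cond.sum())
    if p_e <= 0.0:
        return None
    if target_var in evidence:
        return 1.0 if evidence[target_var] == target_state else 0.0
    t_axis = axes_left.index(target_var)
    marg = cond.sum(axis=tuple(i for i in range(cond.ndim) if i != t_axis))
    return float(marg[net.state_spaces[target_var].index(target_state)] / p_e)


def table_rows(net: CredalNetwork):
    for v in net.variables:
        for cfg in net.parent_configs(v):
            yield v, cfg


def cpts_from_choice(net: CredalNetwork, choice: dict) -> dict[str, np.ndarray]:
    """Assemble CPT arrays from one distribution per (variable, config)."""
    cpts = {}
    for v in net.variables:
        shape = tuple(net.state_spaces[p].cardinality for p in net.parents[v]) + (
            net.state_spaces[v].cardinality,
        )
        arr = np.empty(shape)
        for cfg in net.parent_configs(v):
            idx = tuple(
                net.state_spaces[p].index(s) for p, s in zip(net.parents[v], cfg)
            )
            arr[idx] = choice[(v, cfg)]
        cpts[v] = arr
    return cpts


def brute_force_bounds(
    net: CredalNetwork,
    target_var: str,
    target_state: str,
    evidence: dict[str, str] | None = None,
    do: dict[str, str] | None = None,
) -> tuple[float, float]:
    """Exhaustive min/max over every combination of table vertices."""
    work = net.mutilate(do) if do else net
    evidence = {**(evidence or {}), **(do or {})}
    keys = list(table_rows(work))
    vertex_lists = [work.tables[k].vertices() for k in keys]
    lo, hi = np.inf, -np.inf
    for combo in itertools.product(*vertex_lists):
        cpts = cpts_from_choice(work, dict(zip(keys, combo)))
        val = oracle_posterior(work, cpts, target_var, target_state, evidence)
        if val is None:
            continue
        lo, hi = min(lo, val), max(hi, val)
    return float(lo), float(hi)


# ---------------------------------------------------------------------------
# Random-network generator for property and acceptance tests
# ---------------------------------------------------------------------------

def random_interval_row(k: int, rng: np.random.Generator, width: float = 0.3):
    p = rng.dirichlet(np.ones(k))
    half = rng.uniform(0.0, width / 2, size=k)
    lower = np.clip(p - half, 0.0, 1.0)
    upper = np.clip(p + half, 0.0, 1.0)
    return CredalSetSpec(IntervalDistribution(lower, upper))


def random_network(
    rng: np.random.Generator,
    n_nodes: int = 4,
    max_card: int = 3,
    point_only: bool = False,
    max_interval_rows: int = 6,
) -> CredalNetwork:
    """Random DAG (nodes in topological order, <=2 parents) with random tables."""
    names = [f"X{i}" for i in range(n_nodes)]
    spaces = [
        StateSpace(n, tuple(f"s{j}" for j in range(rng.integers(2, max_card + 1))))
        for n in names
    ]
    parents: dict[str, tuple[str, ...]] = {}
    for i, n in enumerate(names):
        if i == 0:
            parents[n] = ()
            continue
        k = int(rng.integers(0, min(2, i) + 1))
        parents[n] = tuple(
            names[j] for j in sorted(rng.choice(i, size=k, replace=False))
        )
    net_spaces = {s.name: s for s in spaces}
    tables: dict = {}
    interval_budget = 0 if point_only else max_interval_rows
    for n in names:
        k = net_spaces[n].cardinality
        for cfg in itertools.product(
            *[net_spaces[p].states for p in parents[n]]
        ):
            if interval_budget > 0 and rng.random() < 0.5:
                tables[(n, cfg)] = random_interval_row(k, rng)
                interval_budget -= 1
            else:
                tables[(n, cfg)] = CredalSetSpec.from_point(rng.dirichlet(np.ones(k)))
    return CredalNetwork(spaces, parents, tables)
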