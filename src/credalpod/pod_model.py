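"""The packaged place-of-death reference network and its scenario layer.

The network reconstructs the *structure* of the expert-elicited causal
model from the underlying chart-review study: anticancer treatment gates
end-of-life communication, which drives patient and family awareness of
dying; awareness gates whether preferences get assessed; symptom burden
and treatment drive hospital days; family circumstances determine the
family's preference for the last place of care; and place of death
depends on both preferences, hospital days, the home-care network and
the area of residence.

The *numbers* in the shipped tables are illustrative fixtures chosen to
be qualitatively consistent with that study's narrative (the family
preference exerting the largest influence on place of death, and so on).
The elicited intervals themselves were never published, so every table
carries ``provenance: "illustrative"`` and lives in a data file —
recovering the true values later requires no code change.  Scenario
files annotate the study's headline impact figures as
``reference_impact_pct`` so reports can print the packaged-model value
beside them; they are context, not assertions.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from ._version import __version__
from .cohort import default_dictionary
from .config import RunConfig
from .core import CredalNetwork, validate_network
from .exceptions import ParseError, ScenarioError, ValidationError
from .inference import impact, posterior_bounds
from .io import parse_network_obj

TARGET_VARIABLE = "place_of_death"


@dataclass(frozen=True)
class ReferenceModel:
    """A validated POD network whose tables all carry provenance labels."""

    net: CredalNetwork
    description: str = ""

    @property
    def provenance(self) -> dict:
        return {key: m.get("provenance") for key, m in self.net.table_meta.items()}


def _check_reference(net: CredalNetwork) -> None:
    report = validate_network(net)
    if not report.ok:
        raise ValidationError(str(report))
    if any(net.parents.get(v) and TARGET_VARIABLE in net.parents[v] for v in net.variables):
        raise ValidationError(f"{TARGET_VARIABLE} must have no children")
    dictionary = default_dictionary()
    for v in net.variables:
        if v in dictionary:
            expected = dictionary.column(v).states
            if tuple(net.states(v)) != tuple(expected):
                raise ValidationError(
                    f"variable {v!r} states {list(net.states(v))} differ from "
                    f"the cohort dictionary {list(expected)}"
                )
    for v in net.variables:
        for cfg in net.parent_configs(v):
            if "provenance" not in net.table_meta.get((v, cfg), {}):
                raise ValidationError(
                    f"table {v!r} given {cfg!r} lacks a provenance label"
                )


def load_reference_model(path: str | Path | None = None) -> ReferenceModel:
    """Load and fully validate the packaged (or a user-supplied) POD network."""
    if path is None:
        with resources.files("credalpod.data").joinpath("pod-reference.json").open() as fh:
            obj = json.load(fh)
    else:
        obj = json.loads(Path(path).read_text())
    if not isinstance(obj, dict):
        raise ParseError("network file must contain a JSON object")
    net = parse_network_obj(obj)
    _check_reference(net)
    return ReferenceModel(net=net, description=getattr(net, "description", ""))


# ---------------------------------------------------------------------------
# Scenarios
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ImpactRequest:
    variable: str
    mode: str = "observe"
    reference_impact_pct: float | None = None
    note: str = ""


@dataclass(frozen=True)
class QuerySpec:
    name: str
    evidence: Mapping[str, str] = field(default_factory=dict)
    do: Mapping[str, str] = field(default_factory=dict)


@dataclass(frozen=True)
class ScenarioSpec:
    """A named bundle of queries against the reference model."""

    name: str
    target_variable: str
    target_state: str
    description: str = ""
    evidence: Mapping[str, str] = field(default_factory=dict)
    do: Mapping[str, str] = field(default_factory=dict)
    queries: tuple[QuerySpec, ...] = ()
    impacts: tuple[ImpactRequest, ...] = ()

    @classmethod
    def from_obj(cls, obj: Mapping) -> "ScenarioSpec":
        return cls(
            name=obj["name"],
            description=obj.get("description", ""),
            target_variable=obj["target"]["variable"],
            target_state=obj["target"]["state"],
            evidence=dict(obj.get("evidence", {})),
            do=dict(obj.get("do", {})),
            queries=tuple(
                QuerySpec(
                    name=q["name"],
                    evidence=dict(q.get("evidence", {})),
                    do=dict(q.get("do", {})),
                )
                for q in obj.get("queries", ())
            ),
            impacts=tuple(
                ImpactRequest(
                    variable=i["variable"],
                    mode=i.get("mode", "observe"),
                    reference_impact_pct=i.get("reference_impact_pct"),
                    note=i.get("note", ""),
                )
                for i in obj.get("impacts", ())
            ),
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "ScenarioSpec":
        return cls.from_obj(json.loads(Path(path).read_text()))

    def validate_against(self, net: CredalNetwork) -> None:
        self._merge(self.evidence, self.do)  # conflict check
        for var, state in {**self.evidence, **self.do}.items():
            net.state_spaces[var].index(state)
        net.state_spaces[self.target_variable].index(self.target_state)
        for q in self.queries:
            ev = self._merge(self.evidence, q.evidence)
            do = self._merge(self.do, q.do)
            self._merge(ev, do)
            for var, state in {**ev, **do}.items():
                net.state_spaces[var].index(state)
        for imp in self.impacts:
            net.states(imp.variable)
            if imp.mode not in ("observe", "do"):
                raise ScenarioError(f"impact mode {imp.mode!r} invalid")
            if imp.variable == self.target_variable:
                raise ScenarioError("impact variable cannot be the target")
            if self.do:
                raise ScenarioError(
                    "impacts are not combined with scenario-level do-assignments"
                )

    @staticmethod
    def _merge(a: Mapping[str, str], b: Mapping[str, str]) -> dict[str, str]:
        out = dict(a)
        for var, state in b.items():
            if var in out and out[var] != state:
                raise ScenarioError(
                    f"variable {var!r} assigned two states ({out[var]!r}, {state!r})"
                )
            out[var] = state
        return out


def scenario_names() -> list[str]:
    base = resources.files("credalpod.data").joinpath("scenarios")
    return sorted(p.name[: -len(".json")] for p in base.iterdir() if p.name.endswith(".json"))


def load_scenario(name: str) -> ScenarioSpec:
    """Load a packaged scenario by name, or any scenario JSON by path."""
    p = Path(name)
    if p.suffix == ".json" and p.exists():
        return ScenarioSpec.from_json(p)
    base = resources.files("credalpod.data").joinpath("scenarios")
    f = base.joinpath(f"{name}.json")
    try:
        with f.open() as fh:
            return ScenarioSpec.from_obj(json.load(fh))
    except FileNotFoundError:
        raise ScenarioError(
            f"unknown scenario {name!r}; packaged scenarios: {scenario_names()}"
        ) from None


@dataclass
class ScenarioResult:
    scenario: str
    table: pd.DataFrame
    metadata: dict = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(
            {
                "scenario": self.scenario,
                "metadata": self.metadata,
                "rows": json.loads(self.table.to_json(orient="records")),
            },
            indent=1,
        )

    def __str__(self) -> str:
        return f"scenario {self.scenario!r}\n" + self.table.to_string(index=False)


def run_scenario(
    model: ReferenceModel | CredalNetwork,
    scenario: ScenarioSpec | str,
    config: RunConfig | None = None,
) -> ScenarioResult:
    """Run every query and impact request of a scenario.

    One result row per query (interval bounds) and per impact request
    (percentage points, with the study's narrative figure alongside when
    annotated).  Reproducible bit-for-bit for a fixed config.
    """
    net = model.net if isinstance(model, ReferenceModel) else model
    if isinstance(scenario, str):
        scenario = load_scenario(scenario)
    config = config or RunConfig()
    scenario.validate_against(net)

    rows: list[dict] = []
    queries = scenario.queries or (QuerySpec(name="target"),)
    for q in queries:
        ev = scenario._merge(scenario.evidence, q.evidence)
        do = scenario._merge(scenario.do, q.do)
        res = posterior_bounds(
            net,
            scenario.target_variable,
            scenario.target_state,
            ev,
            do,
            budget=config.exact_budget,
            restarts=config.restarts,
            seed=config.seed,
        )
        rows.append(
            {
                "query": q.name,
                "kind": "bounds",
                "mode": "do" if do else "observe",
                "detail": " ".join(
                    [f"{v}={s}" for v, s in ev.items()]
                    + [f"do({v}={s})" for v, s in do.items()]
                )
                or "(marginal)",
                "lower": res.lower,
                "upper": res.upper,
                "model_points": None,
                "reference_points": None,
                "exact": res.exact,
                "method": res.method,
            }
        )
    for i, imp in enumerate(scenario.impacts):
        res_i = impact(
            net,
            scenario.target_variable,
            scenario.target_state,
            imp.variable,
            mode=imp.mode,
            evidence=scenario.evidence,
            budget=config.exact_budget,
            restarts=config.restarts,
            seed=config.seed + 101 * (i + 1),
        )
        rows.append(
            {
                "query": f"impact[{imp.variable}]",
                "kind": "impact",
                "mode": imp.mode,
                "detail": imp.note or f"lower-bound spread across {imp.variable} states",
                "lower": None,
                "upper": None,
                "model_points": res_i.points,
                "reference_points": imp.reference_impact_pct,
                "exact": res_i.exact,
                "method": "impact",
            }
        )
    table = pd.DataFrame(
        rows,
        columns=[
            "query", "kind", "mode", "detail", "lower", "upper",
            "model_points", "reference_points", "exact", "method",
        ],
    )
    return ScenarioResult(
        scenario=scenario.name,
        table=table,
        metadata={
            "model": net.name,
            "seed": config.seed,
            "config_hash": config.hash(),
            "version": __version__,
        },
    )


def run_all_scenarios(
    model: ReferenceModel | None = None, config: RunConfig | None = None
) -> dict[str, ScenarioResult]:
    model = model or load_reference_model()
    return {name: run_scenario(model, name, config) for name in scenario_names()}
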