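"""Reading and writing the network JSON dialect.

Top-level keys: ``variables`` (name, states[]), ``arcs`` (child,
parents[]) and ``tables``.  A table addresses one (variable, parent
configuration) row via a ``parent_config`` map parent-name -> state and
carries either explicit ``lower``/``upper`` vectors (indexed by the
variable's canonical state order) or a list of expert ``judgments``
compiled at load time; optional ``orderings`` are pairs
``[state_more_probable, state_less_probable]`` and ``provenance`` is a
free-text label.  Parsing is schema-checked with pydantic and loss-free:
``serialize(parse(x))`` preserves every field.  A generated JSON-Schema
for the dialect ships as ``data/network-schema.json``.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional

import pydantic
from pydantic import BaseModel, Field

from .core import CredalNetwork, CredalSetSpec, IntervalDistribution, StateSpace
from .elicitation import VerbalScale, compile_judgments, judgments_from_obj
from .exceptions import ParseError, StructuralError


class VariableModel(BaseModel):
    name: str
    states: list[str] = Field(min_length=2)


class ArcModel(BaseModel):
    child: str
    parents: list[str]


class TableModel(BaseModel):
    variable: str
    parent_config: dict[str, str] = {}
    lower: Optional[list[float]] = None
    upper: Optional[list[float]] = None
    orderings: list[tuple[str, str]] = []
    judgments: list[dict] = []
    provenance: Optional[str] = None


class NetworkModel(BaseModel):
    name: str = ""
    description: str = ""
    #: Defaults applied to every table that does not override them
    #: (currently only "provenance" is meaningful).
    table_defaults: dict[str, str] = {}
    variables: list[VariableModel] = Field(min_length=1)
    arcs: list[ArcModel] = []
    tables: list[TableModel] = []


def network_json_schema() -> dict:
    return NetworkModel.model_json_schema()


def parse_network_obj(obj: dict, scale: VerbalScale | None = None) -> CredalNetwork:
    try:
        model = NetworkModel.model_validate(obj)
    except pydantic.ValidationError as exc:
        first = exc.errors()[0]
        pointer = "/" + "/".join(str(p) for p in first["loc"])
        raise ParseError(first["msg"], location=pointer) from exc

    variables = [StateSpace(v.name, tuple(v.states)) for v in model.variables]
    spaces = {v.name: v for v in variables}
    parents: dict[str, tuple[str, ...]] = {}
    for arc in model.arcs:
        if arc.child not in spaces:
            raise ParseError(f"arc child {arc.child!r} is not a declared variable")
        if arc.child in parents:
            raise ParseError(f"duplicate arc entry for child {arc.child!r}")
        parents[arc.child] = tuple(arc.parents)

    tables: dict[tuple[str, tuple[str, ...]], CredalSetSpec] = {}
    meta: dict[tuple[str, tuple[str, ...]], dict] = {}
    for i, t in enumerate(model.tables):
        where = f"/tables/{i}"
        if t.variable not in spaces:
            raise ParseError(f"table for unknown variable {t.variable!r}", where)
        ss = spaces[t.variable]
        declared = parents.get(t.variable, ())
        if set(t.parent_config) != set(declared):
            raise ParseError(
                f"parent_config keys {sorted(t.parent_config)} do not match "
                f"declared parents {list(declared)} of {t.variable!r}",
                where,
            )
        cfg = tuple(t.parent_config[p] for p in declared)
        key = (t.variable, cfg)
        if key in tables:
            raise ParseError(f"duplicate table for {t.variable!r} given {cfg!r}", where)
        try:
            orderings = tuple((ss.index(a), ss.index(b)) for a, b in t.orderings)
            if t.lower is not None or t.upper is not None:
                if t.lower is None or t.upper is None:
                    raise StructuralError("lower and upper must be given together")
                base = IntervalDistribution(t.lower, t.upper)
                spec = CredalSetSpec(base, orderings)
            elif t.judgments:
                spec = compile_judgments(judgments_from_obj(t.judgments), ss, scale)
                spec = CredalSetSpec(spec.base, spec.orderings + orderings)
            else:
                raise StructuralError(
                    "table needs lower/upper vectors or judgments"
                )
        except StructuralError as exc:
            raise ParseError(str(exc), where) from exc
        tables[key] = spec
        m: dict = {}
        if t.provenance is not None:
            m["provenance"] = t.provenance
        elif "provenance" in model.table_defaults:
            m["provenance"] = model.table_defaults["provenance"]
        if t.judgments:
            m["judgments"] = t.judgments
        meta[key] = m

    net = CredalNetwork(variables, parents, tables, name=model.name, table_meta=meta)
    net.description = model.description  # type: ignore[attr-defined]
    return net


def parse_network(path: str | Path, scale: VerbalScale | None = None) -> CredalNetwork:
    """Parse a network file; raises :class:`ParseError` with a JSON-pointer
    location on schema violations."""
    try:
        obj = json.loads(Path(path).read_text())
    except json.JSONDecodeError as exc:
        raise ParseError(f"invalid JSON in {path}: {exc}") from exc
    if not isinstance(obj, dict):
        raise ParseError(f"{path}: top level must be a JSON object")
    return parse_network_obj(obj)


def serialize_network_obj(net: CredalNetwork) -> dict:
    variables = [
        {"name": v, "states": list(net.states(v))} for v in net.variables
    ]
    arcs = [
        {"child": v, "parents": list(ps)}
        for v, ps in net.parents.items()
        if ps
    ]
    tables = []
    for v in net.variables:
        for cfg in net.parent_configs(v):
            key = (v, cfg)
            if key not in net.tables:
                continue
            spec = net.tables[key]
            ss = net.state_spaces[v]
            entry: dict = {
                "variable": v,
                "parent_config": dict(zip(net.parents[v], cfg)),
                "lower": [round(float(x), 12) for x in spec.base.lower],
                "upper": [round(float(x), 12) for x in spec.base.upper],
            }
            if spec.orderings:
                entry["orderings"] = [
                    [ss.states[a], ss.states[b]] for a, b in spec.orderings
                ]
            m = net.table_meta.get(key, {})
            if "provenance" in m:
                entry["provenance"] = m["provenance"]
            if "judgments" in m:
                entry["judgments"] = m["judgments"]
            tables.append(entry)
    obj = {
        "name": net.name,
        "description": getattr(net, "description", ""),
        "variables": variables,
        "arcs": arcs,
        "tables": tables,
    }
    return obj


def serialize_network(net: CredalNetwork, path: str | Path | None = None) -> str:
    text = json.dumps(serialize_network_obj(net), indent=1)
    if path is not None:
        Path(path).write_text(text + "\n")
    return text
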