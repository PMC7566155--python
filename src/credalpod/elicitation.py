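"""Turning expert judgments into credal sets.

Experts who cannot give a precise number can still say that an event is
"very probable", or that one outcome is more probable than another.  This
module maps such statements onto the interval/ordering credal sets of
:mod:`credalpod.core`:

* a *verbal* judgment looks a term up in a :class:`VerbalScale`;
* a *numeric-interval* judgment supplies ``[l, u]`` directly;
* a *comparative* judgment ``p(a) >= p(b)`` becomes an ordering constraint.

States about which nothing is said keep the vacuous interval ``[0, 1]``:
silence is modelled as ignorance, never as uniformity.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .core import CredalSetSpec, IntervalDistribution, StateSpace, normalize_reachable
from .exceptions import FeasibilityError, StructuralError

JUDGMENT_KINDS = ("numeric-interval", "verbal", "comparative")


@dataclass(frozen=True)
class VerbalScale:
    """An ordered mapping from verbal probability terms to intervals."""

    terms: tuple[tuple[str, tuple[float, float]], ...]

    def __post_init__(self) -> None:
        seen = set()
        for term, (lo, hi) in self.terms:
            if term in seen:
                raise StructuralError(f"duplicate verbal term {term!r}")
            seen.add(term)
            if not (0.0 <= lo <= hi <= 1.0):
                raise StructuralError(
                    f"verbal term {term!r} has interval [{lo}, {hi}] outside [0, 1]"
                )

    def interval(self, term: str) -> tuple[float, float]:
        for t, iv in self.terms:
            if t == term:
                return iv
        raise StructuralError(
            f"unknown verbal term {term!r}; valid terms: {[t for t, _ in self.terms]}"
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "VerbalScale":
        data = json.loads(Path(path).read_text())
        return cls._from_obj(data)

    @classmethod
    def _from_obj(cls, data) -> "VerbalScale":
        return cls(tuple((e["term"], (float(e["lower"]), float(e["upper"]))) for e in data["terms"]))

    def to_obj(self) -> dict:
        return {
            "terms": [
                {"term": t, "lower": lo, "upper": hi} for t, (lo, hi) in self.terms
            ]
        }


def default_scale() -> VerbalScale:
    """The packaged seven-term scale (see ``data/verbal-scale.json``).

    Symmetric and deliberately overlapping; shipped as an editable config
    file so a different elicitation vocabulary needs no code change.
    """
    with resources.files("credalpod.data").joinpath("verbal-scale.json").open() as fh:
        return VerbalScale._from_obj(json.load(fh))


@dataclass(frozen=True)
class Judgment:
    """One expert statement about one conditional distribution row.

    kind "numeric-interval": payload ``(state, lower, upper)``;
    kind "verbal":           payload ``(state, term)``;
    kind "comparative":      payload ``(state_more_probable, state_less_probable)``.
    """

    kind: str
    payload: tuple

    def __post_init__(self) -> None:
        if self.kind not in JUDGMENT_KINDS:
            raise StructuralError(
                f"judgment kind {self.kind!r} not in {JUDGMENT_KINDS}"
            )
        n = {"numeric-interval": 3, "verbal": 2, "comparative": 2}[self.kind]
        if len(self.payload) != n:
            raise StructuralError(
                f"{self.kind} judgment expects a payload of length {n}"
            )

    @classmethod
    def interval(cls, state: str, lower: float, upper: float) -> "Judgment":
        return cls("numeric-interval", (state, float(lower), float(upper)))

    @classmethod
    def verbal(cls, state: str, term: str) -> "Judgment":
        return cls("verbal", (state, term))

    @classmethod
    def comparative(cls, more_probable: str, less_probable: str) -> "Judgment":
        return cls("comparative", (more_probable, less_probable))


def verbal_to_interval(term: str, scale: VerbalScale | None = None) -> tuple[float, float]:
    """Look a verbal term up in the scale (package default if omitted)."""
    scale = scale or default_scale()
    return scale.interval(term)


def compile_judgments(
    judgments: Sequence[Judgment],
    state_space: StateSpace,
    scale: VerbalScale | None = None,
) -> CredalSetSpec:
    """Compile expert judgments for one CPT row into a credal set.

    At most one interval-type (numeric or verbal) judgment per state is
    allowed; unjudged states stay vacuous.  The interval part is tightened
    with :func:`~credalpod.core.normalize_reachable`; orderings are kept
    as constraints.  An empty polytope is rejected with the offending
    constraints named.
    """
    scale = scale or default_scale()
    k = state_space.cardinality
    lower = np.zeros(k)
    upper = np.ones(k)
    judged: set[int] = set()
    orderings: list[tuple[int, int]] = []
    for j in judgments:
        if j.kind == "comparative":
            a, b = (state_space.index(s) for s in j.payload)
            orderings.append((a, b))
            continue
        if j.kind == "verbal":
            state, term = j.payload
            lo, hi = scale.interval(term)
        else:
            state, lo, hi = j.payload
        i = state_space.index(state)
        if i in judged:
            raise StructuralError(
                f"multiple interval judgments for state {state!r} of {state_space.name!r}"
            )
        judged.add(i)
        lower[i], upper[i] = lo, hi

    try:
        base = normalize_reachable(IntervalDistribution(lower, upper))
    except Exception as exc:
        raise FeasibilityError(
            f"judgments for {state_space.name!r} are contradictory: {exc}"
        ) from exc
    spec = CredalSetSpec(base, tuple(dict.fromkeys(orderings)))
    if not spec.is_feasible():
        named = [
            f"p({state_space.states[a]}) >= p({state_space.states[b]})"
            for a, b in spec.orderings
        ]
        raise FeasibilityError(
            f"judgments for {state_space.name!r} are contradictory "
            f"(intervals plus orderings {named} admit no distribution)"
        )
    return spec


def judgments_from_obj(items: Sequence[Mapping]) -> list[Judgment]:
    """Parse the ``tables[].judgments`` JSON form into :class:`Judgment` s."""
    out = []
    for it in items:
        kind = it.get("kind")
        if kind == "verbal":
            out.append(Judgment.verbal(it["state"], it["term"]))
        elif kind == "numeric-interval":
            out.append(Judgment.interval(it["state"], it["lower"], it["upper"]))
        elif kind == "comparative":
            out.append(Judgment.comparative(it["more_probable"], it["less_probable"]))
        else:
            raise StructuralError(f"unknown judgment kind {kind!r}")
    return out
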