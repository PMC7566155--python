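"""Synthetic patient cohorts.

Two generation modes:

* **marginal-faithful** — reproduces a published summary table exactly:
  every categorical column gets exactly the specified state counts and
  every integer column is constructed to hit its printed mean exactly
  while containing the printed minimum and maximum at least once.
  Columns are shuffled independently with seeded generators, so
  cross-column joints are random by design (the summary table publishes
  no joint distribution, and none is invented).
* **model-driven** — picks one point distribution per credal-network
  table (a vertex selection rule) and ancestrally samples records from
  the resulting Bayesian network; the chosen network is returned for
  ground-truth comparisons.

The packaged default marginal spec transcribes the 116-patient cohort
summary of the underlying chart-review study (``data/cohort-summary-spec.json``);
the column dictionary (``data/dictionary.json``) is the single source of
truth for names and state vocabularies, shared with the reference credal
network.  The missing marker is the literal ``NA``.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from ._version import __version__
from .core import CredalNetwork
from .exceptions import ConstructionError, StructuralError, ValidationError

MISSING = "NA"

VERTEX_RULES = ("lower-corner", "upper-corner", "midpoint", "random-per-table")


# ---------------------------------------------------------------------------
# Column dictionary
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ColumnDef:
    name: str
    type: str  # "categorical" | "integer"
    states: tuple[str, ...] = ()
    allow_missing: bool = False

    def __post_init__(self) -> None:
        if self.type not in ("categorical", "integer"):
            raise StructuralError(f"column {self.name!r}: unknown type {self.type!r}")
        if self.type == "categorical" and len(self.states) < 2:
            raise StructuralError(f"categorical column {self.name!r} needs >=2 states")


@dataclass(frozen=True)
class Dictionary:
    columns: tuple[ColumnDef, ...]

    def __post_init__(self) -> None:
        names = [c.name for c in self.columns]
        if len(set(names)) != len(names):
            raise StructuralError("duplicate column names in dictionary")

    def __contains__(self, name: str) -> bool:
        return any(c.name == name for c in self.columns)

    def column(self, name: str) -> ColumnDef:
        for c in self.columns:
            if c.name == name:
                return c
        raise StructuralError(f"unknown column {name!r}")

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(c.name for c in self.columns)

    @classmethod
    def from_obj(cls, obj: Mapping) -> "Dictionary":
        cols = []
        for c in obj["columns"]:
            cols.append(
                ColumnDef(
                    name=c["name"],
                    type=c["type"],
                    states=tuple(c.get("states", ())),
                    allow_missing=bool(c.get("allow_missing", False)),
                )
            )
        return cls(tuple(cols))

    @classmethod
    def from_json(cls, path: str | Path) -> "Dictionary":
        return cls.from_obj(json.loads(Path(path).read_text()))


def default_dictionary() -> Dictionary:
    """The packaged cohort column dictionary."""
    with resources.files("credalpod.data").joinpath("dictionary.json").open() as fh:
        return Dictionary.from_obj(json.load(fh))


# ---------------------------------------------------------------------------
# Marginal specification
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class IntegerColumnSpec:
    mean: float
    min: int
    max: int


@dataclass(frozen=True)
class MarginalSpec:
    """Exact per-column targets for a marginal-faithful cohort."""

    n: int
    categorical: Mapping[str, Mapping[str, int]]
    integer: Mapping[str, IntegerColumnSpec]

    def validate(self, dictionary: Dictionary | None = None) -> None:
        if self.n < 0:
            raise ValidationError("n must be non-negative")
        for col, counts in self.categorical.items():
            total = sum(counts.values())
            if total != self.n:
                raise ValidationError(
                    f"column {col!r}: counts sum to {total}, expected n={self.n}"
                )
            if any(c < 0 for c in counts.values()):
                raise ValidationError(f"column {col!r}: negative count")
            if dictionary is not None and col in dictionary:
                cd = dictionary.column(col)
                allowed = set(cd.states) | ({MISSING} if cd.allow_missing else set())
                bad = set(counts) - allowed
                if bad:
                    raise ValidationError(
                        f"column {col!r}: states {sorted(bad)} not in dictionary"
                    )
        for col, spec in self.integer.items():
            if self.n == 0:
                continue
            if not (spec.min <= spec.mean <= spec.max):
                raise ValidationError(
                    f"column {col!r}: mean {spec.mean} outside [{spec.min}, {spec.max}]"
                )
            total = self.n * spec.mean
            if abs(total - round(total)) > 1e-9:
                raise ValidationError(
                    f"column {col!r}: n*mean = {total} is not an integer"
                )

    @classmethod
    def from_obj(cls, obj: Mapping) -> "MarginalSpec":
        integer = {
            col: IntegerColumnSpec(float(s["mean"]), int(s["min"]), int(s["max"]))
            for col, s in obj.get("integer", {}).items()
        }
        return cls(
            n=int(obj["n"]),
            categorical={
                c: {k: int(v) for k, v in m.items()}
                for c, m in obj.get("categorical", {}).items()
            },
            integer=integer,
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "MarginalSpec":
        return cls.from_obj(json.loads(Path(path).read_text()))

    def to_obj(self) -> dict:
        return {
            "n": self.n,
            "categorical": {c: dict(m) for c, m in self.categorical.items()},
            "integer": {
                c: {"mean": s.mean, "min": s.min, "max": s.max}
                for c, s in self.integer.items()
            },
        }

    def hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_obj(), sort_keys=True).encode()
        ).hexdigest()[:16]


def default_summary_spec() -> MarginalSpec:
    """The packaged 116-patient cohort composition."""
    with resources.files("credalpod.data").joinpath("cohort-summary-spec.json").open() as fh:
        return MarginalSpec.from_obj(json.load(fh))


# ---------------------------------------------------------------------------
# Cohort container
# ---------------------------------------------------------------------------

@dataclass
class Cohort:
    """Ordered patient records plus their dictionary and generation metadata."""

    df: pd.DataFrame
    dictionary: Dictionary
    metadata: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.df)

    def validate(self) -> None:
        for col in self.df.columns:
            if col not in self.dictionary:
                raise ValidationError(f"column {col!r} not in dictionary")
            cd = self.dictionary.column(col)
            vals = self.df[col]
            if cd.type == "categorical":
                allowed = set(cd.states) | ({MISSING} if cd.allow_missing else set())
                bad = set(vals.unique()) - allowed
                if bad:
                    raise ValidationError(
                        f"column {col!r} contains invalid values {sorted(bad)}"
                    )
            else:
                if len(vals) and (vals.astype(int) < 0).any():
                    raise ValidationError(f"column {col!r} has negative day counts")

    def to_csv(self, path: str | Path) -> None:
        lines = [f"# credalpod-cohort {__version__}"]
        for k in sorted(self.metadata):
            lines.append(f"# {k}={self.metadata[k]}")
        body = self.df.to_csv(index=False)
        Path(path).write_text("\n".join(lines) + "\n" + body)

    @classmethod
    def read_csv(cls, path: str | Path, dictionary: Dictionary | None = None) -> "Cohort":
        dictionary = dictionary or default_dictionary()
        meta: dict[str, str] = {}
        text = Path(path).read_text().splitlines()
        for line in text:
            if not line.startswith("#"):
                break
            stripped = line.lstrip("# ")
            if "=" in stripped:
                k, v = stripped.split("=", 1)
                meta[k.strip()] = v.strip()
        df = pd.read_csv(path, comment="#", keep_default_na=False, dtype=str)
        for col in df.columns:
            if col in dictionary and dictionary.column(col).type == "integer":
                df[col] = df[col].astype(int)
        cohort = cls(df=df, dictionary=dictionary, metadata=meta)
        cohort.validate()
        return cohort


# ---------------------------------------------------------------------------
# Marginal-faithful generation
# ---------------------------------------------------------------------------

def _exact_mean_values(n: int, spec: IntegerColumnSpec) -> np.ndarray:
    """Deterministic integer multiset with exact mean and printed extremes.

    Fill with the floor of the mean, place min and max once each, then
    spread the residual in +/-1 increments round-robin over the free
    cells.  The caller shuffles.
    """
    if n == 0:
        return np.array([], dtype=int)
    total = round(n * spec.mean)
    if n == 1:
        if not (spec.min <= total <= spec.max):
            raise ConstructionError("single-record mean outside [min, max]")
        return np.array([total], dtype=int)
    base = math.floor(spec.mean)
    vals = np.full(n, base, dtype=int)
    vals[0], vals[1] = spec.min, spec.max
    residual = total - int(vals.sum())
    nfree = n - 2
    if residual != 0:
        if nfree == 0:
            raise ConstructionError(
                f"mean {spec.mean} unreachable with n=2 and extremes "
                f"{spec.min}, {spec.max}"
            )
        q, r = divmod(residual, nfree)
        free = vals[2:]
        free += q
        free[:r] += 1
        if (free < spec.min).any() or (free > spec.max).any():
            raise ConstructionError(
                f"mean {spec.mean} infeasible for range [{spec.min}, {spec.max}]"
            )
        vals[2:] = free
    return vals


def generate_marginal_cohort(
    spec: MarginalSpec | None = None,
    seed: int = 0,
    dictionary: Dictionary | None = None,
) -> Cohort:
    """Build a cohort whose per-column summary reproduces ``spec`` exactly."""
    dictionary = dictionary or default_dictionary()
    spec = spec or default_summary_spec()
    spec.validate(dictionary)

    root = np.random.SeedSequence(seed)
    ordered_cols = [
        c for c in dictionary.names if c in spec.categorical or c in spec.integer
    ]
    # Spec columns outside the dictionary order are appended alphabetically.
    extra = sorted((set(spec.categorical) | set(spec.integer)) - set(ordered_cols))
    ordered_cols += extra
    children = {c: child for c, child in zip(ordered_cols, root.spawn(len(ordered_cols)))}

    data: dict[str, np.ndarray | list] = {}
    for col in ordered_cols:
        rng = np.random.default_rng(children[col])
        if col in spec.categorical:
            values: list[str] = []
            for state, count in spec.categorical[col].items():
                values.extend([state] * count)
            arr = np.array(values, dtype=object)
            rng.shuffle(arr)
            data[col] = arr
        else:
            vals = _exact_mean_values(spec.n, spec.integer[col])
            rng.shuffle(vals)
            data[col] = vals

    df = pd.DataFrame(data, columns=ordered_cols)
    cohort = Cohort(
        df=df,
        dictionary=dictionary,
        metadata={
            "mode": "marginal",
            "seed": str(seed),
            "n": str(spec.n),
            "spec_hash": spec.hash(),
        },
    )
    cohort.validate()
    return cohort


# ---------------------------------------------------------------------------
# Model-driven generation
# ---------------------------------------------------------------------------

def select_vertices(
    net: CredalNetwork, rule: str, rng: np.random.Generator | None = None
) -> dict[str, np.ndarray]:
    """One point distribution per table, as CPT arrays (parents..., child).

    Rules: ``lower-corner`` / ``upper-corner`` pick the vertex closest (L1)
    to the lower / upper bound vector; ``midpoint`` takes the vertex
    centroid (a valid interior distribution); ``random-per-table`` draws a
    vertex uniformly with the supplied generator.
    """
    if rule not in VERTEX_RULES:
        raise StructuralError(f"vertex rule {rule!r} not in {VERTEX_RULES}")
    if rule == "random-per-table" and rng is None:
        raise StructuralError("random-per-table needs a seeded generator")
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
            if spec.is_point:
                arr[idx] = spec.base.lower
                continue
            verts = spec.vertices()
            if rule == "lower-corner":
                arr[idx] = verts[np.abs(verts - spec.base.lower).sum(axis=1).argmin()]
            elif rule == "upper-corner":
                arr[idx] = verts[np.abs(verts - spec.base.upper).sum(axis=1).argmin()]
            elif rule == "midpoint":
                arr[idx] = verts.mean(axis=0)
            else:
                arr[idx] = verts[int(rng.integers(len(verts)))]
        cpts[v] = arr
    return cpts


def generate_model_cohort(
    net: CredalNetwork,
    rule: str = "midpoint",
    n: int = 1000,
    seed: int = 0,
) -> tuple[Cohort, dict[str, np.ndarray]]:
    """Ancestral-sample ``n`` records from a vertex-selected Bayesian network.

    Returns the cohort and the selected CPT arrays (the ground truth the
    cohort was drawn from).
    """
    root = np.random.SeedSequence(seed)
    rng_sel, rng_samp = (np.random.default_rng(c) for c in root.spawn(2))
    cpts = select_vertices(net, rule, rng_sel)

    order = net.topological_order()
    cols: dict[str, np.ndarray] = {}
    for v in order:
        card = net.state_spaces[v].cardinality
        parents = net.parents[v]
        if parents:
            parent_idx = np.stack([cols[p] for p in parents])
            flat = np.ravel_multi_index(
                parent_idx,
                tuple(net.state_spaces[p].cardinality for p in parents),
            )
            probs = cpts[v].reshape(-1, card)[flat]
        else:
            probs = np.broadcast_to(cpts[v], (n, card))
        cum = np.cumsum(probs, axis=1)
        u = rng_samp.random(n)
        cols[v] = (u[:, None] > cum).sum(axis=1).clip(0, card - 1)

    df = pd.DataFrame(
        {
            v: np.array(net.state_spaces[v].states, dtype=object)[cols[v]]
            for v in order
        },
        columns=list(order),
    )
    dictionary = Dictionary(
        tuple(
            ColumnDef(name=v, type="categorical", states=net.states(v))
            for v in order
        )
    )
    cohort = Cohort(
        df=df,
        dictionary=dictionary,
        metadata={"mode": "model", "seed": str(seed), "rule": rule, "n": str(n)},
    )
    return cohort, cpts


# ---------------------------------------------------------------------------
# Summaries
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CohortSummary:
    n: int
    categorical: Mapping[str, Mapping[str, int]]
    integer: Mapping[str, IntegerColumnSpec]

    def matches(self, spec: MarginalSpec) -> bool:
        if self.n != spec.n:
            return False
        for col, counts in spec.categorical.items():
            observed = self.categorical.get(col, {})
            if {k: v for k, v in counts.items() if v} != {
                k: v for k, v in observed.items() if v
            }:
                return False
        for col, s in spec.integer.items():
            o = self.integer.get(col)
            if o is None or (o.mean, o.min, o.max) != (s.mean, s.min, s.max):
                return False
        return True

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for col, counts in self.categorical.items():
            for state, count in counts.items():
                rows.append({"column": col, "detail": state, "value": count})
        for col, s in self.integer.items():
            rows.append({"column": col, "detail": "mean", "value": s.mean})
            rows.append({"column": col, "detail": "range", "value": f"{s.min}-{s.max}"})
        return pd.DataFrame(rows, columns=["column", "detail", "value"])


def summarize(cohort: Cohort) -> CohortSummary:
    """Per-column counts, exact means and ranges, summary-table style."""
    categorical: dict[str, dict[str, int]] = {}
    integer: dict[str, IntegerColumnSpec] = {}
    for col in cohort.df.columns:
        cd = cohort.dictionary.column(col) if col in cohort.dictionary else None
        series = cohort.df[col]
        if cd is not None and cd.type == "integer":
            if len(series):
                vals = series.astype(int)
                mean = float(vals.sum()) / len(vals)
                if mean == int(mean):
                    mean = int(mean)
                integer[col] = IntegerColumnSpec(
                    mean=float(mean), min=int(vals.min()), max=int(vals.max())
                )
            continue
        states = list(cd.states) if cd is not None else sorted(series.unique())
        counts = series.value_counts()
        out = {s: int(counts.get(s, 0)) for s in states}
        if int(counts.get(MISSING, 0)):
            out[MISSING] = int(counts.get(MISSING, 0))
        categorical[col] = out
    return CohortSummary(n=len(cohort), categorical=categorical, integer=integer)


# ---------------------------------------------------------------------------
# Discretization of day-count columns for the classifier
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DiscretizationConfig:
    """How integer day-count columns become categorical classifier features.

    Hospital days use clinically conventional cuts (none / up to two weeks
    / longer); the assessment-to-death interval is split at its empirical
    tertiles.
    """

    hospital_days_column: str = "days_in_hospital_60"
    hospital_days_cuts: tuple[int, int] = (0, 14)
    assessment_column: str = "assessment_to_death_days"

    def to_obj(self) -> dict:
        return {
            "hospital_days_column": self.hospital_days_column,
            "hospital_days_cuts": list(self.hospital_days_cuts),
            "assessment_column": self.assessment_column,
        }


def discretize(
    df: pd.DataFrame, config: DiscretizationConfig | None = None
) -> pd.DataFrame:
    """Return a copy with binned-band columns added."""
    config = config or DiscretizationConfig()
    out = df.copy()
    zero_cut, low_cut = config.hospital_days_cuts
    if config.hospital_days_column in out.columns:
        days = out[config.hospital_days_column].astype(int)
        out["hospital_days_band"] = np.select(
            [days <= zero_cut, days <= low_cut],
            [f"<={zero_cut}", f"{zero_cut + 1}-{low_cut}"],
            default=f">{low_cut}",
        )
    if config.assessment_column in out.columns and len(out):
        days = out[config.assessment_column].astype(int)
        t1, t2 = np.quantile(days, [1 / 3, 2 / 3])
        out["assessment_band"] = np.select(
            [days <= t1, days <= t2], ["early", "middle"], default="late"
        )
    return out


#: Default feature set for the place-of-death classifier on summary-faithful cohorts.
DEFAULT_CLASSIFIER_FEATURES: tuple[str, ...] = (
    "area_of_residence",
    "living_arrangements",
    "kps",
    "symptom_burden",
    "cancer_treatment",
    "patient_awareness",
    "family_awareness",
    "family_conditions",
    "patient_preference",
    "family_preference",
    "palliative_physician_visits",
    "palliative_nurse_visits",
    "general_practitioner",
    "home_care_services",
    "volunteers",
    "social_worker",
    "hospital_days_band",
)
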