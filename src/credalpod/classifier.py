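"""Naive Bayes place-of-death classifier.

A generative classifier over categorical chart-review features, assuming
feature independence given the class.  Laplace smoothing with weight
``alpha`` (default 1); a record's missing features — the literal ``NA``
marker, pandas missing values, or the chart states ``not_assessed`` /
``not_available`` — are simply skipped, both when counting and when
scoring.  Missingness is treated as informative only in the credal model,
where "not assessed" is an explicit state; here it is absence of signal.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .exceptions import EvaluationError, FitError, PredictionError

logger = logging.getLogger(__name__)

#: Values treated as "feature not observed" by the classifier.
MISSING_MARKERS = frozenset({"NA", "not_assessed", "not_available", ""})


def _is_missing(value) -> bool:
    return pd.isna(value) or (isinstance(value, str) and value in MISSING_MARKERS)


@dataclass
class NBModel:
    """A fitted naive Bayes model.

    ``conditionals[f]`` is a DataFrame with feature levels as the index
    and class states as columns; every column sums to one.
    """

    class_var: str
    classes: tuple[str, ...]
    priors: pd.Series
    conditionals: dict[str, pd.DataFrame]
    alpha: float
    meta: dict = field(default_factory=dict)

    @property
    def features(self) -> tuple[str, ...]:
        return tuple(self.conditionals)

    def check(self, tol: float = 1e-12) -> None:
        assert abs(self.priors.sum() - 1.0) <= tol
        for f, tab in self.conditionals.items():
            colsums = tab.sum(axis=0).to_numpy()
            assert np.all(np.abs(colsums - 1.0) <= tol), f"{f} columns do not normalise"

    # -- persistence -------------------------------------------------------

    def to_obj(self) -> dict:
        return {
            "class_var": self.class_var,
            "classes": list(self.classes),
            "alpha": self.alpha,
            "priors": {c: float(self.priors[c]) for c in self.classes},
            "conditionals": {
                f: {
                    "levels": list(tab.index),
                    "probs": {c: [float(x) for x in tab[c]] for c in self.classes},
                }
                for f, tab in self.conditionals.items()
            },
            "meta": self.meta,
        }

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_obj(), indent=1) + "\n")

    @classmethod
    def from_obj(cls, obj: Mapping) -> "NBModel":
        classes = tuple(obj["classes"])
        priors = pd.Series({c: obj["priors"][c] for c in classes})
        conds = {}
        for f, tab in obj["conditionals"].items():
            conds[f] = pd.DataFrame(
                {c: tab["probs"][c] for c in classes}, index=tab["levels"]
            )
        return cls(
            class_var=obj["class_var"],
            classes=classes,
            priors=priors,
            conditionals=conds,
            alpha=float(obj["alpha"]),
            meta=dict(obj.get("meta", {})),
        )

    @classmethod
    def load(cls, path: str | Path) -> "NBModel":
        return cls.from_obj(json.loads(Path(path).read_text()))


def fit_naive_bayes(
    cohort: pd.DataFrame,
    class_var: str,
    features: Sequence[str],
    alpha: float = 1.0,
    levels: Mapping[str, Sequence[str]] | None = None,
) -> NBModel:
    """Fit by smoothed counting.

    priors: ``(n_c + alpha) / (n + alpha * K)``;
    conditionals: ``(n_{f=v,c} + alpha) / (n_{f observed,c} + alpha * K_f)``,
    where records missing feature ``f`` are excluded from ``f``'s counts.
    ``levels`` can pin each feature's value vocabulary (e.g. from the data
    dictionary); otherwise the observed non-missing values are used.
    """
    if class_var not in cohort.columns:
        raise FitError(f"class column {class_var!r} not in cohort")
    y = cohort[class_var]
    if y.map(_is_missing).any():
        raise FitError(f"class column {class_var!r} has missing values")
    n = len(cohort)
    if n == 0:
        raise FitError("empty cohort")
    classes = tuple(sorted(pd.unique(y)))
    if len(classes) < 2:
        raise FitError(f"cohort has a single class {classes!r}; nothing to learn")

    k = len(classes)
    counts = y.value_counts()
    priors = pd.Series(
        {c: (counts.get(c, 0) + alpha) / (n + alpha * k) for c in classes}
    )

    conds: dict[str, pd.DataFrame] = {}
    for f in features:
        if f == class_var:
            raise FitError("class variable cannot be one of its own features")
        if f not in cohort.columns:
            raise FitError(f"feature column {f!r} not in cohort")
        col = cohort[f]
        observed = ~col.map(_is_missing)
        if levels and f in levels:
            f_levels = [v for v in levels[f] if v not in MISSING_MARKERS]
        else:
            f_levels = sorted(pd.unique(col[observed]))
        if not f_levels:
            logger.warning("feature %r has no observed values; dropped", f)
            continue
        tab = pd.DataFrame(index=f_levels, columns=list(classes), dtype=float)
        for c in classes:
            sel = col[observed & (y == c)]
            vc = sel.value_counts()
            denom = len(sel) + alpha * len(f_levels)
            if denom == 0:
                tab[c] = 1.0 / len(f_levels)
            else:
                tab[c] = [(vc.get(v, 0) + alpha) / denom for v in f_levels]
        conds[f] = tab
    model = NBModel(
        class_var=class_var,
        classes=classes,
        priors=priors,
        conditionals=conds,
        alpha=float(alpha),
        meta={"n": n},
    )
    if alpha > 0:
        model.check()
    return model


def predict(model: NBModel, record: Mapping) -> tuple[pd.Series, str]:
    """Class posterior and argmax prediction for one (possibly partial) record.

    Skips missing features; posterior is proportional to the prior times
    the product of conditionals of *present* features, computed in log
    space.  Ties break in canonical class order.
    """
    with np.errstate(divide="ignore"):
        logp = np.log(np.clip(model.priors.to_numpy(dtype=float), 0.0, None))
    for f, tab in model.conditionals.items():
        if f not in record:
            continue
        v = record[f]
        if _is_missing(v):
            continue
        if v not in tab.index:
            raise PredictionError(
                f"value {v!r} of feature {f!r} unknown to the model "
                f"(known: {list(tab.index)})"
            )
        with np.errstate(divide="ignore"):
            logp = logp + np.log(tab.loc[v].to_numpy(dtype=float))
    if np.all(np.isneginf(logp)):
        raise PredictionError("record has probability zero under every class")
    m = logp.max()
    p = np.exp(logp - m)
    posterior = pd.Series(p / p.sum(), index=list(model.classes))
    predicted = model.classes[int(np.argmax(posterior.to_numpy()))]
    return posterior, predicted


def predict_frame(model: NBModel, cohort: pd.DataFrame) -> pd.Series:
    """Vector of predicted classes, one per cohort row."""
    preds = [predict(model, row)[1] for row in cohort.to_dict("records")]
    return pd.Series(preds, index=cohort.index, name=f"predicted_{model.class_var}")


@dataclass(frozen=True)
class EvaluationReport:
    n: int
    model_accuracy: float
    baseline_accuracy: float
    loocv_accuracy: float
    confusion: pd.DataFrame = field(repr=False)

    def __str__(self) -> str:
        return (
            f"n={self.n}  model accuracy {self.model_accuracy:.4f}  "
            f"baseline accuracy {self.baseline_accuracy:.4f}  "
            f"LOOCV accuracy {self.loocv_accuracy:.4f}"
        )


def evaluate(
    model: NBModel,
    cohort: pd.DataFrame,
    baseline_column: str,
) -> EvaluationReport:
    """Accuracy of the model vs a recorded baseline prediction column.

    In-sample accuracy, per-class confusion, and leave-one-out
    cross-validated accuracy (refit n times with the held-out record
    excluded, same features/levels/alpha).
    """
    y = cohort[model.class_var]
    if y.map(_is_missing).any():
        raise EvaluationError("missing class labels in evaluation cohort")
    if baseline_column not in cohort.columns:
        raise EvaluationError(f"baseline column {baseline_column!r} not in cohort")
    bad = set(pd.unique(cohort[baseline_column])) - set(model.classes)
    if bad:
        raise EvaluationError(
            f"baseline column uses values {sorted(bad)} outside the class states"
        )

    preds = predict_frame(model, cohort)
    model_acc = float((preds == y).mean())
    baseline_acc = float((cohort[baseline_column] == y).mean())
    confusion = pd.crosstab(y, preds).reindex(
        index=list(model.classes), columns=list(model.classes), fill_value=0
    )

    levels = {f: list(tab.index) for f, tab in model.conditionals.items()}
    hits = 0
    for i in range(len(cohort)):
        train = cohort.drop(cohort.index[i])
        try:
            m_i = fit_naive_bayes(
                train, model.class_var, list(model.features), model.alpha, levels
            )
            _, pred = predict(m_i, cohort.iloc[i].to_dict())
        except (FitError, PredictionError):
            continue
        hits += int(pred == y.iloc[i])
    loocv = hits / len(cohort)
    return EvaluationReport(
        n=len(cohort),
        model_accuracy=model_acc,
        baseline_accuracy=baseline_acc,
        loocv_accuracy=float(loocv),
        confusion=confusion,
    )
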