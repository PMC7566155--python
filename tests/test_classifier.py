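"""Naive Bayes fitting, prediction, missing-data handling and evaluation."""

import numpy as np
import pandas as pd
import pytest

from credalpod.classifier import (
    NBModel,
    evaluate,
    fit_naive_bayes,
    predict,
    predict_frame,
)
from credalpod.exceptions import EvaluationError, FitError, PredictionError

TOY = pd.DataFrame({"x": ["x1", "x1", "x2", "x2"], "y": ["h", "h", "h", "o"]})


class TestFit:
    def test_laplace_counts_match_hand_computation(self):
        model = fit_naive_bayes(TOY, "y", ["x"], alpha=1.0)
        assert model.priors["h"] == pytest.approx(2 / 3)
        assert model.priors["o"] == pytest.approx(1 / 3)
        assert model.conditionals["x"].loc["x2", "h"] == pytest.approx(0.4)
        assert model.conditionals["x"].loc["x2", "o"] == pytest.approx(2 / 3)

    def test_unsmoothed_zero_frequencies_allowed(self):
        model = fit_naive_bayes(TOY, "y", ["x"], alpha=0.0)
        assert model.conditionals["x"].loc["x1", "o"] == 0.0

    def test_records_missing_a_feature_excluded_from_its_counts(self):
        df = pd.DataFrame(
            {"x": ["x1", "NA", "x2", "not_assessed"], "y": ["h", "h", "o", "o"]}
        )
        model = fit_naive_bayes(df, "y", ["x"], alpha=0.0)
        # each class has exactly one observed record for x
        assert model.conditionals["x"].loc["x1", "h"] == 1.0
        assert model.conditionals["x"].loc["x2", "o"] == 1.0

    def test_entirely_missing_feature_dropped_with_warning(self, caplog):
        df = pd.DataFrame({"x": ["NA", "NA"], "z": ["a", "b"], "y": ["h", "o"]})
        with caplog.at_level("WARNING"):
            model = fit_naive_bayes(df, "y", ["x", "z"], alpha=1.0)
        assert model.features == ("z",)
        assert any("dropped" in r.message for r in caplog.records)

    def test_degenerate_cohorts_rejected(self):
        with pytest.raises(FitError):
            fit_naive_bayes(TOY.iloc[:0], "y", ["x"])
        with pytest.raises(FitError):
            fit_naive_bayes(TOY[TOY.y == "h"], "y", ["x"])
        with pytest.raises(FitError):
            fit_naive_bayes(TOY.assign(y=["h", "h", "NA", "o"]), "y", ["x"])


class TestPredict:
    def test_worked_posterior(self):
        model = fit_naive_bayes(TOY, "y", ["x"], alpha=1.0)
        posterior, predicted = predict(model, {"x": "x2"})
        assert posterior["h"] == pytest.approx(0.545, abs=5e-4)
        assert predicted == "h"

    def test_all_features_missing_returns_prior(self):
        model = fit_naive_bayes(TOY, "y", ["x"], alpha=1.0)
        posterior, predicted = predict(model, {"x": "NA"})
        assert posterior["h"] == pytest.approx(model.priors["h"])
        assert predicted == "h"

    def test_zero_conditional_propagates_without_smoothing(self):
        model = fit_naive_bayes(TOY, "y", ["x"], alpha=0.0)
        posterior, _ = predict(model, {"x": "x1"})
        assert posterior["o"] == 0.0

    def test_unknown_value_named_in_error(self):
        model = fit_naive_bayes(TOY, "y", ["x"], alpha=1.0)
        with pytest.raises(PredictionError, match="x9"):
            predict(model, {"x": "x9"})

    def test_feature_order_invariance_and_normalisation(self):
        df = TOY.assign(w=["w1", "w2", "w1", "w2"])
        m1 = fit_naive_bayes(df, "y", ["x", "w"], alpha=1.0)
        m2 = fit_naive_bayes(df, "y", ["w", "x"], alpha=1.0)
        p1, _ = predict(m1, {"x": "x2", "w": "w1"})
        p2, _ = predict(m2, {"w": "w1", "x": "x2"})
        assert p1.sum() == pytest.approx(1.0, abs=1e-12)
        pd.testing.assert_series_equal(p1, p2)

    def test_json_roundtrip(self, tmp_path):
        model = fit_naive_bayes(TOY, "y", ["x"], alpha=1.0)
        path = tmp_path / "m.json"
        model.save(path)
        loaded = NBModel.load(path)
        p0, _ = predict(model, {"x": "x2"})
        p1, _ = predict(loaded, {"x": "x2"})
        pd.testing.assert_series_equal(p0, p1)


class TestEvaluate:
    def _six_records(self):
        return pd.DataFrame(
            {
                "x": ["a", "a", "b", "b", "a", "b"],
                "z": ["u", "v", "u", "v", "v", "u"],
                "y": ["h", "h", "o", "o", "h", "o"],
                "team": ["h", "o", "o", "o", "h", "h"],
            }
        )

    def test_perfect_model_and_identity_baseline(self):
        df = self._six_records()
        model = fit_naive_bayes(df, "y", ["x"], alpha=0.0)
        report = evaluate(model, df.assign(team=df.y), "team")
        assert report.model_accuracy == 1.0
        assert report.baseline_accuracy == 1.0
        assert int(report.confusion.to_numpy().trace()) == 6

    def test_loocv_equals_manual_refit_loop(self):
        df = self._six_records()
        model = fit_naive_bayes(df, "y", ["x", "z"], alpha=1.0)
        report = evaluate(model, df, "team")
        hits = 0
        levels = {f: list(t.index) for f, t in model.conditionals.items()}
        for i in range(len(df)):
            m = fit_naive_bayes(df.drop(df.index[i]), "y", ["x", "z"], 1.0, levels)
            _, pred = predict(m, df.iloc[i].to_dict())
            hits += pred == df.y.iloc[i]
        assert report.loocv_accuracy == pytest.approx(hits / len(df))

    def test_baseline_outside_class_states_rejected(self):
        df = self._six_records().assign(team=["h", "o", "o", "o", "h", "x"])
        model = fit_naive_bayes(df, "y", ["x"], alpha=1.0)
        with pytest.raises(EvaluationError):
            evaluate(model, df, "team")

    def test_missing_labels_rejected(self):
        df = self._six_records()
        model = fit_naive_bayes(df, "y", ["x"], alpha=1.0)
        with pytest.raises(EvaluationError):
            evaluate(model, df.assign(y=["h", "NA", "o", "o", "h", "o"]), "team")


class TestParameterRecovery:
    def test_conditionals_recovered_from_model_cohort(self, reference_model):
        """Fitting on a 10,000-record vertex-selected cohort recovers the
        generating network's feature-given-class conditionals within 0.03."""
        from credalpod.cohort import generate_model_cohort
        from credalpod.core import CredalNetwork, CredalSetSpec
        from credalpod.inference import bayesian_posterior

        net = reference_model.net
        cohort, cpts = generate_model_cohort(net, rule="midpoint", n=10_000, seed=42)
        point_net = CredalNetwork(
            list(net.state_spaces.values()),
            dict(net.parents),
            {
                (v, cfg): CredalSetSpec.from_point(
                    cpts[v][
                        tuple(
                            net.state_spaces[p].index(s)
                            for p, s in zip(net.parents[v], cfg)
                        )
                    ]
                )
                for v in net.variables
                for cfg in net.parent_configs(v)
            },
        )
        features = ["area_of_residence", "symptom_burden", "hospital_days", "cancer_treatment"]
        model = fit_naive_bayes(cohort.df, "place_of_death", features, alpha=1.0)
        class_counts = cohort.df["place_of_death"].value_counts()
        for f in features:
            for c in model.classes:
                # rare classes carry binomial noise above the tolerance at
                # this cohort size; they get a looser sanity bound
                tol = 0.03 if class_counts[c] >= 2000 else 0.08
                for v in net.states(f):
                    truth = bayesian_posterior(point_net, f, v, {"place_of_death": c})
                    est = model.conditionals[f].loc[v, c]
                    assert est == pytest.approx(truth, abs=tol), (f, v, c)

    def test_predict_frame_matches_rowwise_predict(self):
        model = fit_naive_bayes(TOY, "y", ["x"], alpha=1.0)
        preds = predict_frame(model, TOY)
        assert list(preds) == [predict(model, r)[1] for r in TOY.to_dict("records")]
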