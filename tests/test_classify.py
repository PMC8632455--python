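"""Splits, network training, metrics and cross-validation protocols."""

from dataclasses import replace

import numpy as np
import pytest

from ramanff.classify import (
    ANNConfig,
    confusion_and_report,
    five_fold_cv,
    loocv,
    predict_labels,
    predict_proba,
    pregnancy_rate_summary,
    report_from_counts,
    roc_curve_auc,
    split_train_test,
    train_ann,
)
from ramanff.errors import ValidationError
from ramanff.spectra import SampleMeta, Spectrum, SpectrumSet, WavenumberGrid
from ramanff.synthetic import default_config, generate_dataset
from ramanff.preprocess import preprocess_set

FAST_ANN = ANNConfig(max_epochs=120, seed=0)


def _labeled_set(n_pos, n_neg, reps=1, seed=0):
    rng = np.random.default_rng(seed)
    grid = WavenumberGrid(600, 649)
    samples, spectra = [], []
    for i in range(n_pos + n_neg):
        lab = "HQ" if i < n_pos else "LQ"
        samples.append(SampleMeta(f"s{i}", blastocyst=lab))
        spectra.append([Spectrum(grid, rng.random(50) + 0.5) for _ in range(reps)])
    return SpectrumSet(samples, spectra)


class TestSplit:
    def test_exact_stratification_50_50(self):
        ds = _labeled_set(50, 50)
        train, test = split_train_test(ds, "blastocyst", seed=0)
        for part, n_each in ((train, 40), (test, 10)):
            labels = part.labels("blastocyst")
            assert int(np.sum(labels == "HQ")) == n_each
            assert int(np.sum(labels == "LQ")) == n_each

    def test_configured_counts_75_75_to_50_50_train(self):
        ds = _labeled_set(75, 75)
        train, test = split_train_test(
            ds, "blastocyst", seed=1, train_per_class={"HQ": 50, "LQ": 50}
        )
        assert train.n_samples == 100 and test.n_samples == 50
        assert int(np.sum(test.labels("blastocyst") == "HQ")) == 25

    def test_same_seed_identical_membership_no_leakage(self):
        ds = _labeled_set(10, 10, reps=3)
        t1, e1 = split_train_test(ds, "blastocyst", seed=5)
        t2, e2 = split_train_test(ds, "blastocyst", seed=5)
        ids = lambda s: {m.sample_id for m in s.samples}
        assert ids(t1) == ids(t2) and ids(e1) == ids(e2)
        assert ids(t1).isdisjoint(ids(e1))
        assert ids(t1) | ids(e1) == ids(ds)
        # replicates travel with their sample
        assert t1.replicates_per_sample == 3 and e1.replicates_per_sample == 3

    def test_small_class_rejected(self):
        with pytest.raises(ValidationError):
            split_train_test(_labeled_set(3, 10), "blastocyst")


class TestTraining:
    def test_separable_cohort_classified_perfectly(self, separable_cohort):
        train, test = split_train_test(separable_cohort, "blastocyst", seed=0)
        model = train_ann(train, FAST_ANN, "blastocyst")
        pred = predict_labels(model, test)
        assert np.all(pred == test.labels("blastocyst"))
        assert all(np.isfinite(model.training_history))

    def test_probabilities_normalized_and_deterministic(self, separable_cohort):
        model = train_ann(separable_cohort, FAST_ANN, "blastocyst")
        X = separable_cohort.intensity_matrix()[:3]
        probs = predict_proba(model, np.vstack([X, X[0:1]]))
        np.testing.assert_allclose(probs.sum(axis=1), 1, atol=1e-6)
        np.testing.assert_array_equal(probs[0], probs[3])

    def test_width_mismatch_rejected(self, separable_cohort):
        model = train_ann(separable_cohort, FAST_ANN, "blastocyst")
        with pytest.raises(ValidationError):
            predict_proba(model, np.ones((1, model.input_width + 1)))

    def test_single_class_training_rejected(self):
        ds = _labeled_set(6, 0)
        with pytest.raises(ValidationError):
            train_ann(ds, FAST_ANN, "blastocyst")

    def test_training_reproducible_to_float_precision(self):
        ds = _labeled_set(8, 8, seed=3)
        cfg = ANNConfig(max_epochs=30, seed=42)
        m1 = train_ann(ds, cfg, "blastocyst")
        m2 = train_ann(ds, cfg, "blastocyst")
        assert abs(m1.training_history[-1] - m2.training_history[-1]) < 1e-10


class TestMetrics:
    def test_blastocyst_model_counts(self):
        cm, report = report_from_counts(23, 2, 3, 22, positive_class="HQ")
        hq = report.per_class["HQ"]
        assert round(100 * hq["precision"], 2) == 88.46
        assert round(100 * hq["sensitivity"], 2) == 92.00
        assert round(hq["f1"], 4) == 0.9020
        assert round(100 * report.accuracy, 2) == 90.00
        lq = report.per_class[[c for c in report.per_class if c != "HQ"][0]]
        assert round(lq["f1"], 4) == 0.8980
        assert round(100 * lq["precision"], 2) == 91.67
        assert round(100 * lq["sensitivity"], 2) == 88.00

    def test_pregnancy_model_counts(self):
        cm, report = report_from_counts(25, 10, 3, 12, positive_class="success")
        s = report.per_class["success"]
        assert round(100 * s["precision"], 2) == 89.29
        assert round(100 * s["sensitivity"], 2) == 71.43
        assert round(s["f1"], 4) == 0.7937
        f = report.per_class[[c for c in report.per_class if c != "success"][0]]
        assert round(100 * f["precision"], 2) == 54.55
        assert round(100 * f["sensitivity"], 2) == 80.00
        assert round(f["f1"], 4) == 0.6486
        assert round(100 * report.accuracy, 2) == 74.00

    def test_perfect_prediction(self):
        _, report = report_from_counts(5, 0, 0, 5)
        assert report.accuracy == 1.0
        assert all(v == 1.0 for m in report.per_class.values() for v in m.values())

    def test_zero_over_zero_reported_undefined(self):
        y = np.array(["a", "a", "b"])
        pred = np.array(["a", "a", "a"])
        with pytest.warns(UserWarning, match="undefined"):
            _, report = confusion_and_report(y, pred, "b")
        assert report.per_class["b"]["precision"] is None


class TestROC:
    def test_perfect_ranking(self):
        _, auc = roc_curve_auc([0, 0, 1, 1], [0.1, 0.2, 0.8, 0.9])
        assert auc == 1.0

    def test_all_tied_scores(self):
        _, auc = roc_curve_auc([0, 1, 0, 1], [0.5, 0.5, 0.5, 0.5])
        assert auc == 0.5

    def test_matches_pairwise_concordance_oracle(self):
        rng = np.random.default_rng(11)
        for _ in range(25):
            n = int(rng.integers(4, 20))
            y = rng.integers(0, 2, n)
            if len(set(y)) < 2:
                continue
            scores = np.round(rng.random(n), 1)  # rounding forces ties
            _, auc = roc_curve_auc(y, scores)
            pos, neg = scores[y == 1], scores[y == 0]
            conc = sum((p > q) + 0.5 * (p == q) for p in pos for q in neg)
            assert auc == pytest.approx(conc / (len(pos) * len(neg)), abs=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(ValidationError):
            roc_curve_auc([1, 1, 1], [0.1, 0.5, 0.9])


class TestCrossValidation:
    def test_five_fold_separable_perfect(self, separable_cohort):
        summary = five_fold_cv(separable_cohort, FAST_ANN, "blastocyst")
        assert summary.n_folds == 5
        assert summary.auc_mean == pytest.approx(1.0)
        assert summary.auc_sd == pytest.approx(0.0)

    def test_loocv_prediction_count_and_accuracy(self, separable_cohort):
        sub = separable_cohort.subset([m.sample_id for m in separable_cohort.samples[:5]]
                                      + [m.sample_id for m in separable_cohort.samples[10:15]])
        res = loocv(sub, ANNConfig(max_epochs=300, seed=0), "blastocyst")
        assert len(res["predicted"]) == sub.n_samples
        assert res["accuracy"] == 1.0


class TestPregnancyRates:
    def test_study_counts(self):
        pairs = [("HQ", "success")] * 62 + [("HQ", "failure")] * 13
        pairs += [("LQ", "success")] * 23 + [("LQ", "failure")] * 52
        out = pregnancy_rate_summary(pairs)
        assert out["HQ"] == {"n": 75, "successes": 62, "rate_percent": 83}
        assert out["LQ"] == {"n": 75, "successes": 23, "rate_percent": 31}

    def test_zero_successes(self):
        out = pregnancy_rate_summary([("HQ", "failure")] * 10 + [("LQ", "success")] * 2)
        assert out["HQ"]["rate_percent"] == 0

    def test_empty_stratum_warns_undefined(self):
        with pytest.warns(UserWarning, match="empty"):
            out = pregnancy_rate_summary([("HQ", "success")] * 3)
        assert out["LQ"]["rate_percent"] is None
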