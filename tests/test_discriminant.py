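"""Fisher index, LDA fitting, ablation, cross-validation, confusion metrics."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from glycolda.discriminant import (
    ClassificationReport,
    CrossValPlan,
    ablation,
    classify,
    confusion_metrics,
    cross_validate,
    fisher_index,
    fit_lda,
    select_features,
)
from glycolda.quantify import FeatureMatrix


def _fm(X, labels, columns=None):
    columns = columns or [f"f{i}" for i in range(X.shape[1])]
    idx = pd.Index([f"s{i}" for i in range(X.shape[0])], name="sample_id")
    return FeatureMatrix(
        pd.DataFrame(X, index=idx, columns=columns), pd.Series(labels, index=idx)
    )


def _gaussian_fm(rng, n_per_class=20, p=2, shift=3.0):
    X = rng.standard_normal((2 * n_per_class, p))
    X[:n_per_class, 0] += shift
    labels = ["melanoma"] * n_per_class + ["control"] * n_per_class
    return _fm(X, labels)


def test_fisher_index_identical_means_is_zero():
    x = [1.0, 2.0, 3.0, 1.0, 2.0, 3.0]
    y = ["melanoma"] * 3 + ["control"] * 3
    assert fisher_index(x, y) == pytest.approx(0.0)


def test_fisher_index_zero_within_variance_is_infinite():
    assert fisher_index([0, 0, 0, 1, 1, 1], ["melanoma"] * 3 + ["control"] * 3) == math.inf
    assert fisher_index([2, 2, 2, 2], ["melanoma"] * 2 + ["control"] * 2) == 0.0


def test_fisher_index_from_exact_moments():
    """n1=n2=10, means 0 vs 1, sample sd 1 in both -> F = 5 by the formula."""
    base = np.arange(10, dtype=float)
    g = (base - base.mean()) / base.std(ddof=1)  # mean 0, sd 1 exactly
    x = np.concatenate([g + 1.0, g])
    y = ["melanoma"] * 10 + ["control"] * 10
    assert fisher_index(x, y) == pytest.approx(5.0, abs=1e-9)


@given(a=st.floats(0.1, 100.0), b=st.floats(-50.0, 50.0))
def test_fisher_index_affine_invariant(a, b):
    rng = np.random.default_rng(2)
    x = rng.standard_normal(30)
    x[:15] += 1.0
    y = ["melanoma"] * 15 + ["control"] * 15
    assert fisher_index(a * x + b, y) == pytest.approx(fisher_index(x, y), rel=1e-9)


def test_select_features_recovers_planted(rng):
    """3 planted mean-shifted features among 50 noise features are ranked first."""
    n = 60
    X = rng.standard_normal((n, 53))
    labels = ["melanoma"] * 30 + ["control"] * 30
    planted = ["f0", "f1", "f2"]
    X[:30, :3] += 3.0
    fm = _fm(X, labels)
    top = select_features(fm, 3)
    assert {s.feature for s in top} == set(planted)
    assert [s.rank for s in top] == [1, 2, 3]


def test_select_features_one_third_rule():
    rng = np.random.default_rng(0)
    fm = _gaussian_fm(rng, n_per_class=19, p=20)
    fm.values = fm.values.iloc[:37]
    fm.labels = fm.labels.iloc[:37]
    with pytest.raises(ValueError, match="one-third"):
        select_features(fm, 13)
    assert len(select_features(fm, 12)) == 12


def test_select_features_deterministic_under_ties():
    X = np.ones((12, 4))
    labels = ["melanoma"] * 6 + ["control"] * 6
    fm = _fm(X, labels)
    top = select_features(fm, 3)
    assert [s.feature for s in top] == ["f0", "f1", "f2"]
    assert all(s.fisher_index == 0.0 for s in top)


def test_fit_lda_separable_training_accuracy(rng):
    fm = _gaussian_fm(rng, shift=8.0)
    model = fit_lda(fm, ["f0", "f1"])
    pred, _ = classify(model, fm)
    assert (pred == fm.labels).all()


def test_fit_lda_matches_brute_force_direction(rng):
    """Weight direction maximizes the Fisher ratio J(w) on 2-feature data."""
    for trial in range(5):
        n = 25
        X = rng.standard_normal((2 * n, 2)) @ np.array([[1.0, 0.6], [0.0, 0.8]])
        X[:n] += np.array([1.5, 0.5])
        fm = _fm(X, ["melanoma"] * n + ["control"] * n)
        model = fit_lda(fm, ["f0", "f1"])

        mu1 = X[:n].mean(axis=0)
        mu0 = X[n:].mean(axis=0)
        sb = np.outer(mu1 - mu0, mu1 - mu0)
        sw = np.zeros((2, 2))
        for sub in (X[:n], X[n:]):
            c = sub - sub.mean(axis=0)
            sw += c.T @ c
        best, best_j = None, -np.inf
        for theta in np.linspace(0, np.pi, 20000, endpoint=False):
            w = np.array([np.cos(theta), np.sin(theta)])
            j = (w @ sb @ w) / (w @ sw @ w)
            if j > best_j:
                best, best_j = w, j
        cos = abs(model.weights @ best) / np.linalg.norm(model.weights)
        assert cos > 0.999


def test_fit_lda_agrees_with_reference_implementation(rng):
    """Cross-check predictions against sklearn's LDA with equal priors."""
    sklearn_lda = pytest.importorskip("sklearn.discriminant_analysis")
    fm = _gaussian_fm(rng, n_per_class=25, p=4, shift=1.5)
    model = fit_lda(fm, list(fm.values.columns), shrinkage=0.0)
    pred, _ = classify(model, fm)
    ref = sklearn_lda.LinearDiscriminantAnalysis(priors=[0.5, 0.5])
    ref.fit(fm.values.to_numpy(), fm.labels.to_numpy())
    ref_pred = ref.predict(fm.values.to_numpy())
    assert (pred.to_numpy() == ref_pred).mean() == 1.0
    cos = abs(ref.coef_[0] @ model.weights) / (
        np.linalg.norm(ref.coef_[0]) * np.linalg.norm(model.weights)
    )
    assert cos > 0.999


def test_classify_feature_rescaling_invariance(rng):
    fm = _gaussian_fm(rng, shift=2.0)
    model = fit_lda(fm, ["f0", "f1"])
    pred1, _ = classify(model, fm)
    scaled = FeatureMatrix(fm.values * [10.0, 0.2], fm.labels)
    model2 = fit_lda(scaled, ["f0", "f1"])
    pred2, _ = classify(model2, scaled)
    assert (pred1 == pred2).all()


def test_classify_threshold_tie_goes_to_melanoma(rng):
    fm = _gaussian_fm(rng)
    model = fit_lda(fm, ["f0", "f1"])
    # construct a sample projecting exactly onto the threshold
    w = model.weights
    x = model.threshold * w / (w @ w)
    probe = _fm(x.reshape(1, 2), ["unknown"])
    probe.labels[:] = "control"  # label irrelevant for prediction
    pred, proj = classify(model, probe)
    assert proj.iloc[0] == pytest.approx(model.threshold)
    assert pred.iloc[0] == "melanoma"


def test_classify_missing_feature_errors(rng):
    fm = _gaussian_fm(rng)
    model = fit_lda(fm, ["f0", "f1"])
    with pytest.raises(ValueError, match="lacks"):
        classify(model, _fm(fm.values[["f0"]].to_numpy(), fm.labels.tolist(), ["f0"]))


def test_ablation_signal_collapse(rng):
    """Dropping the only informative feature collapses accuracy to ~chance."""
    n = 20
    X = rng.standard_normal((2 * n, 3))
    X[:n, 0] += 6.0
    fm = _fm(X, ["melanoma"] * n + ["control"] * n)
    reports = ablation(fm, ["f0", "f1", "f2"])
    assert len(reports) == 3
    assert reports["f1"].accuracy == 100.0 and reports["f2"].accuracy == 100.0
    assert reports["f0"].accuracy < 75.0


def test_ablation_duplicate_feature_redundant(rng):
    n = 20
    X = rng.standard_normal((2 * n, 2))
    X[:n, 0] += 4.0
    X = np.column_stack([X, X[:, 0]])
    fm = _fm(X, ["melanoma"] * n + ["control"] * n)
    reports = ablation(fm, ["f0", "f1", "f2"])
    assert reports["f2"].accuracy == reports["f1"].accuracy == 100.0


def test_cross_validate_bookkeeping(default_features):
    """37 samples, 25 train, 10 reps -> exactly 120 pooled predictions."""
    report = cross_validate(default_features, CrossValPlan(seed=3), k=10)
    assert report.total == 120


def test_cross_validate_reproducible(default_features):
    r1 = cross_validate(default_features, CrossValPlan(seed=11), k=10)
    r2 = cross_validate(default_features, CrossValPlan(seed=11), k=10)
    assert r1 == r2


def test_cross_validate_separable_is_perfect(rng):
    fm = _gaussian_fm(rng, n_per_class=20, shift=10.0)
    report = cross_validate(
        fm, CrossValPlan(n_train=27, n_reps=5, seed=2), features=["f0", "f1"]
    )
    assert report.accuracy == 100.0


def test_cross_validate_stratified_keeps_balance(default_features):
    report = cross_validate(
        default_features, CrossValPlan(seed=5, stratified=True), k=10
    )
    assert report.total == 120


@pytest.mark.parametrize(
    "counts, expected",
    [
        # S100B row: 12/18 melanomas missed, 18/19 controls correct
        ((6, 12, 18, 1), {"sensitivity": 33.3, "specificity": 94.7, "ppv": 85.7, "npv": 60.0}),
        # resubstitution classification: 3 + 1 errors
        ((15, 3, 18, 1), {"accuracy": 89.2, "sensitivity": 83.3, "npv": 85.7}),
        # cross-validation: 52/55 and 64/65 correct
        ((52, 3, 64, 1), {"accuracy": 96.7, "specificity": 98.5, "ppv": 98.1, "npv": 95.5}),
    ],
)
def test_confusion_metrics_printed_rows(counts, expected):
    report = confusion_metrics(*counts)
    for metric, value in expected.items():
        assert getattr(report, metric) == value


def test_confusion_metrics_zero_denominator_is_not_available():
    report = confusion_metrics(0, 0, 5, 1)
    assert report.sensitivity is None
    assert report.specificity == pytest.approx(83.3)


def test_confusion_metrics_recompute_from_counts():
    r = confusion_metrics(52, 3, 64, 1)
    d = r.as_dict()
    assert d["tp"] + d["fn"] + d["tn"] + d["fp"] == r.total == 120
    assert d["positive_class"] == "melanoma"
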