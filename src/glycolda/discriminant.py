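"""Fisher-index feature ranking, two-class LDA, ablation and leave-1/3-out CV.

Fisher's index of one feature is the classical one-way ANOVA variance ratio

    F = [ sum_g n_g (mu_g - mu)^2 / (G-1) ] / [ sum_g sum_i (x_gi - mu_g)^2 / (n-G) ]

— the higher F, the better the univariate class separation.  The classifier
is Fisher's linear discriminant: the weight vector solves S_w w = mu_mel -
mu_ctrl with S_w the pooled within-class scatter (shrinkage-regularized),
and a sample is called melanoma when its projection falls on the melanoma
side of the midpoint between the projected class means (equal priors; ties
go to melanoma).  Performance is assessed by repeated random-subsampling
("leave-1/3-out") cross-validation: by default 25 of 37 samples train the
model and the 12 held-out samples are predicted, repeated 10 times, pooling
120 predictions.

A general small-sample rule limits the number of predictors to fewer than
one-third of the sample count; it is enforced at feature-selection time
against the full cohort size.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import linalg

from .masses import round_half_away
from .quantify import FeatureMatrix

__all__ = [
    "POSITIVE_CLASS",
    "NEGATIVE_CLASS",
    "FeatureScore",
    "LDAModel",
    "ClassificationReport",
    "CrossValPlan",
    "fisher_index",
    "select_features",
    "fit_lda",
    "classify",
    "ablation",
    "cross_validate",
    "confusion_metrics",
]

POSITIVE_CLASS = "melanoma"
NEGATIVE_CLASS = "control"


@dataclass(frozen=True)
class FeatureScore:
    feature: str
    fisher_index: float
    rank: int


@dataclass
class LDAModel:
    features: list[str]
    weights: np.ndarray
    threshold: float
    projected_means: dict[str, float]
    shrinkage: float = 1e-3
    meta: dict = field(default_factory=dict)


@dataclass(frozen=True)
class ClassificationReport:
    """Confusion counts (melanoma = positive) with derived metrics in percent.

    Metrics are rounded to one decimal, half away from zero; a metric whose
    denominator is zero is reported as None (not available), never as 0.
    """

    tp: int
    fn: int
    tn: int
    fp: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fn, self.tn, self.fp) < 0:
            raise ValueError("confusion counts must be >= 0")
        if self.total == 0:
            raise ValueError("confusion matrix is empty")

    @property
    def total(self) -> int:
        return self.tp + self.fn + self.tn + self.fp

    @staticmethod
    def _pct(num: int, den: int) -> Optional[float]:
        if den == 0:
            return None
        return round_half_away(100.0 * num / den, 1)

    @property
    def sensitivity(self) -> Optional[float]:
        return self._pct(self.tp, self.tp + self.fn)

    @property
    def specificity(self) -> Optional[float]:
        return self._pct(self.tn, self.tn + self.fp)

    @property
    def ppv(self) -> Optional[float]:
        return self._pct(self.tp, self.tp + self.fp)

    @property
    def npv(self) -> Optional[float]:
        return self._pct(self.tn, self.tn + self.fn)

    @property
    def accuracy(self) -> Optional[float]:
        return self._pct(self.tp + self.tn, self.total)

    def as_dict(self) -> dict:
        return {
            "positive_class": POSITIVE_CLASS,
            "tp": self.tp,
            "fn": self.fn,
            "tn": self.tn,
            "fp": self.fp,
            "sensitivity_pct": self.sensitivity,
            "specificity_pct": self.specificity,
            "ppv_pct": self.ppv,
            "npv_pct": self.npv,
            "accuracy_pct": self.accuracy,
        }


@dataclass
class CrossValPlan:
    """Repeated random-subsampling plan (leave-1/3-out by default)."""

    n_train: int = 25
    n_reps: int = 10
    seed: int = 0
    stratified: bool = False


def confusion_metrics(tp: int, fn: int, tn: int, fp: int) -> ClassificationReport:
    """Build a report from raw confusion counts."""
    return ClassificationReport(tp=tp, fn=fn, tn=tn, fp=fp)


def fisher_index(values: Sequence[float], labels: Sequence[str]) -> float:
    """Between- over within-group variance ratio for one feature (two classes).

    Zero within-group variance with distinct means returns +inf (perfect
    univariate separation sentinel); zero between and within returns 0.
    """
    x = np.asarray(values, dtype=float)
    y = np.asarray(labels)
    if not np.all(np.isfinite(x)):
        raise ValueError("feature values must be finite")
    classes = [POSITIVE_CLASS, NEGATIVE_CLASS]
    groups = [x[y == c] for c in classes]
    if any(len(g) < 2 for g in groups):
        raise ValueError("each class needs >= 2 samples")
    n = len(x)
    g = len(groups)
    mu = x.mean()
    between = sum(len(grp) * (grp.mean() - mu) ** 2 for grp in groups) / (g - 1)
    within = sum(((grp - grp.mean()) ** 2).sum() for grp in groups) / (n - g)
    if within == 0:
        return math.inf if between > 0 else 0.0
    return float(between / within)


def select_features(
    matrix: FeatureMatrix, k: int, n_total: Optional[int] = None
) -> list[FeatureScore]:
    """Rank features by Fisher's index and return the top k.

    Enforces the small-sample rule k < n/3, with n the cohort size
    (``n_total`` lets callers that select inside a training fold apply the
    rule against the full cohort, as the original procedure does).  Ties
    (including multiple infinite scores) are broken by feature descriptor,
    lexicographically, so selection is deterministic.
    """
    n = n_total if n_total is not None else len(matrix.values)
    if not k >= 1:
        raise ValueError("k must be >= 1")
    if k >= n / 3:
        raise ValueError(
            f"k={k} violates the one-third rule: the number of independent variables "
            f"must be less than one-third of the sample count (n={n}, so k < {n / 3:.1f})"
        )
    labels = matrix.labels.to_numpy()
    scored = [
        (col, fisher_index(matrix.values[col].to_numpy(), labels))
        for col in matrix.values.columns
    ]
    scored.sort(key=lambda t: (-t[1], t[0]))
    return [
        FeatureScore(feature=col, fisher_index=f, rank=r + 1)
        for r, (col, f) in enumerate(scored[:k])
    ]


def fit_lda(
    matrix: FeatureMatrix,
    features: Sequence[str],
    shrinkage: float = 1e-3,
    meta: Optional[dict] = None,
) -> LDAModel:
    """Fit Fisher's linear discriminant on the given features.

    Solves (1-l) S_w + l diag(S_w) applied to w = mu_mel - mu_ctrl, orients
    w so melanoma projects high, and sets the decision threshold at the
    midpoint of the projected class means.
    """
    features = list(features)
    missing = [f for f in features if f not in matrix.values.columns]
    if missing:
        raise ValueError(f"features not in matrix: {missing}")
    X = matrix.values[features].to_numpy(dtype=float)
    y = matrix.labels.to_numpy()
    n, p = X.shape
    if p >= n:
        raise ValueError("need fewer features than samples")
    groups = {}
    for cls in (POSITIVE_CLASS, NEGATIVE_CLASS):
        sub = X[y == cls]
        if len(sub) < 2:
            raise ValueError(f"need >= 2 samples of class {cls!r}")
        groups[cls] = sub
    mu_pos = groups[POSITIVE_CLASS].mean(axis=0)
    mu_neg = groups[NEGATIVE_CLASS].mean(axis=0)
    s_w = np.zeros((p, p))
    for sub in groups.values():
        centered = sub - sub.mean(axis=0)
        s_w += centered.T @ centered
    if shrinkage > 0:
        s_w = (1.0 - shrinkage) * s_w + shrinkage * np.diag(np.diag(s_w))
    try:
        w = linalg.solve(s_w, mu_pos - mu_neg, assume_a="sym")
    except linalg.LinAlgError as err:
        raise ValueError(
            f"within-class scatter singular at shrinkage {shrinkage}; increase shrinkage"
        ) from err
    if not np.any(w):
        raise ValueError("degenerate discriminant: identical class means")
    if w @ (mu_pos - mu_neg) < 0:
        w = -w
    proj_pos = float(w @ mu_pos)
    proj_neg = float(w @ mu_neg)
    return LDAModel(
        features=features,
        weights=w,
        threshold=(proj_pos + proj_neg) / 2.0,
        projected_means={POSITIVE_CLASS: proj_pos, NEGATIVE_CLASS: proj_neg},
        shrinkage=shrinkage,
        meta=dict(meta or {}),
    )


def classify(model: LDAModel, matrix: FeatureMatrix) -> tuple[pd.Series, pd.Series]:
    """Predict labels; also return projected coordinates for plotting.

    A sample exactly at the threshold is assigned to melanoma (documented
    tie rule: the screening-oriented choice).
    """
    missing = [f for f in model.features if f not in matrix.values.columns]
    if missing:
        raise ValueError(f"matrix lacks model features: {missing}")
    X = matrix.values[model.features].to_numpy(dtype=float)
    scores = X @ model.weights
    labels = np.where(scores >= model.threshold, POSITIVE_CLASS, NEGATIVE_CLASS)
    idx = matrix.values.index
    return pd.Series(labels, index=idx, name="predicted"), pd.Series(
        scores, index=idx, name="projection"
    )


def _confusion(true: pd.Series, pred: pd.Series) -> tuple[int, int, int, int]:
    tp = int(((true == POSITIVE_CLASS) & (pred == POSITIVE_CLASS)).sum())
    fn = int(((true == POSITIVE_CLASS) & (pred == NEGATIVE_CLASS)).sum())
    tn = int(((true == NEGATIVE_CLASS) & (pred == NEGATIVE_CLASS)).sum())
    fp = int(((true == NEGATIVE_CLASS) & (pred == POSITIVE_CLASS)).sum())
    return tp, fn, tn, fp


def ablation(
    matrix: FeatureMatrix,
    features: Sequence[str],
    shrinkage: float = 1e-3,
) -> dict[str, ClassificationReport]:
    """Leave-one-variable-out resubstitution assessment.

    For each selected feature, refit on the remaining features and report
    the confusion counts on the training data itself; ordered as given.
    """
    features = list(features)
    if len(features) < 2:
        raise ValueError("ablation needs >= 2 features")
    out: dict[str, ClassificationReport] = {}
    for omitted in features:
        rest = [f for f in features if f != omitted]
        model = fit_lda(matrix, rest, shrinkage=shrinkage, meta={"omitted": omitted})
        pred, _ = classify(model, matrix)
        out[omitted] = ClassificationReport(*_confusion(matrix.labels, pred))
    return out


def cross_validate(
    matrix: FeatureMatrix,
    plan: CrossValPlan,
    features: Optional[Sequence[str]] = None,
    k: int = 10,
    nested: bool = False,
    shrinkage: float = 1e-3,
    max_redraws: int = 100,
) -> ClassificationReport:
    """Repeated random-subsampling CV pooling confusion counts over reps.

    By default the feature list is fixed before CV (selected once on the
    full cohort when ``features`` is None), mirroring the original
    procedure; ``nested=True`` instead re-runs Fisher selection inside each
    training fold, which avoids selection leakage and is the honest
    generalization estimate.  Unstratified draws that miss a class are
    redrawn (counted in the report meta) up to ``max_redraws``.
    """
    n = len(matrix.values)
    if not 0 < plan.n_train < n:
        raise ValueError(f"n_train must be in (0, {n})")
    if plan.n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    if not nested and features is None:
        features = [s.feature for s in select_features(matrix, k)]

    rng = np.random.default_rng(plan.seed)
    index = matrix.values.index
    labels = matrix.labels
    pos_idx = index[labels == POSITIVE_CLASS]
    neg_idx = index[labels == NEGATIVE_CLASS]
    counts = np.zeros(4, dtype=int)
    redraws = 0
    for _ in range(plan.n_reps):
        if plan.stratified:
            n_pos = round(plan.n_train * len(pos_idx) / n)
            train = list(rng.choice(pos_idx, n_pos, replace=False)) + list(
                rng.choice(neg_idx, plan.n_train - n_pos, replace=False)
            )
        else:
            for _attempt in range(max_redraws + 1):
                train = list(rng.choice(index, plan.n_train, replace=False))
                picked = set(labels.loc[train])
                if POSITIVE_CLASS in picked and NEGATIVE_CLASS in picked:
                    break
                redraws += 1
            else:
                raise ValueError(f"training draw missing a class after {max_redraws} redraws")
        test = index.difference(train, sort=False)
        train_fm = FeatureMatrix(matrix.values.loc[train], labels.loc[train])
        if nested:
            fold_features = [s.feature for s in select_features(train_fm, k, n_total=n)]
        else:
            fold_features = list(features)
        model = fit_lda(train_fm, fold_features, shrinkage=shrinkage)
        test_fm = FeatureMatrix(matrix.values.loc[test], labels.loc[test])
        pred, _ = classify(model, test_fm)
        counts += np.array(_confusion(test_fm.labels, pred))
    report = ClassificationReport(*[int(c) for c in counts])
    assert report.total == plan.n_reps * (n - plan.n_train)
    if redraws:
        object.__setattr__(report, "_redraws", redraws)
    return report
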