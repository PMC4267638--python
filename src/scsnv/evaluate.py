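"""ROC analysis with 10-fold cross-validation and the paired AUC t-test.

The evaluation protocol: for every score (a single score variation or an
ensemble probability), sweep the cutoff over the whole score range to build
a ROC curve, report the area under it, and pick the cutoff that maximizes
accuracy *on the training folds*; sensitivity, specificity, accuracy, PPV
and NPV are then measured on the held-out fold at that cutoff.  All
quantities are arithmetic means over the k folds, and the k per-fold curves
are vertically averaged on a fixed 101-point false-positive-rate grid.
AUC differences between two scores sharing a fold assignment are compared
with the cross-validated paired t-test (df = k - 1).

A score is "positive" when strictly greater than the cutoff.  Rows whose
score is missing (NaN) for a given method are discarded from that method's
evaluation, mirroring the per-tool missing-score rule.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from sklearn.base import clone
from sklearn.metrics import roc_curve as _sk_roc_curve
from sklearn.model_selection import KFold, StratifiedKFold

from .ensemble import GentleBoostClassifier, SpliceRandomForest, predict_scores
from .variation import FeatureRow, FEATURE_NAMES_7, FEATURE_NAMES_11


@dataclass
class RocCurve:
    fpr: np.ndarray
    tpr: np.ndarray
    auc: float


@dataclass
class ConfusionMetrics:
    """Confusion counts and the derived rates; None marks undefined ratios."""

    tp: int
    fp: int
    tn: int
    fn: int
    sensitivity: float | None = field(init=False)
    specificity: float | None = field(init=False)
    accuracy: float | None = field(init=False)
    ppv: float | None = field(init=False)
    npv: float | None = field(init=False)

    def __post_init__(self):
        for name in ("tp", "fp", "tn", "fn"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        total = self.tp + self.fp + self.tn + self.fn
        if total == 0:
            raise ValueError("empty confusion table")

        def ratio(num, den):
            return num / den if den > 0 else None

        self.sensitivity = ratio(self.tp, self.tp + self.fn)
        self.specificity = ratio(self.tn, self.tn + self.fp)
        self.accuracy = (self.tp + self.tn) / total
        self.ppv = ratio(self.tp, self.tp + self.fp)
        self.npv = ratio(self.tn, self.tn + self.fn)


@dataclass
class CVReport:
    fold_aucs: list
    fold_cutoffs: list
    fold_metrics: list
    mean_auc: float
    mean_cutoff: float
    mean_metrics: dict
    grid_fpr: np.ndarray
    mean_tpr: np.ndarray
    fold_assignment: np.ndarray


@dataclass
class PairedTTest:
    differences: np.ndarray
    t: float
    df: int
    p: float


def _check_two_classes(labels):
    labels = np.asarray(labels)
    if np.unique(labels).size < 2:
        raise ValueError("both classes must be present")
    return labels


def roc_auc(scores, labels) -> RocCurve:
    """ROC curve over all unique-score thresholds, AUC by the trapezoid rule.

    Tied scores are grouped into a single step, so constant scores give the
    diagonal (AUC 0.5).
    """
    scores = np.asarray(scores, dtype=float)
    labels = _check_two_classes(labels)
    fpr, tpr, _ = _sk_roc_curve(labels, scores, drop_intermediate=False)
    return RocCurve(fpr, tpr, float(np.trapezoid(tpr, fpr)))


def _candidate_cutoffs(scores) -> np.ndarray:
    u = np.unique(scores)
    mids = (u[:-1] + u[1:]) / 2.0
    return np.concatenate([[-np.inf], mids, [np.inf]])


def optimum_cutoff(scores, labels) -> float:
    """Accuracy-maximizing cutoff (score > cutoff => positive call).

    Candidates are the midpoints between adjacent sorted unique scores plus
    the two infinities; ties are broken by highest sensitivity+specificity,
    then by the smallest cutoff.
    """
    scores = np.asarray(scores, dtype=float)
    labels = _check_two_classes(np.asarray(labels, dtype=int))
    n_pos = int((labels == 1).sum())
    n_neg = int((labels == 0).sum())
    best = None
    for c in _candidate_cutoffs(scores):
        pred = scores > c
        tp = int(np.sum(pred & (labels == 1)))
        fp = int(np.sum(pred & (labels == 0)))
        acc = (tp + (n_neg - fp)) / (n_pos + n_neg)
        sens_spec = tp / n_pos + (n_neg - fp) / n_neg
        key = (acc, sens_spec, -c)
        if best is None or key > best[0]:
            best = (key, c)
    return float(best[1])


def confusion_at_cutoff(scores, labels, cutoff) -> ConfusionMetrics:
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    pred = scores > cutoff
    return ConfusionMetrics(
        tp=int(np.sum(pred & (labels == 1))),
        fp=int(np.sum(pred & (labels == 0))),
        tn=int(np.sum(~pred & (labels == 0))),
        fn=int(np.sum(~pred & (labels == 1))),
    )


def confusion_from_counts(tp, fn, fp, tn) -> ConfusionMetrics:
    return ConfusionMetrics(tp=tp, fp=fp, tn=tn, fn=fn)


class SingleFeatureScorer:
    """Scores rows by one raw feature column; the degenerate 'model'.

    Used to evaluate each score variation on its own under the same CV
    protocol as the ensembles.
    """

    def __init__(self, feature):
        self.feature = feature

    def get_params(self, deep=True):
        return {"feature": self.feature}

    def set_params(self, **params):
        for k, v in params.items():
            setattr(self, k, v)
        return self

    def _index(self, n_features: int) -> int:
        if isinstance(self.feature, str):
            names = FEATURE_NAMES_7 if n_features == 7 else FEATURE_NAMES_11
            return names.index(self.feature)
        return int(self.feature)

    def fit(self, X, y=None):
        return self

    def score_rows(self, X: np.ndarray) -> np.ndarray:
        return X[:, self._index(X.shape[1])]


def _rows_to_xy(rows):
    if isinstance(rows, tuple):
        X, y = rows
        return np.asarray(X, dtype=float), np.asarray(y, dtype=int)
    if rows and isinstance(rows[0], FeatureRow):
        X = np.vstack([r.features for r in rows])
        y = np.asarray([r.label for r in rows], dtype=int)
        return X, y
    raise TypeError("rows must be FeatureRow list or (X, y) tuple")


def _model_scores(model, X) -> np.ndarray:
    if isinstance(model, SingleFeatureScorer):
        return model.score_rows(X)
    return predict_scores(model, X)


def resolve_model_spec(spec, seed=None):
    """Map a model spec string to an estimator.

    Accepted: "ada" (gentle boost, 7 or 11 features), "ada_real" (real
    boost), "rf", "single:<feature-name-or-index>", or any object already
    implementing fit/predict_proba.
    """
    if not isinstance(spec, str):
        return spec
    if spec in ("ada", "ada_gentle"):
        return GentleBoostClassifier(variant="gentle", loss="logistic", random_state=seed)
    if spec == "ada_real":
        return GentleBoostClassifier(variant="real", loss="logistic", random_state=seed)
    if spec == "rf":
        return SpliceRandomForest(random_state=seed)
    if spec.startswith("single:"):
        feat = spec.split(":", 1)[1]
        return SingleFeatureScorer(int(feat) if feat.isdigit() else feat)
    raise ValueError(f"unknown model spec {spec!r}")


def _clone_model(model):
    if isinstance(model, SingleFeatureScorer):
        return SingleFeatureScorer(model.feature)
    try:
        return clone(model)
    except TypeError:
        return model


def cross_validate(rows, model_spec, k: int = 10, seed=None, stratified: bool = True) -> CVReport:
    """k-fold cross-validated ROC evaluation of one scoring model.

    Per fold: fit on the k-1 training folds, pick the accuracy-maximizing
    cutoff on the training-fold scores, then measure AUC and confusion
    metrics on the held-out fold.  Rows the model cannot score (NaN) are
    discarded from that fold's evaluation.
    """
    X, y = _rows_to_xy(rows)
    n = X.shape[0]
    if n < k:
        raise ValueError(f"n={n} < k={k}")
    _check_two_classes(y)
    model = resolve_model_spec(model_spec, seed=seed)

    if stratified:
        splitter = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    else:
        splitter = KFold(n_splits=k, shuffle=True, random_state=seed)
    assignment = np.empty(n, dtype=int)
    fold_aucs, fold_cutoffs, fold_metrics = [], [], []
    grid = np.linspace(0.0, 1.0, 101)
    tprs = []

    for fold, (tr, te) in enumerate(splitter.split(X, y)):
        assignment[te] = fold
        if np.unique(y[tr]).size < 2:
            raise ValueError(
                "a training fold lacks a class; use stratified fold assignment"
            )
        m = _clone_model(model).fit(X[tr], y[tr])
        tr_scores = _model_scores(m, X[tr])
        tr_ok = np.isfinite(tr_scores)
        cutoff = optimum_cutoff(tr_scores[tr_ok], y[tr][tr_ok])
        te_scores = _model_scores(m, X[te])
        te_ok = np.isfinite(te_scores)
        s, l = te_scores[te_ok], y[te][te_ok]
        fold_cutoffs.append(cutoff)
        fold_metrics.append(confusion_at_cutoff(s, l, cutoff) if s.size else None)
        if s.size and np.unique(l).size == 2:
            curve = roc_auc(s, l)
            fold_aucs.append(curve.auc)
            tprs.append(np.interp(grid, curve.fpr, curve.tpr))
        else:
            fold_aucs.append(float("nan"))

    aucs = np.asarray(fold_aucs)
    mean_tpr = np.mean(tprs, axis=0) if tprs else np.full_like(grid, np.nan)
    if tprs:
        mean_tpr[0], mean_tpr[-1] = 0.0, 1.0
    metric_names = ("accuracy", "sensitivity", "specificity", "ppv", "npv")
    mean_metrics = {}
    for name in metric_names:
        vals = [getattr(m, name) for m in fold_metrics if m is not None]
        vals = [v for v in vals if v is not None]
        mean_metrics[name] = float(np.mean(vals)) if vals else float("nan")
    return CVReport(
        fold_aucs=fold_aucs,
        fold_cutoffs=fold_cutoffs,
        fold_metrics=fold_metrics,
        mean_auc=float(np.nanmean(aucs)) if np.isfinite(aucs).any() else float("nan"),
        mean_cutoff=float(np.mean([c for c in fold_cutoffs if np.isfinite(c)])),
        mean_metrics=mean_metrics,
        grid_fpr=grid,
        mean_tpr=mean_tpr,
        fold_assignment=assignment,
    )


def cv_paired_ttest(aucs_a, aucs_b) -> PairedTTest:
    """Paired t-test on per-fold AUC differences (df = k - 1).

    Degenerate inputs: identical AUCs give t=0, p=1; constant nonzero
    differences give |t|=inf, p=0 (the zero-variance limit).
    """
    a = np.asarray(aucs_a, dtype=float)
    b = np.asarray(aucs_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("fold AUC vectors must be 1-d and equal length")
    k = a.size
    if k < 2:
        raise ValueError("need at least 2 folds")
    d = a - b
    mean = d.mean()
    sd = d.std(ddof=1)
    if sd == 0:
        if mean == 0:
            return PairedTTest(d, 0.0, k - 1, 1.0)
        return PairedTTest(d, float(np.sign(mean)) * float("inf"), k - 1, 0.0)
    t = mean * np.sqrt(k) / sd
    p = 2.0 * stats.t.sf(abs(t), k - 1)
    return PairedTTest(d, float(t), k - 1, float(p))


#: Scores evaluated in the standard comparison report, in display order.
REPORT_MODELS_7 = [(name, f"single:{name}") for name in FEATURE_NAMES_7] + [
    ("AdaBoost", "ada"),
    ("Random forests", "rf"),
]


def comparison_report(rows, k: int = 10, seed=None, include_11: bool = True):
    """Cross-validated AUC/cutoff/metrics table over single scores + ensembles.

    With 11-feature rows (and ``include_11``), the 11-score ensembles are
    appended: real-boost AdaBoost (ada_add) and the forest (rf_add).
    Returns ``{name: CVReport}`` in display order.
    """
    X, y = _rows_to_xy(rows)
    out = {}
    for name, spec in REPORT_MODELS_7:
        if spec.startswith("single:"):
            out[name] = cross_validate((X, y), spec, k=k, seed=seed)
        else:
            out[name] = cross_validate((X[:, :7], y), spec, k=k, seed=seed)
    if include_11 and X.shape[1] == 11:
        out["ada_add"] = cross_validate((X, y), "ada_real", k=k, seed=seed)
        out["rf_add"] = cross_validate((X, y), "rf", k=k, seed=seed)
    return out
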