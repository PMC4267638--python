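"""Ensemble classifiers producing splice-altering probability scores.

Two models are trained on the score-variation feature table:

* :class:`GentleBoostClassifier` — additive boosting with small regression
  (gentle boost) or class-probability (real boost) trees, fitted under a
  logistic or exponential loss.  The additive margin F(x) is mapped to a
  probability via 1/(1 + exp(-2F)); the output is the ``ada_score``.
  Missing feature values are tolerated: each base tree learns, per split,
  which child minimizes weighted training loss for missing values and reuses
  that route at prediction.
* :class:`SpliceRandomForest` — a thin wrapper around a standard random
  forest (500 trees, sqrt(p) features per split).  The fraction of trees
  voting positive is the ``rf_score``.  Rows with missing cells are dropped
  at training (with a recorded count) and refused at prediction.

Both follow the scikit-learn estimator protocol and serialize to versioned
JSON without pickling.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin, clone
from sklearn.ensemble import RandomForestClassifier
from sklearn.tree import DecisionTreeClassifier, DecisionTreeRegressor
from sklearn.utils import check_random_state
from sklearn.utils.validation import check_is_fitted

from .variation import FeatureRow

_PROB_EPS = 1e-6


@dataclass
class ImportanceReport:
    """Per-feature relative importance of a trained ensemble."""

    importances: np.ndarray
    measure: str  # boost_selection_frequency | mean_decrease_accuracy
    feature_names: tuple | None = None


def _as_matrix(rows):
    """FeatureRow list or array-like -> (X, y or None)."""
    if isinstance(rows, (list, tuple)) and rows and isinstance(rows[0], FeatureRow):
        X = np.vstack([r.features for r in rows])
        labels = [r.label for r in rows]
        y = None if any(l is None for l in labels) else np.asarray(labels, dtype=int)
        return X, y
    return np.asarray(rows, dtype=float), None


class GentleBoostClassifier(ClassifierMixin, BaseEstimator):
    """Adaptive boosting with gentle/real base updates under logistic loss.

    Parameters
    ----------
    variant : {"gentle", "real"}
        Gentle boost fits a weighted least-squares regression tree to the
        +/-1 response each round; real boost fits a weighted classification
        tree and uses the half log-odds of its leaf probabilities.
    loss : {"logistic", "exponential"}
        Drives the example re-weighting; logistic is the default.
    n_iter : int
        Number of boosting rounds (base trees).
    max_depth : int
        Depth of each base tree (2 keeps the learners weak).
    random_state : int or None
        Seeds base-learner tie-breaking; fits are reproducible given it.

    Notes
    -----
    Each round is accepted at the largest step size in {1, 1/2, 1/4, 1/8}
    that does not increase the training loss, so the recorded
    ``train_loss_path_`` is non-increasing by construction.
    """

    def __init__(
        self,
        variant: str = "gentle",
        loss: str = "logistic",
        n_iter: int = 50,
        max_depth: int = 2,
        random_state=None,
    ):
        self.variant = variant
        self.loss = loss
        self.n_iter = n_iter
        self.max_depth = max_depth
        self.random_state = random_state

    # margin-scale loss; yy in {-1,+1}
    def _loss(self, yy, F):
        if self.loss == "logistic":
            return float(np.mean(np.log1p(np.exp(-2.0 * yy * F))))
        return float(np.mean(np.exp(-yy * F)))

    def _weights(self, yy, F):
        if self.loss == "logistic":
            w = 1.0 / (1.0 + np.exp(2.0 * yy * F))
        else:
            w = np.exp(-yy * F)
        s = w.sum()
        if s <= 0 or not np.isfinite(s):
            w = np.full_like(w, 1.0 / len(w))
        else:
            w = w / s
        return w

    def fit(self, X, y=None):
        if self.variant not in ("gentle", "real"):
            raise ValueError(f"unknown variant {self.variant!r}")
        if self.loss not in ("logistic", "exponential"):
            raise ValueError(f"unknown loss {self.loss!r}")
        if self.n_iter < 1:
            raise ValueError("n_iter must be >= 1")
        X_rows, y_rows = _as_matrix(X)
        if y is None:
            y = y_rows
        X = np.asarray(X_rows, dtype=float)
        y = np.asarray(y)
        classes = np.unique(y)
        if not np.isin(classes, [0, 1]).all():
            raise ValueError("labels must be 0/1")
        if classes.size < 2:
            raise ValueError("training set contains a single class")
        if np.bincount(y.astype(int), minlength=2).min() < 2:
            raise ValueError("need at least 2 rows per class")
        rng = check_random_state(self.random_state)
        yy = 2.0 * y - 1.0
        n, p = X.shape
        self.classes_ = np.array([0, 1])
        self.n_features_in_ = p

        F = np.zeros(n)
        self.estimators_ = []
        self.estimator_steps_ = []
        self.train_loss_path_ = [self._loss(yy, F)]
        sel_counts = np.zeros(p)

        for _ in range(self.n_iter):
            w = self._weights(yy, F)
            seed = rng.randint(np.iinfo(np.int32).max)
            if self.variant == "gentle":
                tree = DecisionTreeRegressor(
                    max_depth=self.max_depth, random_state=seed
                )
                tree.fit(X, yy, sample_weight=w)
                f = tree.predict(X)
            else:
                tree = DecisionTreeClassifier(
                    max_depth=self.max_depth, random_state=seed
                )
                tree.fit(X, y, sample_weight=w)
                prob = tree.predict_proba(X)
                p1 = np.clip(prob[:, list(tree.classes_).index(1)], _PROB_EPS, 1 - _PROB_EPS)
                f = 0.5 * np.log(p1 / (1.0 - p1))
            # accept the largest step that does not raise training loss
            current = self.train_loss_path_[-1]
            best_step, best_loss = 0.0, current
            for step in (1.0, 0.5, 0.25, 0.125):
                cand = self._loss(yy, F + step * f)
                if cand <= best_loss:
                    best_step, best_loss = step, cand
                    break
            F = F + best_step * f
            self.estimators_.append(tree)
            self.estimator_steps_.append(best_step)
            self.train_loss_path_.append(best_loss)
            used = tree.tree_.feature
            for feat in used[used >= 0]:
                sel_counts[feat] += 1

        total = sel_counts.sum()
        self.selection_frequency_ = (
            sel_counts / total if total > 0 else np.full(p, 1.0 / p)
        )
        self.train_margin_ = F
        return self

    def decision_function(self, X) -> np.ndarray:
        check_is_fitted(self, "estimators_")
        X, _ = _as_matrix(X)
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != self.n_features_in_:
            raise ValueError(
                f"expected {self.n_features_in_} features, got {X.shape[1] if X.ndim == 2 else 'non-2d'}"
            )
        F = np.zeros(X.shape[0])
        for tree, step in zip(self.estimators_, self.estimator_steps_):
            if step == 0.0:
                continue
            if isinstance(tree, DecisionTreeRegressor):
                f = tree.predict(X)
            else:
                prob = tree.predict_proba(X)
                p1 = np.clip(prob[:, list(tree.classes_).index(1)], _PROB_EPS, 1 - _PROB_EPS)
                f = 0.5 * np.log(p1 / (1.0 - p1))
            F += step * f
        return F

    def predict_proba(self, X) -> np.ndarray:
        p1 = 1.0 / (1.0 + np.exp(-2.0 * self.decision_function(X)))
        return np.column_stack([1.0 - p1, p1])

    def predict(self, X) -> np.ndarray:
        return (self.predict_proba(X)[:, 1] > 0.5).astype(int)

    def importance(self) -> ImportanceReport:
        """Fraction of split selections going to each feature (sums to 1)."""
        check_is_fitted(self, "selection_frequency_")
        return ImportanceReport(
            self.selection_frequency_.copy(), "boost_selection_frequency"
        )


class SpliceRandomForest(ClassifierMixin, BaseEstimator):
    """Random forest emitting the fraction of trees voting splice-altering.

    Defaults mirror the standard implementation: 500 trees, sqrt(p) features
    tried per split, unlimited depth, bootstrap sampling with out-of-bag
    (OOB) accuracy.  Rows with missing cells are dropped at fit time
    (``n_dropped_`` records how many) and refused at prediction, because the
    underlying trees require complete cases.
    """

    def __init__(self, n_trees: int = 500, mtry=None, random_state=None):
        self.n_trees = n_trees
        self.mtry = mtry
        self.random_state = random_state

    def fit(self, X, y=None):
        X_rows, y_rows = _as_matrix(X)
        if y is None:
            y = y_rows
        X = np.asarray(X_rows, dtype=float)
        y = np.asarray(y, dtype=int)
        complete = ~np.isnan(X).any(axis=1)
        self.n_dropped_ = int((~complete).sum())
        X, y = X[complete], y[complete]
        if X.shape[0] == 0:
            raise ValueError("all rows have missing cells; nothing to train on")
        if np.unique(y).size < 2:
            raise ValueError("training set contains a single class")
        mtry = self.mtry if self.mtry is not None else "sqrt"
        self.forest_ = RandomForestClassifier(
            n_estimators=self.n_trees,
            max_features=mtry,
            oob_score=True,
            random_state=self.random_state,
            n_jobs=1,
        )
        self.forest_.fit(X, y)
        self.oob_score_ = float(self.forest_.oob_score_)
        self.classes_ = self.forest_.classes_
        self.n_features_in_ = X.shape[1]
        self._X_train, self._y_train = X, y
        return self

    def _check_complete(self, X):
        if np.isnan(X).any():
            bad = np.where(np.isnan(X).any(axis=1))[0]
            raise ValueError(
                f"random forest cannot score rows with missing cells (rows {bad[:10].tolist()}...)"
            )

    def predict_proba(self, X) -> np.ndarray:
        check_is_fitted(self, "forest_")
        X, _ = _as_matrix(X)
        X = np.asarray(X, dtype=float)
        if X.shape[0] == 0:
            return np.zeros((0, 2))
        if X.shape[1] != self.n_features_in_:
            raise ValueError(f"expected {self.n_features_in_} features")
        self._check_complete(X)
        # fraction of trees voting for each class, matching the vote-based score
        votes = np.zeros((X.shape[0], 2))
        for tree in self.forest_.estimators_:
            pred = tree.predict(X).astype(int)  # labels are 0/1 by construction
            votes[np.arange(X.shape[0]), pred] += 1
        return votes / len(self.forest_.estimators_)

    def predict(self, X) -> np.ndarray:
        return (self.predict_proba(X)[:, 1] > 0.5).astype(int)

    def _oob_mask(self, tree, n: int) -> np.ndarray:
        # replicate the bootstrap draw to recover each tree's OOB rows
        rng = check_random_state(tree.random_state)
        sampled = rng.randint(0, n, n)
        mask = np.ones(n, dtype=bool)
        mask[sampled] = False
        return mask

    def importance(self, n_repeats: int = 1, random_state=0) -> ImportanceReport:
        """OOB permutation importance: mean decrease in accuracy per feature."""
        check_is_fitted(self, "forest_")
        X, y = self._X_train, self._y_train
        n, p = X.shape
        rng = check_random_state(random_state)
        drops = np.zeros(p)
        counts = np.zeros(p)
        for tree in self.forest_.estimators_:
            oob = self._oob_mask(tree, n)
            if oob.sum() < 2:
                continue
            Xo, yo = X[oob], y[oob]
            base = (tree.predict(Xo).astype(int) == yo).mean()
            for j in range(p):
                for _ in range(n_repeats):
                    Xp = Xo.copy()
                    Xp[:, j] = rng.permutation(Xp[:, j])
                    acc = (tree.predict(Xp).astype(int) == yo).mean()
                    drops[j] += base - acc
                    counts[j] += 1
        imp = np.where(counts > 0, drops / np.maximum(counts, 1), 0.0)
        return ImportanceReport(imp, "mean_decrease_accuracy")


# -- pipeline-level helpers --------------------------------------------------


def train_adaboost(rows, variant="gentle", loss="logistic", n_iter=50, seed=None):
    return GentleBoostClassifier(
        variant=variant, loss=loss, n_iter=n_iter, random_state=seed
    ).fit(rows)


def train_random_forest(rows, n_trees=500, mtry=None, seed=None):
    return SpliceRandomForest(n_trees=n_trees, mtry=mtry, random_state=seed).fit(rows)


def predict_scores(model, rows) -> np.ndarray:
    """Probability of splice-altering per row; NaN where the model refuses.

    A random forest cannot score rows with missing cells; those come back as
    NaN rather than raising, so mixed tables can be annotated in one pass.
    """
    X, _ = _as_matrix(rows)
    X = np.asarray(X, dtype=float)
    if X.shape[0] == 0:
        return np.array([])
    if isinstance(model, SpliceRandomForest):
        out = np.full(X.shape[0], np.nan)
        complete = ~np.isnan(X).any(axis=1)
        if complete.any():
            out[complete] = model.predict_proba(X[complete])[:, 1]
        return out
    return model.predict_proba(X)[:, 1]


def importance(model) -> ImportanceReport:
    return model.importance()


def call_splice_altering(ada, rf, cutoff: float = 0.6, rule: str = "either") -> str:
    """Binary splice-altering call from the two ensemble scores.

    Strict ``>`` comparison at the cutoff.  ``rule="either"`` flags a variant
    when at least one available score exceeds the cutoff; ``rule="both"``
    requires both scores present and above it.  Returns "missing" when the
    available scores cannot decide.
    """
    if rule not in ("either", "both"):
        raise ValueError(f"unknown rule {rule!r}")
    ada_ok = ada is not None and not np.isnan(ada)
    rf_ok = rf is not None and not np.isnan(rf)
    if rule == "either":
        if not ada_ok and not rf_ok:
            return "missing"
        return "positive" if (ada_ok and ada > cutoff) or (rf_ok and rf > cutoff) else "negative"
    if not (ada_ok and rf_ok):
        return "missing"
    return "positive" if (ada > cutoff and rf > cutoff) else "negative"


# -- JSON serialization ------------------------------------------------------


def _tree_to_dict(tree) -> dict:
    t = tree.tree_
    return {
        "kind": "regressor" if isinstance(tree, DecisionTreeRegressor) else "classifier",
        "children_left": t.children_left.tolist(),
        "children_right": t.children_right.tolist(),
        "feature": t.feature.tolist(),
        "threshold": t.threshold.tolist(),
        "missing_go_to_left": t.missing_go_to_left.tolist(),
        "value": t.value.tolist(),
        "classes": getattr(tree, "classes_", np.array([])).tolist(),
    }


def save_model(model, path) -> None:
    """Serialize a trained ensemble to versioned JSON (no pickle)."""
    if isinstance(model, GentleBoostClassifier):
        d = {
            "format": "scsnv-adaboost",
            "version": 1,
            "params": model.get_params(),
            "steps": model.estimator_steps_,
            "trees": [_tree_to_dict(t) for t in model.estimators_],
            "selection_frequency": model.selection_frequency_.tolist(),
            "n_features": int(model.n_features_in_),
        }
    elif isinstance(model, SpliceRandomForest):
        d = {
            "format": "scsnv-rf",
            "version": 1,
            "params": model.get_params(),
            "trees": [_tree_to_dict(t) for t in model.forest_.estimators_],
            "classes": model.forest_.classes_.tolist(),
            "n_features": int(model.n_features_in_),
        }
    else:
        raise TypeError(f"cannot serialize {type(model).__name__}")
    with open(path, "w") as fh:
        json.dump(d, fh)


class _JsonTreePredictor:
    """Replays a serialized decision tree (explicit arrays, no pickle)."""

    def __init__(self, d: dict):
        self.left = np.asarray(d["children_left"])
        self.right = np.asarray(d["children_right"])
        self.feature = np.asarray(d["feature"])
        self.threshold = np.asarray(d["threshold"])
        self.missing_left = np.asarray(d["missing_go_to_left"])
        self.value = np.asarray(d["value"])
        self.kind = d["kind"]
        self.classes = np.asarray(d["classes"])

    def leaf_values(self, X: np.ndarray) -> np.ndarray:
        out = np.empty(X.shape[0])
        for i, x in enumerate(X):
            node = 0
            while self.left[node] != -1:
                f = self.feature[node]
                v = x[f]
                if np.isnan(v):
                    go_left = bool(self.missing_left[node])
                else:
                    go_left = v <= self.threshold[node]
                node = self.left[node] if go_left else self.right[node]
            val = self.value[node]
            if self.kind == "regressor":
                out[i] = val[0][0]
            else:
                probs = val[0] / val[0].sum()
                idx = int(np.where(self.classes == 1)[0][0]) if self.classes.size else 1
                out[i] = probs[idx]
        return out


class LoadedBoostModel:
    """Prediction-only boosting model restored from JSON."""

    def __init__(self, d: dict):
        self.params = d["params"]
        self.steps = d["steps"]
        self.trees = [_JsonTreePredictor(t) for t in d["trees"]]
        self.selection_frequency_ = np.asarray(d["selection_frequency"])
        self.n_features_in_ = d["n_features"]

    def decision_function(self, X) -> np.ndarray:
        X, _ = _as_matrix(X)
        X = np.asarray(X, dtype=float)
        F = np.zeros(X.shape[0])
        for tree, step in zip(self.trees, self.steps):
            if step == 0.0:
                continue
            if tree.kind == "regressor":
                f = tree.leaf_values(X)
            else:
                p1 = np.clip(tree.leaf_values(X), _PROB_EPS, 1 - _PROB_EPS)
                f = 0.5 * np.log(p1 / (1.0 - p1))
            F += step * f
        return F

    def predict_proba(self, X) -> np.ndarray:
        p1 = 1.0 / (1.0 + np.exp(-2.0 * self.decision_function(X)))
        return np.column_stack([1.0 - p1, p1])


class LoadedForestModel:
    """Prediction-only forest model restored from JSON."""

    def __init__(self, d: dict):
        self.params = d["params"]
        self.trees = [_JsonTreePredictor(t) for t in d["trees"]]
        self.classes_ = np.asarray(d["classes"])
        self.n_features_in_ = d["n_features"]

    def predict_proba(self, X) -> np.ndarray:
        X, _ = _as_matrix(X)
        X = np.asarray(X, dtype=float)
        if np.isnan(X).any():
            raise ValueError("random forest cannot score rows with missing cells")
        votes = np.zeros((X.shape[0], 2))
        for tree in self.trees:
            pred = (tree.leaf_values(X) > 0.5).astype(int)
            votes[np.arange(X.shape[0]), pred] += 1
        return votes / len(self.trees)


def load_model(path):
    with open(path) as fh:
        d = json.load(fh)
    fmt = d.get("format")
    if fmt == "scsnv-adaboost":
        return LoadedBoostModel(d)
    if fmt == "scsnv-rf":
        return LoadedForestModel(d)
    raise ValueError(f"unknown model format {fmt!r}")
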