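"""Monte-Carlo stacked-ensemble classification of tissue classes.

A transparent stand-in for the AutoML protocol used on the tabular feature
sets: 100-fold Monte-Carlo train/validate splitting with a class-balanced
validate set, per-fold preprocessing strictly inside the fold (range
normalization from train statistics, redundancy reduction, univariate
rank-test feature selection, minority upsampling by convex interpolation),
a two-layer stacked ensemble of heterogeneous base learners with a logistic
meta-learner trained on out-of-fold base predictions, per-feature ranking
weights from permutation importance, and confusion-matrix analytics
including the collapse of {border, fibrosis} into one pathological class.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold, cross_val_predict
from sklearn.neighbors import KNeighborsClassifier

PATHOLOGICAL = ("border", "fibrosis")


# ---------------------------------------------------------------------------
# Monte-Carlo split plan
# ---------------------------------------------------------------------------

@dataclass
class MCSplitPlan:
    folds: list[tuple[np.ndarray, np.ndarray]]  # (train idx, validate idx)
    seed: int
    n_per_class: int


def make_mc_splits(labels, n_folds: int = 100, validate_fraction: float = 0.2,
                   seed: int = 0) -> MCSplitPlan:
    """Random train/validate folds with a class-balanced validate set.

    Each fold draws an equal number of validate cases per class totalling
    approximately ``validate_fraction`` of the data (floored to the feasible
    equal count), leaving the remainder — imbalanced — as the train split.
    """
    labels = np.asarray(labels)
    classes, counts = np.unique(labels, return_counts=True)
    k = classes.size
    n_val_per_class = max(int(np.floor(validate_fraction * labels.size / k)), 1)
    if np.any(counts <= n_val_per_class):
        lacking = classes[counts <= n_val_per_class]
        raise ValueError(
            f"classes {list(lacking)} too small for {n_val_per_class} "
            "validate cases each")
    rng = np.random.default_rng(seed)
    folds = []
    for _ in range(n_folds):
        val_idx = np.concatenate([
            rng.choice(np.nonzero(labels == c)[0], n_val_per_class, replace=False)
            for c in classes])
        train_idx = np.setdiff1d(np.arange(labels.size), val_idx)
        folds.append((train_idx, np.sort(val_idx)))
    return MCSplitPlan(folds, seed, n_val_per_class)


def balance_training_set(X: np.ndarray, y: np.ndarray, seed: int = 0
                         ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Upsample minority classes to the majority count.

    Synthetic rows are convex combinations of two distinct same-class
    originals (coordinate-wise on the feature vector); the returned flag
    array marks them.  A singleton class is duplicated with small jitter
    (with a warning) since no pair exists to interpolate.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    rng = np.random.default_rng(seed)
    classes, counts = np.unique(y, return_counts=True)
    n_max = counts.max()
    xs, ys, flags = [X], [y], [np.zeros(len(y), dtype=bool)]
    for c, n in zip(classes, counts):
        need = n_max - n
        if need == 0:
            continue
        rows = np.nonzero(y == c)[0]
        synth = np.empty((need, X.shape[1]))
        if n == 1:
            warnings.warn(f"singleton class {c!r}: duplicating with jitter")
            scale = np.abs(X[rows[0]]) * 1e-3 + 1e-6
            synth = X[rows[0]] + rng.normal(0, scale, size=(need, X.shape[1]))
        else:
            for i in range(need):
                a, b = rng.choice(rows, 2, replace=False)
                lam = rng.uniform()
                synth[i] = lam * X[a] + (1 - lam) * X[b]
        xs.append(synth)
        ys.append(np.full(need, c, dtype=y.dtype))
        flags.append(np.ones(need, dtype=bool))
    return np.vstack(xs), np.concatenate(ys), np.concatenate(flags)


# ---------------------------------------------------------------------------
# Stacked ensemble
# ---------------------------------------------------------------------------

def _default_base_learners(seed: int, n_train: int):
    """Three heterogeneous decision-boundary families.

    The neighbour count adapts downward so tiny folds stay fittable.
    """
    k = max(1, min(5, n_train // 2))
    return [
        ("linear", LogisticRegression(max_iter=2000, C=1.0, random_state=seed)),
        ("forest", RandomForestClassifier(n_estimators=100, random_state=seed)),
        ("knn", KNeighborsClassifier(n_neighbors=k)),
    ]


@dataclass
class EnsembleConfig:
    redundancy_threshold: float = 0.95
    n_selected: int = 20
    stack_cv: int = 3


class StackedEnsemble:
    """Two-layer mixed stacked classifier with leakage-free preprocessing.

    ``fit`` learns all preprocessing state (feature ranges, redundancy
    drops, univariate selection) from the training rows only; the
    meta-learner is trained on out-of-fold base-learner class probabilities.
    """

    def __init__(self, config: EnsembleConfig | None = None, seed: int = 0):
        self.config = config or EnsembleConfig()
        self.seed = seed
        self.features_: list[str] | None = None

    # -- preprocessing -----------------------------------------------------
    def _fit_preprocess(self, X: pd.DataFrame, y: np.ndarray) -> np.ndarray:
        from .harmonize import kruskal_wallis

        cols = list(X.columns)
        # range normalization from train statistics
        self.lo_ = X.min(axis=0)
        self.hi_ = X.max(axis=0)
        Z = self._normalize(X)
        # redundancy reduction: drop the later of any |r| > threshold pair
        keep = list(Z.columns)
        corr = Z.corr().abs()
        dropped = set()
        for i, a in enumerate(cols):
            if a in dropped:
                continue
            for b in cols[i + 1:]:
                if b not in dropped and corr.loc[a, b] > self.config.redundancy_threshold:
                    dropped.add(b)
        keep = [c for c in cols if c not in dropped]
        # univariate selection: top-m by Kruskal-Wallis H across classes
        scores = {}
        for c in keep:
            vals = Z[c].to_numpy()
            try:
                h, _ = kruskal_wallis(*[vals[y == cls] for cls in np.unique(y)])
            except ValueError:
                h = 0.0
            scores[c] = h
        ranked = sorted(keep, key=lambda c: (-scores[c], c))
        self.features_ = ranked[: self.config.n_selected]
        return Z[self.features_].to_numpy()

    def _normalize(self, X: pd.DataFrame) -> pd.DataFrame:
        span = (self.hi_ - self.lo_).replace(0, 1.0)
        return ((X - self.lo_) / span).clip(-1.0, 2.0).fillna(0.5)

    def _transform(self, X: pd.DataFrame) -> np.ndarray:
        return self._normalize(X)[self.features_].to_numpy()

    # -- fitting -----------------------------------------------------------
    def fit(self, X: pd.DataFrame, y) -> "StackedEnsemble":
        y = np.asarray(y)
        self.classes_ = np.unique(y)
        if self.classes_.size < 2:
            raise ValueError("need >= 2 classes to fit")
        Z = self._fit_preprocess(X, y)
        Zb, yb, _ = balance_training_set(Z, y, seed=self.seed)
        n_splits = min(self.config.stack_cv, np.bincount(
            pd.factorize(yb)[0]).min())
        n_splits = max(n_splits, 2)
        self.base_ = _default_base_learners(
            self.seed, len(Zb) * (n_splits - 1) // n_splits)
        meta_features = []
        cv = StratifiedKFold(n_splits=n_splits, shuffle=True,
                             random_state=self.seed)
        for _, learner in self.base_:
            proba = cross_val_predict(learner, Zb, yb, cv=cv,
                                      method="predict_proba")
            meta_features.append(proba)
            learner.fit(Zb, yb)
        self.meta_ = LogisticRegression(max_iter=2000, random_state=self.seed)
        self.meta_.fit(np.hstack(meta_features), yb)
        return self

    def _meta_input(self, Z: np.ndarray) -> np.ndarray:
        return np.hstack([learner.predict_proba(Z) for _, learner in self.base_])

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        return self.meta_.predict(self._meta_input(self._transform(X)))

    def predict_proba(self, X: pd.DataFrame) -> np.ndarray:
        return self.meta_.predict_proba(self._meta_input(self._transform(X)))

    # -- feature ranking ---------------------------------------------------
    def feature_weights(self, X: pd.DataFrame, y, n_repeats: int = 3,
                        all_features: list[str] | None = None) -> pd.Series:
        """Normalized permutation importance of the full stack.

        Accuracy drop when one retained feature is shuffled, averaged over
        repeats, clipped at zero and normalized to sum 1; features dropped
        during preprocessing get weight 0.
        """
        y = np.asarray(y)
        rng = np.random.default_rng(self.seed)
        base_acc = float(np.mean(self.predict(X) == y))
        drops = {}
        for feat in self.features_:
            acc = []
            for _ in range(n_repeats):
                Xp = X.copy()
                Xp[feat] = rng.permutation(Xp[feat].to_numpy())
                acc.append(float(np.mean(self.predict(Xp) == y)))
            drops[feat] = max(base_acc - float(np.mean(acc)), 0.0)
        names = all_features if all_features is not None else list(X.columns)
        w = pd.Series({f: drops.get(f, 0.0) for f in names})
        total = w.sum()
        if total > 0:
            w = w / total
        else:
            w[self.features_] = 1.0 / len(self.features_)
        return w


# ---------------------------------------------------------------------------
# Confusion analytics
# ---------------------------------------------------------------------------

@dataclass
class ConfusionReport:
    labels: list[str]
    matrix: np.ndarray  # rows = true, cols = predicted

    @property
    def accuracy(self) -> float:
        return float(np.trace(self.matrix) / self.matrix.sum())

    @property
    def sensitivity(self) -> dict[str, float]:
        out = {}
        for i, lab in enumerate(self.labels):
            row = self.matrix[i].sum()
            out[lab] = float(self.matrix[i, i] / row) if row else float("nan")
        return out

    @property
    def specificity(self) -> float | None:
        """For binary reports: true-negative rate of the second label."""
        if len(self.labels) != 2:
            return None
        tn = self.matrix[0, 0]
        fp = self.matrix[0, 1]
        return float(tn / (tn + fp)) if tn + fp else float("nan")

    def collapse(self, grouping: dict[str, str] | None = None) -> "ConfusionReport":
        """Merge labels (default: border+fibrosis -> pathological)."""
        if grouping is None:
            grouping = {c: ("pathological" if c in PATHOLOGICAL else c)
                        for c in self.labels}
        new_labels = sorted(set(grouping.values()),
                            key=lambda l: l == "pathological")
        idx = {l: i for i, l in enumerate(new_labels)}
        m = np.zeros((len(new_labels), len(new_labels)), dtype=self.matrix.dtype)
        for i, a in enumerate(self.labels):
            for j, b in enumerate(self.labels):
                m[idx[grouping[a]], idx[grouping[b]]] += self.matrix[i, j]
        return ConfusionReport(new_labels, m)


def confusion(y_true, y_pred, labels: list[str]) -> ConfusionReport:
    y_true, y_pred = np.asarray(y_true), np.asarray(y_pred)
    k = len(labels)
    lut = {l: i for i, l in enumerate(labels)}
    m = np.zeros((k, k), dtype=np.int64)
    for t, p in zip(y_true, y_pred):
        m[lut[t], lut[p]] += 1
    return ConfusionReport(list(labels), m)


# ---------------------------------------------------------------------------
# Protocol drivers
# ---------------------------------------------------------------------------

@dataclass
class MCResult:
    models: list[StackedEnsemble]
    fold_accuracies: np.ndarray
    fold_weights: pd.DataFrame  # folds x features
    plan: MCSplitPlan

    @property
    def accuracy_mean(self) -> float:
        return float(self.fold_accuracies.mean())

    @property
    def accuracy_sd(self) -> float:
        return float(self.fold_accuracies.std())

    def weight_summary(self) -> pd.DataFrame:
        """Mean ± sd ranking weight per feature across folds."""
        return pd.DataFrame({"weight_mean": self.fold_weights.mean(),
                             "weight_sd": self.fold_weights.std()})


def run_monte_carlo(
    X: pd.DataFrame,
    y,
    n_folds: int = 100,
    validate_fraction: float = 0.2,
    seed: int = 0,
    config: EnsembleConfig | None = None,
) -> MCResult:
    """Fit one stacked ensemble per Monte-Carlo fold and collect analytics."""
    y = np.asarray(y)
    plan = make_mc_splits(y, n_folds, validate_fraction, seed)
    models, accs, weights = [], [], []
    for fold_i, (tr, va) in enumerate(plan.folds):
        if np.unique(y[tr]).size < 2:
            continue  # degenerate fold
        model = StackedEnsemble(config, seed=seed + fold_i)
        model.fit(X.iloc[tr], y[tr])
        pred = model.predict(X.iloc[va])
        accs.append(float(np.mean(pred == y[va])))
        weights.append(model.feature_weights(X.iloc[va], y[va],
                                             all_features=list(X.columns)))
        models.append(model)
    return MCResult(models, np.asarray(accs),
                    pd.DataFrame(weights).reset_index(drop=True), plan)


def majority_vote(models: list[StackedEnsemble], X: pd.DataFrame) -> np.ndarray:
    """Aggregate fold models on held-out data by per-case majority vote."""
    preds = np.stack([m.predict(X) for m in models])
    out = []
    for col in preds.T:
        vals, counts = np.unique(col, return_counts=True)
        out.append(vals[np.argmax(counts)])
    return np.asarray(out)


def evaluate_on_test(models: list[StackedEnsemble], X_test: pd.DataFrame,
                     y_test, labels: list[str]) -> dict[str, ConfusionReport]:
    """Majority-vote test inference: 3-class and collapsed binary reports."""
    y_test = np.asarray(y_test)
    unknown = set(y_test) - set(labels)
    if unknown:
        raise ValueError(f"test labels {unknown} missing from label set")
    pred = majority_vote(models, X_test)
    report = confusion(y_test, pred, labels)
    return {"multiclass": report, "binary": report.collapse()}
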