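"""The eight-classifier suite: archetypes, training protocols, registry.

The suite's naming convention is "model type"-"number of features": ADTree7,
ADTree8, SVM5, LR5, LR9, SVM12, SVM10, LR10.  Four archetypes stand behind
them — boosted alternating decision trees (own implementation, see
:mod:`vidphen.adtree`), L1/L2-penalized logistic regression, linear SVM and
RBF-kernel SVM (scikit-learn).  Every trained model exposes the same surface:
an ordered feature subset, a class prediction and a probability of the
affected class via a monotone logistic link (for SVMs a Platt-style logistic
fit on training margins).

Conventions used throughout:

* class labels are 1 (affected) / 0 (unaffected); ties at probability exactly
  0.5 classify as affected (screening favors sensitivity);
* class imbalance is handled by weights inversely proportional to class size
  (optionally bootstrap up-sampling for the tree models);
* the unscorable code 8 must be imputed before a model scores a vector —
  policies: ``zero``, ``feature_mode_from_training`` (default), ``drop_rater``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import GridSearchCV, StratifiedKFold
from sklearn.svm import SVC, LinearSVC

from .adtree import ADTreeModel, TrainingError, fit_adtree
from .schema import UNSCORABLE, FeatureSchema

ARCHETYPES = ("adtree", "logreg", "svm_linear", "svm_rbf")
IMPUTE_POLICIES = ("zero", "feature_mode_from_training", "drop_rater")

REGISTRY_NAMES = ("ADTree7", "ADTree8", "SVM5", "LR5", "LR9", "SVM12", "SVM10", "LR10")


def _sigmoid(z):
    return 1.0 / (1.0 + np.exp(-np.asarray(z, dtype=float)))


@dataclass(frozen=True)
class ModelSpec:
    """Training protocol for one named classifier."""

    name: str
    archetype: str
    penalty: str = "l1"  # l1 | l2 | none (linear models)
    target_n_features: int = 5
    class_weighting: str = "inverse_class_size"  # or "none"
    upsampling_bootstraps: int = 0
    cv_folds: int = 10
    seed: int = 0

    def __post_init__(self):
        if self.archetype not in ARCHETYPES:
            raise ValueError(f"unknown archetype {self.archetype!r}")
        if self.target_n_features < 1:
            raise ValueError("target_n_features must be >= 1")
        if self.cv_folds < 2:
            raise ValueError("cv_folds must be >= 2")


def registry_specs(seed: int = 0, lr5_penalty: str = "l1") -> dict[str, ModelSpec]:
    """Default ModelSpec for each of the eight named classifiers.

    ``lr5_penalty`` surfaces the documented toggle between the sparse L1
    default and an L2 variant for the 5-feature logistic model.
    """
    mk = lambda i, **kw: ModelSpec(seed=seed + i, **kw)
    return {
        "ADTree7": mk(1, name="ADTree7", archetype="adtree", target_n_features=7,
                      upsampling_bootstraps=1000),
        "ADTree8": mk(2, name="ADTree8", archetype="adtree", target_n_features=8,
                      upsampling_bootstraps=1000),
        "SVM5": mk(3, name="SVM5", archetype="svm_linear", penalty="l1",
                   target_n_features=5),
        "LR5": mk(4, name="LR5", archetype="logreg", penalty=lr5_penalty,
                  target_n_features=5),
        "LR9": mk(5, name="LR9", archetype="logreg", penalty="l1",
                  target_n_features=9),
        "SVM12": mk(6, name="SVM12", archetype="svm_rbf", penalty="none",
                    target_n_features=12),
        "SVM10": mk(7, name="SVM10", archetype="svm_linear", penalty="l2",
                    target_n_features=10),
        "LR10": mk(8, name="LR10", archetype="logreg", penalty="l1",
                   target_n_features=10),
    }


@dataclass
class TrainedModel:
    """A fitted classifier over a declared ordered feature subset.

    ``params`` is archetype-specific (standardizer, coefficients or support
    set, or the serialized ADTree) and always carries ``feature_modes`` (the
    per-feature training-set mode) for missing-code imputation.
    """

    name: str
    archetype: str
    feature_ids: tuple[str, ...]
    params: dict

    # -- margins and probabilities -------------------------------------------------

    def _check_vector(self, x) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        if x.ndim == 1:
            x = x[None, :]
        if x.shape[1] != len(self.feature_ids):
            raise ValueError(
                f"{self.name}: expected vectors of length {len(self.feature_ids)}, "
                f"got {x.shape[1]}"
            )
        if (x == UNSCORABLE).any():
            raise ValueError(
                f"{self.name}: vector contains the unscorable code {UNSCORABLE}; "
                "run impute_missing first"
            )
        return x

    def _standardized(self, X):
        mean = np.asarray(self.params["scaler_mean"])
        scale = np.asarray(self.params["scaler_scale"])
        return (X - mean) / scale

    def margins(self, X) -> np.ndarray:
        X = self._check_vector(X)
        p = self.params
        if self.archetype == "adtree":
            return ADTreeModel.from_dict(p["adtree"]).margins(X)
        Z = self._standardized(X)
        if self.archetype in ("logreg", "svm_linear"):
            return Z @ np.asarray(p["coef"]) + p["intercept"]
        if self.archetype == "svm_rbf":
            sv = np.asarray(p["support_vectors"])
            dual = np.asarray(p["dual_coef"])
            d2 = ((Z[:, None, :] - sv[None, :, :]) ** 2).sum(axis=2)
            return np.exp(-p["gamma"] * d2) @ dual + p["intercept"]
        raise ValueError(f"unknown archetype {self.archetype!r}")

    def predict_proba(self, x) -> np.ndarray:
        """Probability of the affected class, via the model's logistic link."""
        m = self.margins(x)
        p = self.params
        if self.archetype == "logreg":
            out = _sigmoid(m)
        elif self.archetype == "adtree":
            out = _sigmoid(2.0 * m)  # boosting margin -> probability
        else:
            out = _sigmoid(p["platt_coef"] * m + p["platt_intercept"])
        return out

    def predict(self, x) -> np.ndarray:
        return (self.predict_proba(x) >= 0.5).astype(int)  # tie -> affected

    # -- serialization -------------------------------------------------------------

    def to_dict(self) -> dict:
        def conv(v):
            if isinstance(v, np.ndarray):
                return v.tolist()
            if isinstance(v, (np.floating, np.integer)):
                return v.item()
            return v

        return {
            "name": self.name,
            "archetype": self.archetype,
            "feature_ids": list(self.feature_ids),
            "params": {k: conv(v) for k, v in self.params.items()},
        }

    @classmethod
    def from_dict(cls, raw: dict) -> "TrainedModel":
        return cls(
            name=raw["name"],
            archetype=raw["archetype"],
            feature_ids=tuple(raw["feature_ids"]),
            params=dict(raw["params"]),
        )


def save_model(model: TrainedModel, path: str | Path) -> None:
    Path(path).write_text(json.dumps(model.to_dict(), indent=1))


def load_model(path: str | Path) -> TrainedModel:
    return TrainedModel.from_dict(json.loads(Path(path).read_text()))


# -- training ---------------------------------------------------------------------


def _scaler(X):
    mean = X.mean(axis=0)
    scale = X.std(axis=0)
    scale = np.where(scale == 0, 1.0, scale)
    return mean, scale


def _feature_modes(X) -> np.ndarray:
    """Per-column mode of the training scores (smallest score wins ties)."""
    modes = []
    for j in range(X.shape[1]):
        vals, counts = np.unique(X[:, j], return_counts=True)
        modes.append(vals[np.argmax(counts)])
    return np.asarray(modes, dtype=float)


def _class_weight(spec: ModelSpec):
    return "balanced" if spec.class_weighting == "inverse_class_size" else None


def _check_two_classes(y):
    if len(np.unique(y)) < 2:
        raise TrainingError("training requires both classes present")


def _fit_platt(margins, y, seed):
    lr = LogisticRegression(C=1e6, solver="lbfgs", max_iter=1000, random_state=seed)
    lr.fit(np.asarray(margins).reshape(-1, 1), y)
    return float(lr.coef_[0, 0]), float(lr.intercept_[0])


def train_logreg(X, y, spec: ModelSpec, feature_ids) -> TrainedModel:
    _check_two_classes(y)
    mean, scale = _scaler(X)
    Z = (X - mean) / scale
    # sklearn >= 1.8 parametrization: l1_ratio 1 -> pure L1, 0 -> pure L2
    base = LogisticRegression(
        l1_ratio=1.0 if spec.penalty == "l1" else 0.0,
        C=np.inf if spec.penalty == "none" else 1.0,
        solver="liblinear" if spec.penalty in ("l1", "l2") else "lbfgs",
        class_weight=_class_weight(spec),
        random_state=spec.seed,
        max_iter=2000,
    )
    n_splits = min(spec.cv_folds, int(np.bincount(y).min()))
    if n_splits >= 2:
        grid = GridSearchCV(
            base,
            {"C": [0.01, 0.1, 1.0, 10.0, 100.0]},
            cv=StratifiedKFold(n_splits, shuffle=True, random_state=spec.seed),
            scoring="roc_auc",
        )
        grid.fit(Z, y)
        est = grid.best_estimator_
    else:
        est = base.fit(Z, y)
    return TrainedModel(
        name=spec.name,
        archetype="logreg",
        feature_ids=tuple(feature_ids),
        params={
            "coef": est.coef_[0],
            "intercept": float(est.intercept_[0]),
            "scaler_mean": mean,
            "scaler_scale": scale,
            "C": float(est.C),
            "penalty": spec.penalty,
            "feature_modes": _feature_modes(X),
        },
    )


def train_linear_svm(X, y, spec: ModelSpec, feature_ids) -> TrainedModel:
    _check_two_classes(y)
    mean, scale = _scaler(X)
    Z = (X - mean) / scale
    est = LinearSVC(
        penalty=spec.penalty if spec.penalty != "none" else "l2",
        dual=False,
        class_weight=_class_weight(spec),
        random_state=spec.seed,
        max_iter=20000,
    )
    est.fit(Z, y)
    margins = Z @ est.coef_[0] + est.intercept_[0]
    a, b = _fit_platt(margins, y, spec.seed)
    return TrainedModel(
        name=spec.name,
        archetype="svm_linear",
        feature_ids=tuple(feature_ids),
        params={
            "coef": est.coef_[0],
            "intercept": float(est.intercept_[0]),
            "scaler_mean": mean,
            "scaler_scale": scale,
            "platt_coef": a,
            "platt_intercept": b,
            "penalty": spec.penalty,
            "feature_modes": _feature_modes(X),
        },
    )


def train_rbf_svm(X, y, spec: ModelSpec, feature_ids) -> TrainedModel:
    _check_two_classes(y)
    mean, scale = _scaler(X)
    Z = (X - mean) / scale
    est = SVC(kernel="rbf", gamma="scale", class_weight=_class_weight(spec),
              random_state=spec.seed)
    est.fit(Z, y)
    margins = est.decision_function(Z)
    a, b = _fit_platt(margins, y, spec.seed)
    return TrainedModel(
        name=spec.name,
        archetype="svm_rbf",
        feature_ids=tuple(feature_ids),
        params={
            "support_vectors": est.support_vectors_,
            "dual_coef": est.dual_coef_[0],
            "intercept": float(est.intercept_[0]),
            "gamma": float(est._gamma),
            "scaler_mean": mean,
            "scaler_scale": scale,
            "platt_coef": a,
            "platt_intercept": b,
            "feature_modes": _feature_modes(X),
        },
    )


def train_adtree(X, y, spec: ModelSpec, feature_ids) -> TrainedModel:
    _check_two_classes(y)
    trace: list = []
    tree = fit_adtree(
        X,
        y,
        target_n_features=spec.target_n_features,
        class_weighting=spec.class_weighting,
        upsample_to_parity=spec.upsampling_bootstraps > 0,
        seed=spec.seed,
        loss_trace=trace,
    )
    return TrainedModel(
        name=spec.name,
        archetype="adtree",
        feature_ids=tuple(feature_ids),
        params={
            "adtree": tree.to_dict(),
            "loss_trace": trace,
            "feature_modes": _feature_modes(np.asarray(X, dtype=float)),
        },
    )


_TRAINERS = {
    "logreg": train_logreg,
    "svm_linear": train_linear_svm,
    "svm_rbf": train_rbf_svm,
    "adtree": train_adtree,
}


def train_model(df: pd.DataFrame, spec: ModelSpec, feature_ids) -> TrainedModel:
    """Train one classifier on a feature matrix restricted to its subset."""
    X = df[list(feature_ids)].to_numpy(dtype=float)
    if (X == UNSCORABLE).any():
        raise ValueError("training sheets must not contain the unscorable code 8")
    y = df["label"].to_numpy(dtype=int)
    return _TRAINERS[spec.archetype](X, y, spec, feature_ids)


def train_registry(
    training_sets: dict[str, pd.DataFrame],
    schema: FeatureSchema,
    seed: int = 0,
    lr5_penalty: str = "l1",
) -> dict[str, TrainedModel]:
    """Train all eight named classifiers, each on its own training matrix.

    ``training_sets`` maps classifier name to its score-sheet cohort; a
    missing name raises KeyError.
    """
    specs = registry_specs(seed=seed, lr5_penalty=lr5_penalty)
    out = {}
    for name in REGISTRY_NAMES:
        if name not in training_sets:
            raise KeyError(f"no training set for classifier {name!r}")
        subset = schema.model_subsets[name]
        out[name] = train_model(training_sets[name], specs[name], subset)
    return out


def backward_feature_select(df: pd.DataFrame, spec: ModelSpec, feature_ids) -> dict:
    """Backward elimination: iteratively drop the single lowest-ranked feature.

    At each size the remaining features are refit across ``spec.cv_folds``
    stratified folds on standardized scores; a feature's rank is its mean
    absolute standardized coefficient across folds, and the lowest-ranked
    feature is removed (first such feature on exact ties, so a constant
    feature is removed first, deterministically).  Returns the ranking (best
    feature first), the removal order, and per-size cross-validated accuracy.
    """
    feature_ids = list(feature_ids)
    if len(feature_ids) < 2:
        raise ValueError("backward selection needs at least 2 features")
    y = df["label"].to_numpy(dtype=int)
    _check_two_classes(y)
    remaining = list(feature_ids)
    removal_order: list[str] = []
    per_size = []
    n_splits = max(2, min(spec.cv_folds, int(np.bincount(y).min())))
    while len(remaining) > 1:
        X = df[remaining].to_numpy(dtype=float)
        mean, scale = _scaler(X)
        Z = (X - mean) / scale
        cv = StratifiedKFold(n_splits, shuffle=True, random_state=spec.seed)
        coefs, accs = [], []
        for tr, te in cv.split(Z, y):
            est = LogisticRegression(
                l1_ratio=0.0,
                solver="liblinear",
                class_weight=_class_weight(spec),
                random_state=spec.seed,
                max_iter=2000,
            ).fit(Z[tr], y[tr])
            coefs.append(np.abs(est.coef_[0]))
            accs.append(float((est.predict(Z[te]) == y[te]).mean()))
        rank = np.mean(coefs, axis=0)
        per_size.append({"n_features": len(remaining), "cv_accuracy": float(np.mean(accs))})
        worst = int(np.argmin(rank))
        removal_order.append(remaining.pop(worst))
    removal_order.append(remaining.pop())
    ranking = list(reversed(removal_order))
    return {
        "ranking": ranking,
        "removal_order": removal_order,
        "per_size": pd.DataFrame(per_size),
    }


# -- missing-code imputation and frame scoring ------------------------------------


def impute_missing(vector, policy: str = "feature_mode_from_training", feature_modes=None):
    """Replace unscorable codes per policy; returns (vector, dropped_flag)."""
    if policy not in IMPUTE_POLICIES:
        raise ValueError(f"unknown imputation policy {policy!r}")
    x = np.asarray(vector, dtype=float).copy()
    miss = x == UNSCORABLE
    if not miss.any():
        return x, False
    if policy == "drop_rater":
        return x, True
    if miss.all() and policy == "feature_mode_from_training":
        return x, True  # nothing observed: record is unusable under this policy
    if policy == "zero":
        x[miss] = 0.0
        return x, False
    if feature_modes is None:
        raise ValueError("feature_mode_from_training requires training modes")
    x[miss] = np.asarray(feature_modes, dtype=float)[miss]
    return x, False


def predict_frame(
    model: TrainedModel,
    df: pd.DataFrame,
    schema: FeatureSchema,
    impute_policy: str = "feature_mode_from_training",
) -> pd.DataFrame:
    """Impute, project and score every rater row of a feature matrix.

    Returns a frame aligned with ``df`` holding ``predicted`` (0/1, -1 when
    the row was dropped by the imputation policy), ``probability`` and
    ``dropped``.
    """
    X = df[list(model.feature_ids)].to_numpy(dtype=float)
    modes = np.asarray(model.params["feature_modes"], dtype=float)
    dropped = np.zeros(len(X), dtype=bool)
    for i in range(len(X)):
        X[i], dropped[i] = impute_missing(X[i], impute_policy, modes)
    out = pd.DataFrame(index=df.index)
    proba = np.full(len(X), np.nan)
    if (~dropped).any():
        proba[~dropped] = model.predict_proba(X[~dropped])
    out["probability"] = proba
    out["predicted"] = np.where(dropped, -1, (proba >= 0.5).astype(int))
    out["dropped"] = dropped
    return out
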