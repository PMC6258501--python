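"""Elastic-net logistic video-feature classifier (trained on pooled rater rows).

The pooled rater×video score matrix (three rows per video) is split into
training and held-out test portions at the *video* level — rows of one video
never straddle the split, and each class's video count is stratified exactly.
Hyperparameters (overall penalty weight ``alpha`` and the L1/L2 mixing
``l1_ratio``) are grid-searched by cross-validated AUC (accuracy as the
tie-breaker, sparser — higher ``l1_ratio`` — as the final tie-breaker), the
model is refit with balanced class weights, and nonzero coefficients give the
feature ranking.

``alpha`` is the per-sample penalty weight (the scikit-learn mapping is
``C = 1/(alpha·n)``) on standardized scores.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import GroupKFold

from .metrics import MetricsReport, confusion_metrics, roc_auc
from .schema import FeatureSchema


class SplitError(ValueError):
    pass


class SearchError(RuntimeError):
    pass


class LeakageError(ValueError):
    """Evaluation data overlaps the training videos."""


@dataclass(frozen=True)
class ENConfig:
    alpha_grid: tuple[float, ...] = (0.001, 0.01, 0.1, 1.0)
    l1_ratio_grid: tuple[float, ...] = (0.2, 0.6, 1.0)
    cv_folds: int = 10
    test_fraction: float = 0.2
    seed: int = 0
    max_iter: int = 5000
    tol: float = 1e-4

    def __post_init__(self):
        if not self.alpha_grid or not self.l1_ratio_grid:
            raise ValueError("hyperparameter grids must be nonempty")
        if not 0.0 < self.test_fraction < 1.0:
            raise ValueError("test_fraction must lie in (0, 1)")


@dataclass
class ENModel:
    feature_ids: tuple[str, ...]
    coefficients: np.ndarray
    intercept: float
    alpha: float
    l1_ratio: float
    scaler_mean: np.ndarray
    scaler_scale: np.ndarray
    training_video_ids: frozenset[str]

    @property
    def ranking(self) -> list[str]:
        """Nonzero-coefficient features, by |coefficient| descending."""
        nz = np.flatnonzero(self.coefficients != 0.0)
        order = nz[np.argsort(-np.abs(self.coefficients[nz]), kind="stable")]
        return [self.feature_ids[i] for i in order]

    def predict_proba(self, X) -> np.ndarray:
        Z = (np.asarray(X, dtype=float) - self.scaler_mean) / self.scaler_scale
        return 1.0 / (1.0 + np.exp(-(Z @ self.coefficients + self.intercept)))


def split_train_test(matrix: pd.DataFrame, config: ENConfig):
    """Video-level stratified split; all rows of a video stay together."""
    vids = matrix.groupby("video_id")["label"].first()
    rng = np.random.default_rng(config.seed)
    test_ids: list[str] = []
    for label, group in vids.groupby(vids):
        ids = np.array(sorted(group.index))
        n_test = int(round(config.test_fraction * len(ids)))
        if n_test == 0 or n_test == len(ids):
            raise SplitError(
                f"class {label}: cannot reserve {config.test_fraction:.0%} of "
                f"{len(ids)} videos without emptying a split"
            )
        test_ids.extend(rng.choice(ids, size=n_test, replace=False))
    mask = matrix["video_id"].isin(test_ids)
    return matrix[~mask].copy(), matrix[mask].copy()


def _fit_en(Z, y, alpha, l1_ratio, seed, max_iter, tol=1e-4):
    # alpha is the per-sample penalty weight; sklearn's C is 1/(alpha * n)
    return LogisticRegression(
        solver="saga",
        l1_ratio=float(l1_ratio),
        C=1.0 / (float(alpha) * len(y)),
        class_weight="balanced",
        random_state=seed,
        max_iter=max_iter,
        tol=tol,
    ).fit(Z, y)


def _scaler(X):
    mean = X.mean(axis=0)
    scale = X.std(axis=0)
    return mean, np.where(scale == 0, 1.0, scale)


def grid_search_en(train: pd.DataFrame, config: ENConfig, schema: FeatureSchema):
    """Cross-validated AUC/accuracy per (alpha, l1_ratio); returns the winner.

    Folds are grouped by video so a video's rater rows never split across a
    fold boundary; folds whose held-out part is single-class are skipped with
    a warning.  Returns ``(alpha, l1_ratio, cv_table)``.
    """
    feats = list(schema.feature_ids)
    X = train[feats].to_numpy(dtype=float)
    y = train["label"].to_numpy(dtype=int)
    groups = train["video_id"].to_numpy()
    mean, scale = _scaler(X)
    Z = (X - mean) / scale
    n_groups = len(np.unique(groups))
    cv = GroupKFold(n_splits=min(config.cv_folds, n_groups))
    folds = list(cv.split(Z, y, groups))
    rows = []
    for alpha in config.alpha_grid:
        for l1_ratio in config.l1_ratio_grid:
            aucs, accs = [], []
            for tr, te in folds:
                if len(np.unique(y[te])) < 2 or len(np.unique(y[tr])) < 2:
                    warnings.warn(
                        "skipping a single-class cross-validation fold",
                        stacklevel=2,
                    )
                    continue
                est = _fit_en(Z[tr], y[tr], alpha, l1_ratio, config.seed,
                              config.max_iter, config.tol)
                p = est.predict_proba(Z[te])[:, 1]
                aucs.append(roc_auc_score(y[te], p))
                accs.append(float(((p >= 0.5).astype(int) == y[te]).mean()))
            if not aucs:
                continue
            rows.append(
                {"alpha": alpha, "l1_ratio": l1_ratio,
                 "cv_auc": float(np.mean(aucs)), "cv_accuracy": float(np.mean(accs))}
            )
    if not rows:
        raise SearchError("every cross-validation fold was single-class")
    table = pd.DataFrame(rows)
    best = table.sort_values(
        ["cv_auc", "cv_accuracy", "l1_ratio"], ascending=[False, False, False],
        kind="stable",
    ).iloc[0]
    return float(best["alpha"]), float(best["l1_ratio"]), table


def train_en(
    train: pd.DataFrame,
    alpha: float,
    l1_ratio: float,
    schema: FeatureSchema,
    config: ENConfig = ENConfig(),
) -> ENModel:
    """Fit the elastic-net logistic model with balanced class weights."""
    feats = list(schema.feature_ids)
    X = train[feats].to_numpy(dtype=float)
    y = train["label"].to_numpy(dtype=int)
    mean, scale = _scaler(X)
    est = _fit_en((X - mean) / scale, y, alpha, l1_ratio, config.seed,
                  config.max_iter, config.tol)
    if est.n_iter_[0] >= config.max_iter:
        raise RuntimeError(
            f"elastic-net fit did not converge in {config.max_iter} iterations "
            f"(alpha={alpha}, l1_ratio={l1_ratio})"
        )
    return ENModel(
        feature_ids=tuple(feats),
        coefficients=est.coef_[0].copy(),
        intercept=float(est.intercept_[0]),
        alpha=float(alpha),
        l1_ratio=float(l1_ratio),
        scaler_mean=mean,
        scaler_scale=scale,
        training_video_ids=frozenset(train["video_id"].astype(str)),
    )


def evaluate_en(
    model: ENModel,
    test: pd.DataFrame,
    schema: FeatureSchema,
    n_boot: int = 2000,
    seed: int = 0,
) -> tuple[MetricsReport, pd.DataFrame]:
    """Score held-out rows; refuses any overlap with the training videos."""
    overlap = frozenset(test["video_id"].astype(str)) & model.training_video_ids
    if overlap:
        raise LeakageError(
            f"evaluation set shares {len(overlap)} video(s) with training "
            f"(e.g. {sorted(overlap)[:3]})"
        )
    p = model.predict_proba(test[list(schema.feature_ids)].to_numpy(dtype=float))
    y = test["label"].to_numpy(dtype=int)
    pred = (p >= 0.5).astype(int)
    rep = confusion_metrics(pred, y)
    auc, ci = roc_auc(p, y, n_boot=n_boot, seed=seed)
    rep = MetricsReport(
        tp=rep.tp, fp=rep.fp, tn=rep.tn, fn=rep.fn,
        sensitivity=rep.sensitivity, specificity=rep.specificity,
        accuracy=rep.accuracy, precision=rep.precision, recall=rep.recall,
        uar=rep.uar, n_affected=rep.n_affected, n_unaffected=rep.n_unaffected,
        ira=rep.ira, auc=auc, auc_ci=ci,
    )
    detail = test[["video_id", "rater_id", "label"]].copy()
    detail["probability"] = p
    detail["predicted"] = pred
    return rep, detail
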