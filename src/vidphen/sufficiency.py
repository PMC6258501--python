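"""Rater-sufficiency bootstrap: how many raters are enough?

Given a cohort in which every video was tagged by a full pool of raters
(nine in the original experiment), rater identities are drawn with
replacement — 1,000 trials per rater count k, k from 1 to 9 — and each
trial's majority-consensus classes are compared with the true diagnostic
labels.  Duplicate draws contribute duplicate votes.  Even splits are broken
by one rater drawn uniformly from the pool members *outside* the sampled
subset.  The accuracy distributions per k feed a percentile-bootstrap
comparison of two chosen counts (3 vs 9 by default).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .matrixio import AFFECTED
from .models import TrainedModel, predict_frame
from .schema import FeatureSchema


class SufficiencyError(ValueError):
    pass


@dataclass(frozen=True)
class SufficiencyConfig:
    k_range: tuple[int, ...] = tuple(range(1, 10))
    n_draws: int = 1000
    seed: int = 0
    comparison_pair: tuple[int, int] = (3, 9)
    alpha: float = 0.05

    def __post_init__(self):
        if self.n_draws < 1:
            raise SufficiencyError("n_draws must be >= 1")
        if min(self.k_range) < 1:
            raise SufficiencyError("rater counts must be >= 1")


def rater_votes_table(
    matrix: pd.DataFrame,
    model: TrainedModel,
    schema: FeatureSchema,
    impute_policy: str = "feature_mode_from_training",
):
    """Per-rater class votes as a (n_videos, n_raters) array plus truths.

    Requires every video to be tagged by the same full rater pool.
    """
    pred = predict_frame(model, matrix, schema, impute_policy)
    tab = matrix[["video_id", "rater_id", "label"]].copy()
    tab["predicted"] = pred["predicted"].to_numpy()
    votes = tab.pivot(index="video_id", columns="rater_id", values="predicted")
    if votes.isna().any().any():
        raise SufficiencyError("every video must be tagged by every pool rater")
    truths = tab.groupby("video_id")["label"].first().loc[votes.index]
    return votes.to_numpy(dtype=int), truths.to_numpy(dtype=int), list(votes.index)


def bootstrap_from_votes(
    votes: np.ndarray, truths: np.ndarray, config: SufficiencyConfig
) -> dict[int, np.ndarray]:
    """Resample rater identities with replacement; accuracy per draw per k."""
    votes = np.asarray(votes, dtype=int)
    truths = np.asarray(truths, dtype=int)
    n_videos, n_raters = votes.shape
    if max(config.k_range) > n_raters:
        raise SufficiencyError(
            f"k up to {max(config.k_range)} requested but pool has {n_raters} raters"
        )
    rng = np.random.default_rng(config.seed)
    out: dict[int, np.ndarray] = {}
    all_ids = np.arange(n_raters)
    for k in config.k_range:
        acc = np.empty(config.n_draws)
        for d in range(config.n_draws):
            idx = rng.choice(n_raters, size=k, replace=True)
            sub = votes[:, idx]
            n_aff = (sub == AFFECTED).sum(axis=1)
            if k % 2 == 1:
                pred = (2 * n_aff > k).astype(int)
            else:
                pred = (2 * n_aff > k).astype(int)
                tied = 2 * n_aff == k
                if tied.any():
                    reserve = np.setdiff1d(all_ids, idx)
                    if reserve.size == 0:
                        raise SufficiencyError(
                            "even tie but the draw used every pool rater; "
                            "no reserve rater to break the tie"
                        )
                    pick = rng.choice(reserve, size=int(tied.sum()), replace=True)
                    pred[tied] = votes[np.flatnonzero(tied), pick]
            acc[d] = float((pred == truths).mean())
        out[k] = acc
    return out


def bootstrap_accuracy_by_k(
    matrix: pd.DataFrame,
    model: TrainedModel,
    config: SufficiencyConfig,
    schema: FeatureSchema,
    impute_policy: str = "feature_mode_from_training",
) -> dict[int, np.ndarray]:
    """Full-pipeline form: score the cohort once, then resample rater subsets."""
    votes, truths, _ = rater_votes_table(matrix, model, schema, impute_policy)
    return bootstrap_from_votes(votes, truths, config)


def compare_k(distributions: dict[int, np.ndarray], config: SufficiencyConfig) -> dict:
    """Percentile-bootstrap CI for the difference of mean accuracy between two k.

    The difference is mean(accuracy at the larger k) − mean(accuracy at the
    smaller k); ``significant`` is True when the (1 − alpha) CI excludes 0.
    """
    k1, k2 = config.comparison_pair
    for k in (k1, k2):
        if k not in distributions:
            raise SufficiencyError(f"no accuracy distribution for k={k}")
        if len(distributions[k]) < 2:
            raise SufficiencyError(f"need >= 2 draws at k={k} to compare")
    a, b = np.asarray(distributions[k1]), np.asarray(distributions[k2])
    diff = float(b.mean() - a.mean())
    rng = np.random.default_rng(config.seed + 1)
    n_boot = 2000
    diffs = np.empty(n_boot)
    for i in range(n_boot):
        diffs[i] = (
            b[rng.integers(len(b), size=len(b))].mean()
            - a[rng.integers(len(a), size=len(a))].mean()
        )
    lo, hi = np.percentile(diffs, [100 * config.alpha / 2, 100 * (1 - config.alpha / 2)])
    return {
        "k_pair": (k1, k2),
        "difference": diff,
        "ci_low": float(lo),
        "ci_high": float(hi),
        "alpha": config.alpha,
        "significant": not (lo <= 0.0 <= hi),
    }


def summary_table(distributions: dict[int, np.ndarray]) -> pd.DataFrame:
    rows = []
    for k, acc in sorted(distributions.items()):
        lo, hi = np.percentile(acc, [2.5, 97.5])
        rows.append(
            {"k": k, "mean_accuracy": float(np.mean(acc)), "sd": float(np.std(acc)),
             "ci_low": float(lo), "ci_high": float(hi), "n_draws": len(acc)}
        )
    return pd.DataFrame(rows)
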