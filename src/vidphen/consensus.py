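"""Majority-rules consensus over per-rater classifications.

Each rater's feature vector is scored by a classifier independently; the
video-level class is then decided by vote: with an odd number of raters a
strict majority; with exactly two raters both must agree; when an even number
of raters split evenly, one independent rater drawn uniformly from a reserve
pool (raters not already voting) breaks the tie.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .matrixio import AFFECTED, UNAFFECTED
from .models import TrainedModel, predict_frame
from .schema import FeatureSchema


class ConsensusError(ValueError):
    """Voting cannot proceed (e.g. even tie with no reserve raters)."""


@dataclass(frozen=True)
class ConsensusPolicy:
    """Vote rule parameters.

    ``rule`` is implied by ``n_raters``: unanimity-for-two when n_raters == 2,
    strict majority otherwise, with the random-reserve-rater tie-break for
    even splits.
    """

    n_raters: int = 3
    tiebreak: str = "independent_random_rater"
    seed: int = 0

    @property
    def rule(self) -> str:
        return "unanimity_for_two" if self.n_raters == 2 else "strict_majority"

    def __post_init__(self):
        if self.n_raters < 1:
            raise ValueError("n_raters must be >= 1")


@dataclass(frozen=True)
class ConsensusResult:
    """Per-video consensus outcome."""

    video_id: str
    votes: tuple[int, ...]
    probabilities: tuple[float, ...]
    majority_class: int
    unanimous: bool
    pooled_probability: float
    used_tiebreak: bool = False
    age_years: float = float("nan")
    label: int = -1


def vote(votes, policy: ConsensusPolicy, reserve=None, rng=None):
    """Apply the consensus rule to one vote list.

    Returns ``(majority_class, unanimous, used_tiebreak)``.  ``reserve`` is
    the pool of extra votes an even tie draws from (one drawn uniformly);
    ``rng`` defaults to ``numpy.random.default_rng(policy.seed)``.
    """
    votes = [int(v) for v in votes]
    if len(votes) != policy.n_raters:
        raise ConsensusError(
            f"expected {policy.n_raters} votes, got {len(votes)}"
        )
    unanimous = len(set(votes)) == 1
    n_aff = sum(v == AFFECTED for v in votes)
    n = len(votes)
    if n % 2 == 1:
        majority = AFFECTED if 2 * n_aff > n else UNAFFECTED
        return majority, unanimous, False
    if 2 * n_aff != n:  # even but not tied (covers the two-rater agreement case)
        majority = AFFECTED if 2 * n_aff > n else UNAFFECTED
        return majority, unanimous, False
    reserve = list(reserve) if reserve is not None else []
    if not reserve:
        raise ConsensusError(
            "even split with no reserve raters available for the tie-break"
        )
    if rng is None:
        rng = np.random.default_rng(policy.seed)
    pick = int(rng.integers(len(reserve)))
    return int(reserve[pick]), unanimous, True


def classify_cohort(
    matrix: pd.DataFrame,
    model: TrainedModel,
    policy: ConsensusPolicy,
    schema: FeatureSchema,
    impute_policy: str = "feature_mode_from_training",
    pooling: str = "mean",
):
    """Impute → project → predict → vote, video by video.

    Uses the first ``policy.n_raters`` usable rater rows of each video (sorted
    by rater id); remaining usable rows form the tie-break reserve.  Videos
    with fewer usable raters than the policy requires are skipped and listed
    in the returned report.  Returns ``(results, skipped)``.
    """
    if pooling not in ("mean", "median"):
        raise ValueError("pooling must be 'mean' or 'median'")
    pred = predict_frame(model, matrix, schema, impute_policy)
    rng = np.random.default_rng(policy.seed)
    results: list[ConsensusResult] = []
    skipped: list[dict] = []
    for vid, idx in matrix.groupby("video_id", sort=True).groups.items():
        rows = matrix.loc[idx].sort_values("rater_id", kind="stable")
        p = pred.loc[rows.index]
        usable = rows.index[~p["dropped"]]
        if len(usable) < policy.n_raters:
            skipped.append(
                {"video_id": vid, "n_usable_raters": int(len(usable)),
                 "required": policy.n_raters}
            )
            continue
        voters = usable[: policy.n_raters]
        reserve_votes = pred.loc[usable[policy.n_raters:], "predicted"].tolist()
        votes_list = pred.loc[voters, "predicted"].tolist()
        probs = pred.loc[voters, "probability"].tolist()
        majority, unanimous, used_tb = vote(
            votes_list, policy, reserve=reserve_votes, rng=rng
        )
        pool = float(np.mean(probs) if pooling == "mean" else np.median(probs))
        results.append(
            ConsensusResult(
                video_id=str(vid),
                votes=tuple(int(v) for v in votes_list),
                probabilities=tuple(float(q) for q in probs),
                majority_class=int(majority),
                unanimous=bool(unanimous),
                pooled_probability=pool,
                used_tiebreak=bool(used_tb),
                age_years=float(rows["age_years"].iloc[0]),
                label=int(rows["label"].iloc[0]),
            )
        )
    return results, skipped


def interrater_agreement(results) -> float:
    """Fraction of videos on which all raters' classes coincided (IRA)."""
    results = list(results)
    if not results:
        raise ValueError("interrater agreement of an empty result set is undefined")
    return float(np.mean([r.unanimous for r in results]))


def results_frame(results) -> pd.DataFrame:
    """Consensus results as the documented one-row-per-video table."""
    return pd.DataFrame(
        {
            "video_id": [r.video_id for r in results],
            "votes": ["|".join(map(str, r.votes)) for r in results],
            "probabilities": [
                "|".join(f"{q:.6f}" for q in r.probabilities) for r in results
            ],
            "majority_class": [r.majority_class for r in results],
            "unanimous": [r.unanimous for r in results],
            "used_tiebreak": [r.used_tiebreak for r in results],
            "pooled_probability": [r.pooled_probability for r in results],
            "age_years": [r.age_years for r in results],
            "label": [r.label for r in results],
        }
    )
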