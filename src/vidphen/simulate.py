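"""Synthetic cohorts: instrument-style score sheets and rater-tagged videos.

Two kinds of data are emulated so every downstream stage is testable without
the (non-deposited) study data:

* *Training sheets* — noiseless per-child ordinal score vectors mirroring the
  archived instrument score sheets the classifier suite was trained on,
  including their strong class imbalance (e.g. 1,319 affected vs 70
  unaffected children for the 5-feature models).

* *Video cohorts* — per-video latent score vectors observed independently by
  several raters through a noisy channel: a symmetric adjacent-category
  confusion kernel (a rater records a neighboring severity level with some
  probability) plus independent injection of the unscorable code 8.

Scores are generated from per-feature class-conditional categorical
distributions over {0,1,2,3}.  The affected class's distribution is an
exponential tilt of the unaffected one (``p_aff(s) ∝ p_un(s)·exp(shift·s)``),
so a single ``severity_shift ≥ 0`` knob guarantees first-order stochastic
dominance of affected over unaffected scores for every feature.  A per-feature
shift vector supports "planted signal" cohorts where only a chosen subset of
features is informative.

Ages are drawn per class from a normal distribution truncated to the study's
eligibility window of 1 to 17 years (defaults: affected 4.83 ± 2.25 years,
unaffected 2.92 ± 1.17 years).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .matrixio import AFFECTED, META_COLUMNS, UNAFFECTED
from .schema import UNSCORABLE, FeatureSchema

AGE_MIN, AGE_MAX = 1.0, 17.0


class ConfigError(ValueError):
    """Invalid cohort configuration."""


class NoiseModelError(ValueError):
    """Invalid rater noise model (e.g. confusion kernel rows not summing to 1)."""


class CalibrationError(RuntimeError):
    """Requested interrater agreement level is unattainable."""


@dataclass(frozen=True)
class CohortConfig:
    """Cohort composition: class sizes, per-class age structure, sex mix."""

    n_affected: int
    n_unaffected: int
    age_mean_affected: float = 4.83
    age_sd_affected: float = 2.25
    age_mean_unaffected: float = 2.92
    age_sd_unaffected: float = 1.17
    male_fraction_affected: float = 0.672
    male_fraction_unaffected: float = 0.565
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_affected < 0 or self.n_unaffected < 0:
            raise ConfigError("class counts must be >= 0")
        for p in (self.male_fraction_affected, self.male_fraction_unaffected):
            if not 0.0 <= p <= 1.0:
                raise ConfigError("male fractions must lie in [0, 1]")


class LatentSeverityModel:
    """Class-conditional categorical score distributions with a severity tilt.

    Parameters
    ----------
    unaffected_probs
        (n_features, 4) array; each row a distribution over scores {0,1,2,3}
        for the unaffected class.
    severity_shift
        Scalar or (n_features,) array, >= 0.  The affected class distribution
        for feature f is the exponential tilt
        ``p_aff(s) ∝ p_un(s) * exp(shift_f * s)``.
    """

    def __init__(self, unaffected_probs, severity_shift=1.0):
        probs = np.asarray(unaffected_probs, dtype=float)
        if probs.ndim != 2 or probs.shape[1] != 4:
            raise NoiseModelError("unaffected_probs must be (n_features, 4)")
        if not np.allclose(probs.sum(axis=1), 1.0):
            raise NoiseModelError("each score distribution must sum to 1")
        if (probs < 0).any():
            raise NoiseModelError("probabilities must be non-negative")
        shift = np.broadcast_to(
            np.asarray(severity_shift, dtype=float), (probs.shape[0],)
        ).copy()
        if (shift < 0).any():
            raise NoiseModelError("severity_shift must be >= 0")
        self.unaffected_probs = probs
        self.severity_shift = shift

    @property
    def n_features(self) -> int:
        return self.unaffected_probs.shape[0]

    @property
    def affected_probs(self) -> np.ndarray:
        scores = np.arange(4.0)
        tilt = self.unaffected_probs * np.exp(
            self.severity_shift[:, None] * scores[None, :]
        )
        return tilt / tilt.sum(axis=1, keepdims=True)

    def class_probs(self, label: int) -> np.ndarray:
        return self.affected_probs if label == AFFECTED else self.unaffected_probs

    @classmethod
    def default(
        cls,
        schema: FeatureSchema,
        severity_shift: float = 1.0,
        base=(0.55, 0.25, 0.12, 0.08),
    ) -> "LatentSeverityModel":
        """Every feature shares one baseline distribution and one tilt."""
        probs = np.tile(np.asarray(base, dtype=float), (len(schema.features), 1))
        return cls(probs, severity_shift)

    @classmethod
    def planted(
        cls,
        schema: FeatureSchema,
        informative_features,
        shift: float = 1.0,
        base=(0.55, 0.25, 0.12, 0.08),
    ) -> "LatentSeverityModel":
        """Only the named features carry class signal; all others are null."""
        ids = list(schema.feature_ids)
        shifts = np.zeros(len(ids))
        for fid in informative_features:
            shifts[ids.index(fid)] = shift
        probs = np.tile(np.asarray(base, dtype=float), (len(ids), 1))
        return cls(probs, shifts)


@dataclass(frozen=True)
class RaterNoiseModel:
    """Symmetric adjacent-category confusion plus independent missingness.

    With probability ``error_rate`` a rater records a severity level adjacent
    to the latent one (mass split equally between the two neighbors; at the
    boundary all of it goes to the single neighbor); independently each cell
    is replaced by the unscorable code 8 with probability ``missing_rate``.
    """

    error_rate: float = 0.0
    missing_rate: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.error_rate <= 1.0:
            raise NoiseModelError("error_rate must lie in [0, 1]")
        if not 0.0 <= self.missing_rate <= 1.0:
            raise NoiseModelError("missing_rate must lie in [0, 1]")

    @property
    def kernel(self) -> np.ndarray:
        """4x4 row-stochastic confusion kernel P(recorded s' | latent s)."""
        e = self.error_rate
        k = np.zeros((4, 4))
        for s in range(4):
            k[s, s] = 1.0 - e
            neighbors = [t for t in (s - 1, s + 1) if 0 <= t <= 3]
            for t in neighbors:
                k[s, t] += e / len(neighbors)
        return k

    @staticmethod
    def validate_kernel(kernel: np.ndarray) -> None:
        kernel = np.asarray(kernel, dtype=float)
        if kernel.shape != (4, 4) or (kernel < 0).any() or not np.allclose(
            kernel.sum(axis=1), 1.0
        ):
            raise NoiseModelError("confusion kernel rows must be distributions over 4 scores")


def _truncated_normal(rng, mean, sd, size, lo=AGE_MIN, hi=AGE_MAX):
    out = np.empty(size)
    todo = np.arange(size)
    while todo.size:
        draw = rng.normal(mean, sd, todo.size)
        ok = (draw >= lo) & (draw <= hi)
        out[todo[ok]] = draw[ok]
        todo = todo[~ok]
    return out


def _sample_scores(rng, probs, n_rows):
    """Sample (n_rows, n_features) ordinal scores from per-feature categoricals."""
    cum = probs.cumsum(axis=1)
    u = rng.random((n_rows, probs.shape[0]))
    return (u[:, :, None] > cum[None, :, :]).sum(axis=2)


def _cohort_frame(config: CohortConfig, model: LatentSeverityModel, schema, rng):
    """Latent per-subject table: label, age, male, latent scores."""
    labels = np.concatenate(
        [
            np.full(config.n_affected, AFFECTED, dtype=int),
            np.full(config.n_unaffected, UNAFFECTED, dtype=int),
        ]
    )
    ages = np.concatenate(
        [
            _truncated_normal(
                rng, config.age_mean_affected, config.age_sd_affected, config.n_affected
            ),
            _truncated_normal(
                rng,
                config.age_mean_unaffected,
                config.age_sd_unaffected,
                config.n_unaffected,
            ),
        ]
    )
    male = np.concatenate(
        [
            rng.random(config.n_affected) < config.male_fraction_affected,
            rng.random(config.n_unaffected) < config.male_fraction_unaffected,
        ]
    ).astype(int)
    scores = np.vstack(
        [
            _sample_scores(rng, model.affected_probs, config.n_affected),
            _sample_scores(rng, model.unaffected_probs, config.n_unaffected),
        ]
    ) if len(labels) else np.zeros((0, model.n_features), dtype=int)
    return labels, ages, male, scores


def generate_training_sheets(
    config: CohortConfig, model: LatentSeverityModel, schema: FeatureSchema
) -> pd.DataFrame:
    """Noiseless one-row-per-child score sheets (instrument-style cohort)."""
    if config.n_affected <= 0 or config.n_unaffected <= 0:
        raise ConfigError("training sheets require both classes to be non-empty")
    rng = np.random.default_rng(config.seed)
    labels, ages, male, scores = _cohort_frame(config, model, schema, rng)
    n = len(labels)
    df = pd.DataFrame(
        {
            "video_id": [f"sheet{i:05d}" for i in range(n)],
            "rater_id": "sheet",
            "age_years": ages,
            "label": labels,
            "male": male,
        }
    )
    for j, fid in enumerate(schema.feature_ids):
        df[fid] = scores[:, j]
    return df


def generate_video_cohort(
    config: CohortConfig,
    model: LatentSeverityModel,
    noise: RaterNoiseModel,
    n_raters: int,
    schema: FeatureSchema,
) -> pd.DataFrame:
    """Rater-tagged video cohort: n_raters noisy observations per video.

    All raters of a video share the video's latent score vector; each rater's
    recorded scores are an independent pass of the latent scores through the
    confusion kernel, then independent replacement by 8 at ``missing_rate``.
    """
    if n_raters < 1:
        raise ConfigError("n_raters must be >= 1")
    RaterNoiseModel.validate_kernel(noise.kernel)
    rng = np.random.default_rng(config.seed)
    labels, ages, male, latent = _cohort_frame(config, model, schema, rng)
    n_videos = len(labels)
    kernel_cum = noise.kernel.cumsum(axis=1)
    rows = []
    for r in range(n_raters):
        u = rng.random(latent.shape)
        observed = (u[:, :, None] > kernel_cum[latent]).sum(axis=2)
        miss = rng.random(latent.shape) < noise.missing_rate
        observed = np.where(miss, UNSCORABLE, observed)
        rows.append(observed)
    df = pd.DataFrame(
        {
            "video_id": np.tile([f"vid{i:05d}" for i in range(n_videos)], n_raters),
            "rater_id": np.repeat([f"rater{r + 1}" for r in range(n_raters)], n_videos),
            "age_years": np.tile(ages, n_raters),
            "label": np.tile(labels, n_raters),
            "male": np.tile(male, n_raters),
        }
    )
    allscores = np.vstack(rows) if rows else np.zeros((0, model.n_features), int)
    for j, fid in enumerate(schema.feature_ids):
        df[fid] = allscores[:, j]
    return df.sort_values(["video_id", "rater_id"], kind="stable").reset_index(drop=True)


def _simulated_unanimity(
    error_rate, missing_rate, model, classifier, schema, config, n_raters, seed,
    n_rep: int = 5,
):
    """Monte-Carlo all-raters-agree frequency, averaged over replicate cohorts."""
    from .models import predict_frame

    noise = RaterNoiseModel(error_rate=error_rate, missing_rate=missing_rate)
    vals = []
    for rep in range(n_rep):
        cohort = generate_video_cohort(
            replace(config, seed=seed + 7919 * rep), model, noise, n_raters, schema
        )
        pred = predict_frame(classifier, cohort, schema)
        agree = pred.groupby(cohort["video_id"])["predicted"].agg(
            lambda s: s.nunique() == 1
        )
        vals.append(float(agree.mean()))
    return float(np.mean(vals))


def calibrate_noise(
    target_agreement: float,
    model: LatentSeverityModel,
    classifier,
    schema: FeatureSchema,
    config: CohortConfig | None = None,
    n_raters: int = 3,
    missing_rate: float = 0.0,
    seed: int = 0,
    tol: float = 0.02,
    max_iter: int = 24,
    max_error_rate: float = 0.9,
) -> RaterNoiseModel:
    """Find an error rate whose simulated all-raters-agree frequency matches.

    Bisects the adjacent-category error rate until the Monte-Carlo unanimity
    frequency (all ``n_raters`` raters' model classes coincide) is within
    ``tol`` of ``target_agreement``; raises CalibrationError, reporting the
    achievable range, when the target lies outside it.
    """
    if not 0.0 < target_agreement <= 1.0:
        raise CalibrationError(
            f"target agreement must lie in (0, 1], got {target_agreement}"
        )
    if config is None:
        config = CohortConfig(n_affected=116, n_unaffected=46, seed=seed)

    def unanimity(e):
        return _simulated_unanimity(
            e, missing_rate, model, classifier, schema, config, n_raters, seed
        )

    lo, hi = 0.0, max_error_rate
    u_lo, u_hi = unanimity(lo), unanimity(hi)
    top, floor = max(u_lo, u_hi), min(u_lo, u_hi)
    if target_agreement > top + tol or target_agreement < floor - tol:
        raise CalibrationError(
            f"target agreement {target_agreement:.3f} outside achievable range "
            f"[{floor:.3f}, {top:.3f}] for error rates in [0, {max_error_rate}]"
        )
    if abs(u_lo - target_agreement) <= tol and target_agreement >= u_lo:
        return RaterNoiseModel(error_rate=lo, missing_rate=missing_rate)
    # unanimity decreases (stochastically) in the error rate; bisect
    for _ in range(max_iter):
        mid = 0.5 * (lo + hi)
        u_mid = unanimity(mid)
        if abs(u_mid - target_agreement) <= tol:
            return RaterNoiseModel(error_rate=mid, missing_rate=missing_rate)
        if u_mid > target_agreement:
            lo = mid
        else:
            hi = mid
    achieved = unanimity(0.5 * (lo + hi))
    if abs(achieved - target_agreement) <= max(tol, 0.05):
        return RaterNoiseModel(error_rate=0.5 * (lo + hi), missing_rate=missing_rate)
    raise CalibrationError(
        f"bisection did not reach target {target_agreement:.3f} "
        f"(achieved {achieved:.3f})"
    )
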