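"""Evaluation statistics: confusion metrics, UAR, ROC/AUC, age strata, triage.

UAR (unweighted average recall) is the mean of sensitivity and specificity —
the headline statistic for imbalanced screening cohorts.  Rates whose
denominator is empty (e.g. specificity in a stratum with no unaffected
children) are reported as NaN, never silently 0.  The triage band flags
videos whose pooled class probability falls inside [0.4, 0.6] (inclusive by
default) as inconclusive, to be referred for clinical follow-up instead of
receiving a binary call.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score

from .matrixio import AFFECTED, UNAFFECTED


@dataclass(frozen=True)
class MetricsReport:
    tp: int
    fp: int
    tn: int
    fn: int
    sensitivity: float
    specificity: float
    accuracy: float
    precision: float
    recall: float
    uar: float
    n_affected: int
    n_unaffected: int
    ira: float = float("nan")
    auc: float = float("nan")
    auc_ci: tuple[float, float] = (float("nan"), float("nan"))

    def to_dict(self) -> dict:
        return {
            "tp": self.tp, "fp": self.fp, "tn": self.tn, "fn": self.fn,
            "sensitivity": self.sensitivity, "specificity": self.specificity,
            "accuracy": self.accuracy, "precision": self.precision,
            "recall": self.recall, "uar": self.uar, "ira": self.ira,
            "auc": self.auc, "auc_ci_low": self.auc_ci[0],
            "auc_ci_high": self.auc_ci[1],
            "n_affected": self.n_affected, "n_unaffected": self.n_unaffected,
        }


def uar(sensitivity: float, specificity: float) -> float:
    """Unweighted average recall: the mean of sensitivity and specificity."""
    return (sensitivity + specificity) / 2.0


def _rate(num: int, den: int) -> float:
    return num / den if den > 0 else float("nan")


def confusion_metrics(predictions, truths, ira=float("nan")) -> MetricsReport:
    """Standard confusion-matrix statistics with NaN for undefined rates."""
    predictions = np.asarray(predictions, dtype=int)
    truths = np.asarray(truths, dtype=int)
    if predictions.shape != truths.shape:
        raise ValueError(
            f"predictions ({predictions.shape}) and truths ({truths.shape}) "
            "must have equal length"
        )
    tp = int(((predictions == AFFECTED) & (truths == AFFECTED)).sum())
    fn = int(((predictions == UNAFFECTED) & (truths == AFFECTED)).sum())
    tn = int(((predictions == UNAFFECTED) & (truths == UNAFFECTED)).sum())
    fp = int(((predictions == AFFECTED) & (truths == UNAFFECTED)).sum())
    sens = _rate(tp, tp + fn)
    spec = _rate(tn, tn + fp)
    return MetricsReport(
        tp=tp, fp=fp, tn=tn, fn=fn,
        sensitivity=sens,
        specificity=spec,
        accuracy=_rate(tp + tn, len(truths)),
        precision=_rate(tp, tp + fp),
        recall=sens,
        uar=uar(sens, spec),
        n_affected=tp + fn,
        n_unaffected=tn + fp,
        ira=ira,
    )


def roc_auc(probabilities, truths, n_boot: int = 2000, seed: int = 0):
    """AUC (rank construction) with a stratified percentile-bootstrap 95% CI."""
    probabilities = np.asarray(probabilities, dtype=float)
    truths = np.asarray(truths, dtype=int)
    if len(set(truths.tolist())) < 2:
        raise ValueError("AUC requires both classes present")
    auc = float(roc_auc_score(truths, probabilities))
    rng = np.random.default_rng(seed)
    pos = np.flatnonzero(truths == AFFECTED)
    neg = np.flatnonzero(truths == UNAFFECTED)
    boots = np.empty(n_boot)
    for i in range(n_boot):
        idx = np.concatenate(
            [rng.choice(pos, size=len(pos)), rng.choice(neg, size=len(neg))]
        )
        boots[i] = roc_auc_score(truths[idx], probabilities[idx])
    lo, hi = np.percentile(boots, [2.5, 97.5])
    return auc, (float(lo), float(hi))


@dataclass(frozen=True)
class AgeStratification:
    """Left-open, right-closed age bins: ≤e1, (e1,e2], (e2,e3], >e3 years."""

    edges: tuple[float, ...] = (2.0, 4.0, 6.0)

    @property
    def labels(self) -> tuple[str, ...]:
        e = self.edges
        inner = tuple(f">{a:g}-<={b:g}y" for a, b in zip(e[:-1], e[1:]))
        return (f"<={e[0]:g}y",) + inner + (f">{e[-1]:g}y",)

    def assign(self, age: float) -> str:
        if not age > 0:
            raise ValueError(f"age must be positive, got {age}")
        for edge, lab in zip(self.edges, self.labels):
            if age <= edge:
                return lab
        return self.labels[-1]


@dataclass(frozen=True)
class TriageConfig:
    """Inconclusive-probability band; videos inside it get no binary call."""

    band_low: float = 0.4
    band_high: float = 0.6
    boundary_inclusive: bool = True

    def __post_init__(self):
        if not 0.0 <= self.band_low < self.band_high <= 1.0:
            raise ValueError(
                f"require 0 <= band_low < band_high <= 1, "
                f"got [{self.band_low}, {self.band_high}]"
            )


def flag_inconclusive(probabilities, config: TriageConfig = TriageConfig()):
    """Boolean mask: True where the probability falls in the inconclusive band."""
    p = np.asarray(probabilities, dtype=float)
    if ((p < 0) | (p > 1)).any():
        raise ValueError("probabilities must lie in [0, 1]")
    if config.boundary_inclusive:
        return (p >= config.band_low) & (p <= config.band_high)
    return (p > config.band_low) & (p < config.band_high)


def stratify_by_age(
    results: pd.DataFrame,
    strata: AgeStratification = AgeStratification(),
    pred_col: str = "majority_class",
    truth_col: str = "label",
    age_col: str = "age_years",
    unanimous_col: str = "unanimous",
) -> dict[str, MetricsReport]:
    """Per-age-bin metric reports plus an ``overall`` entry.

    Every video lands in exactly one bin; nonpositive ages raise, naming the
    video.  Strata with a missing class yield NaN for the undefined rate and
    a warning.
    """
    bad = results.index[~(results[age_col] > 0)]
    if len(bad):
        vid = results.loc[bad[0]].get("video_id", bad[0])
        raise ValueError(f"nonpositive age for video {vid!r}")
    bins = results[age_col].map(strata.assign)
    out: dict[str, MetricsReport] = {}
    for name, sub in [("overall", results)] + [
        (lab, results[bins == lab]) for lab in strata.labels
    ]:
        if not len(sub):
            out[name] = None
            continue
        ira = (
            float(sub[unanimous_col].mean()) if unanimous_col in sub else float("nan")
        )
        rep = confusion_metrics(sub[pred_col], sub[truth_col], ira=ira)
        if rep.n_affected == 0 or rep.n_unaffected == 0:
            warnings.warn(
                f"stratum {name!r} has a single class; the undefined rate is NaN",
                stacklevel=2,
            )
        out[name] = rep
    return out


def metrics_table(reports: dict[str, MetricsReport]) -> pd.DataFrame:
    rows = []
    for name, rep in reports.items():
        if rep is None:
            continue
        row = {"stratum": name}
        row.update(rep.to_dict())
        rows.append(row)
    return pd.DataFrame(rows)
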