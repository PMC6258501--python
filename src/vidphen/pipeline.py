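"""End-to-end reproducible runs binding all stages together.

A run is driven by a single YAML config and a master seed.  Per-stage child
seeds are derived deterministically from the master seed, every report header
(manifest) records the config hash, seed and row counts, and rerunning with
the same config and seed reproduces every table byte for byte.

Stage outputs (all plain CSV/JSON under the output directory)::

    sheets_<model>.csv      per-classifier training score sheets
    cohort_videos.csv       3-rater analysis cohort
    cohort_sufficiency.csv  9-rater cohort for the rater-sufficiency bootstrap
    cohort_validation.csv   independent validation cohort
    model_<name>.json       trained classifiers
    consensus_<name>.csv    per-video consensus table
    metrics_<name>.csv      per-age-stratum metric tables
    sufficiency_summary.csv / sufficiency_comparison.json
    triage_metrics.csv      metrics before/after excluding the inconclusive band
    en_model.json / en_metrics.csv / en_cv_table.csv
    manifest.json           seeds, config hash, row counts
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import consensus as cns
from . import elasticnet as en
from . import metrics as mx
from . import models as mdl
from . import simulate as sim
from .matrixio import read_feature_matrix, write_feature_matrix
from .schema import FeatureSchema, load_schema

#: per-classifier training cohort sizes (affected, unaffected) mirroring the
#: instrument score-sheet archives each model was originally fit on
TRAINING_COHORT_SIZES = {
    "ADTree7": (891, 75),
    "ADTree8": (612, 15),
    "SVM5": (1319, 70),
    "LR5": (1319, 70),
    "LR9": (362, 282),
    "SVM12": (510, 93),
    "SVM10": (2870, 273),
    "LR10": (2870, 273),
}


class StageError(RuntimeError):
    pass


@dataclass
class RunConfig:
    """Master configuration for a full pipeline run."""

    schema_path: str | None = None
    seed: int = 0
    outdir: str = "results/run"
    severity_shift: float = 1.0
    target_unanimity: float = 0.72
    missing_rate: float = 0.02
    n_raters: int = 3
    cohort: dict = field(default_factory=lambda: {"n_affected": 116, "n_unaffected": 46})
    sufficiency_cohort: dict = field(
        default_factory=lambda: {"n_affected": 25, "n_unaffected": 25, "n_raters": 9}
    )
    validation_cohort: dict = field(
        default_factory=lambda: {"n_affected": 33, "n_unaffected": 33}
    )
    sufficiency: dict = field(default_factory=dict)  # SufficiencyConfig overrides
    triage: dict = field(default_factory=dict)  # TriageConfig overrides
    en: dict = field(default_factory=dict)  # ENConfig overrides
    en_extra_videos: dict = field(
        default_factory=lambda: {"n_affected": 5, "n_unaffected": 9}
    )
    models: list[str] | None = None
    lr5_penalty: str = "l1"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**raw)

    def config_hash(self) -> str:
        return hashlib.sha256(
            yaml.safe_dump(asdict(self), sort_keys=True).encode()
        ).hexdigest()[:16]

    def child_seed(self, idx: int) -> int:
        return (self.seed * 10007 + 31 * idx + 1) % (2**31)


def _load_schema(config: RunConfig) -> FeatureSchema:
    if config.schema_path is not None and not Path(config.schema_path).exists():
        raise FileNotFoundError(f"schema file not found: {config.schema_path}")
    return load_schema(config.schema_path)


def _manifest_update(outdir: Path, config: RunConfig, entries: dict) -> None:
    path = outdir / "manifest.json"
    manifest = json.loads(path.read_text()) if path.exists() else {}
    manifest.setdefault("config_hash", config.config_hash())
    manifest.setdefault("seed", config.seed)
    manifest.setdefault("outdir", str(outdir))
    manifest.update(entries)
    path.write_text(json.dumps(manifest, indent=1, sort_keys=True))


def cmd_simulate(config: RunConfig) -> dict[str, Path]:
    """Write training sheets and rater cohorts; returns the file map."""
    schema = _load_schema(config)
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    severity = sim.LatentSeverityModel.default(schema, config.severity_shift)
    files: dict[str, Path] = {}
    counts = {}
    for i, name in enumerate(mdl.REGISTRY_NAMES):
        n_aff, n_un = TRAINING_COHORT_SIZES[name]
        cc = sim.CohortConfig(
            n_affected=n_aff, n_unaffected=n_un, seed=config.child_seed(i)
        )
        sheets = sim.generate_training_sheets(cc, severity, schema)
        path = outdir / f"sheets_{name}.csv"
        write_feature_matrix(sheets, path, schema)
        files[f"sheets_{name}"] = path
        counts[f"sheets_{name}_rows"] = len(sheets)
    noise = sim.RaterNoiseModel(error_rate=0.0, missing_rate=config.missing_rate)
    for key, spec, seed_idx in [
        ("cohort_videos", {**config.cohort, "n_raters": config.n_raters}, 100),
        ("cohort_sufficiency", config.sufficiency_cohort, 101),
        ("cohort_validation", {**config.validation_cohort, "n_raters": config.n_raters}, 102),
    ]:
        spec = dict(spec)
        n_raters = spec.pop("n_raters", config.n_raters)
        cc = sim.CohortConfig(seed=config.child_seed(seed_idx), **spec)
        cohort = sim.generate_video_cohort(cc, severity, noise, n_raters, schema)
        path = outdir / f"{key}.csv"
        write_feature_matrix(cohort, path, schema)
        files[key] = path
        counts[f"{key}_rows"] = len(cohort)
    _manifest_update(outdir, config, {"simulate": counts})
    return files


def cmd_train(config: RunConfig) -> dict[str, mdl.TrainedModel]:
    """Train the eight-classifier registry from the simulated sheets."""
    schema = _load_schema(config)
    outdir = Path(config.outdir)
    training_sets = {
        name: read_feature_matrix(outdir / f"sheets_{name}.csv", schema)
        for name in mdl.REGISTRY_NAMES
    }
    registry = mdl.train_registry(
        training_sets, schema, seed=config.seed, lr5_penalty=config.lr5_penalty
    )
    for name, model in registry.items():
        mdl.save_model(model, outdir / f"model_{name}.json")
    _manifest_update(
        outdir, config, {"train": {"models": list(registry)}}
    )
    return registry


def _recalibrated_cohorts(config: RunConfig, schema, registry):
    """Regenerate the rater cohorts with noise calibrated to the unanimity target."""
    severity = sim.LatentSeverityModel.default(schema, config.severity_shift)
    noise = sim.calibrate_noise(
        config.target_unanimity,
        severity,
        registry["LR5"],
        schema,
        n_raters=config.n_raters,
        missing_rate=config.missing_rate,
        seed=config.child_seed(200),
    )
    outdir = Path(config.outdir)
    cohorts = {}
    for key, spec, seed_idx in [
        ("cohort_videos", {**config.cohort, "n_raters": config.n_raters}, 100),
        ("cohort_sufficiency", config.sufficiency_cohort, 101),
        ("cohort_validation", {**config.validation_cohort, "n_raters": config.n_raters}, 102),
    ]:
        spec = dict(spec)
        n_raters = spec.pop("n_raters", config.n_raters)
        cc = sim.CohortConfig(seed=config.child_seed(seed_idx), **spec)
        cohort = sim.generate_video_cohort(cc, severity, noise, n_raters, schema)
        write_feature_matrix(cohort, outdir / f"{key}.csv", schema)
        cohorts[key] = cohort
    _manifest_update(
        outdir,
        config,
        {"noise": {"error_rate": noise.error_rate, "missing_rate": noise.missing_rate}},
    )
    return cohorts, noise


def cmd_consensus(config: RunConfig, registry, cohort: pd.DataFrame) -> dict:
    """Consensus classification + per-age-stratum metrics for each model."""
    schema = _load_schema(config)
    outdir = Path(config.outdir)
    names = config.models or list(mdl.REGISTRY_NAMES)
    out = {}
    policy = cns.ConsensusPolicy(n_raters=config.n_raters, seed=config.child_seed(300))
    for name in names:
        results, skipped = cns.classify_cohort(cohort, registry[name], policy, schema)
        frame = cns.results_frame(results)
        frame.to_csv(outdir / f"consensus_{name}.csv", index=False)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            reports = mx.stratify_by_age(frame)
        table = mx.metrics_table(reports)
        table.to_csv(outdir / f"metrics_{name}.csv", index=False)
        if skipped:
            pd.DataFrame(skipped).to_csv(outdir / f"skipped_{name}.csv", index=False)
        out[name] = {"results": results, "metrics": reports, "skipped": skipped}
    return out


def cmd_sufficiency(config: RunConfig, registry, cohort: pd.DataFrame) -> dict:
    """Rater-sufficiency bootstrap on the 9-rater cohort (ADTree8 model)."""
    from . import sufficiency as suf

    schema = _load_schema(config)
    outdir = Path(config.outdir)
    scfg = suf.SufficiencyConfig(seed=config.child_seed(400), **config.sufficiency)
    dists = suf.bootstrap_accuracy_by_k(cohort, registry["ADTree8"], scfg, schema)
    table = suf.summary_table(dists)
    table.to_csv(outdir / "sufficiency_summary.csv", index=False)
    comparison = suf.compare_k(dists, scfg)
    (outdir / "sufficiency_comparison.json").write_text(
        json.dumps(comparison, indent=1)
    )
    return {"distributions": dists, "summary": table, "comparison": comparison}


def cmd_triage(config: RunConfig, registry, cohort: pd.DataFrame) -> dict:
    """Inconclusive-band triage of the validation cohort under LR5."""
    schema = _load_schema(config)
    outdir = Path(config.outdir)
    policy = cns.ConsensusPolicy(n_raters=config.n_raters, seed=config.child_seed(500))
    results, _ = cns.classify_cohort(cohort, registry["LR5"], policy, schema)
    frame = cns.results_frame(results)
    tcfg = mx.TriageConfig(**config.triage)
    inconclusive = mx.flag_inconclusive(frame["pooled_probability"], tcfg)
    frame["inconclusive"] = inconclusive
    frame.to_csv(outdir / "triage_consensus.csv", index=False)
    rep_all = mx.confusion_metrics(frame["majority_class"], frame["label"])
    keep = frame[~inconclusive]
    rep_conclusive = (
        mx.confusion_metrics(keep["majority_class"], keep["label"])
        if len(keep)
        else None
    )
    table = mx.metrics_table(
        {"all": rep_all, **({"conclusive_only": rep_conclusive} if rep_conclusive else {})}
    )
    table.insert(1, "n_inconclusive", int(inconclusive.sum()))
    table.to_csv(outdir / "triage_metrics.csv", index=False)
    return {
        "frame": frame,
        "n_inconclusive": int(inconclusive.sum()),
        "all": rep_all,
        "conclusive_only": rep_conclusive,
    }


def cmd_en(config: RunConfig, cohort: pd.DataFrame, extra: pd.DataFrame | None) -> dict:
    """Train and evaluate the elastic-net video-feature classifier."""
    schema = _load_schema(config)
    outdir = Path(config.outdir)
    pooled = pd.concat([cohort] + ([extra] if extra is not None else []), ignore_index=True)
    ecfg = en.ENConfig(seed=config.child_seed(600), **config.en)
    train, test = en.split_train_test(pooled, ecfg)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        alpha, l1_ratio, cv_table = en.grid_search_en(train, ecfg, schema)
    cv_table.to_csv(outdir / "en_cv_table.csv", index=False)
    model = en.train_en(train, alpha, l1_ratio, schema, ecfg)
    (outdir / "en_model.json").write_text(
        json.dumps(
            {
                "alpha": model.alpha,
                "l1_ratio": model.l1_ratio,
                "intercept": model.intercept,
                "coefficients": dict(
                    zip(model.feature_ids, model.coefficients.tolist())
                ),
                "ranking": model.ranking,
            },
            indent=1,
        )
    )
    rep, detail = en.evaluate_en(model, test, schema, seed=config.child_seed(601))
    mx.metrics_table({"held_out": rep}).to_csv(outdir / "en_metrics.csv", index=False)
    detail.to_csv(outdir / "en_test_predictions.csv", index=False)
    return {"model": model, "report": rep, "cv_table": cv_table}


def cmd_run_all(config: RunConfig) -> dict:
    """Simulate → train → consensus → sufficiency → triage → elastic net.

    On a stage failure a ``FAILED_<stage>`` marker is written next to the
    partial outputs and the error re-raised.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    bundle: dict = {}
    stage = "simulate"
    try:
        cmd_simulate(config)
        stage = "train"
        registry = bundle["registry"] = cmd_train(config)
        stage = "calibrate"
        schema = _load_schema(config)
        cohorts, noise = _recalibrated_cohorts(config, schema, registry)
        bundle["noise"] = noise
        stage = "consensus"
        bundle["consensus"] = cmd_consensus(config, registry, cohorts["cohort_videos"])
        stage = "sufficiency"
        bundle["sufficiency"] = cmd_sufficiency(
            config, registry, cohorts["cohort_sufficiency"]
        )
        stage = "triage"
        bundle["triage"] = cmd_triage(config, registry, cohorts["cohort_validation"])
        stage = "en"
        severity = sim.LatentSeverityModel.default(schema, config.severity_shift)
        extra_cc = sim.CohortConfig(
            seed=config.child_seed(103), **config.en_extra_videos
        )
        extra = sim.generate_video_cohort(
            extra_cc, severity, noise, config.n_raters, schema
        )
        extra["video_id"] = "extra_" + extra["video_id"]
        bundle["en"] = cmd_en(config, cohorts["cohort_videos"], extra)
    except Exception as exc:
        (outdir / f"FAILED_{stage}").write_text(f"{type(exc).__name__}: {exc}\n")
        raise StageError(f"stage {stage!r} failed: {exc}") from exc
    _manifest_update(outdir, config, {"completed": True})
    return bundle
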