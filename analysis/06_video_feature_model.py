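"""Elastic-net logistic classifier trained directly on the video feature matrix.

Pools the 3-rater rows of the analysis cohort with a small batch of extra
videos (176 videos, 528 rows), reserves 20% of videos as a held-out test set
(video-level split: a video's rows never straddle the split), grid-searches
alpha and the L1 ratio by cross-validated AUC, fits with balanced class
weights, and reports the held-out metrics and the coefficient-ranked
features.  Run 01-03 first.
"""

from vidphen import load_schema
from vidphen.matrixio import read_feature_matrix
from vidphen.pipeline import RunConfig, cmd_en
from vidphen.simulate import (CohortConfig, LatentSeverityModel,
                              RaterNoiseModel, generate_video_cohort)

import json

cfg = RunConfig(seed=1, outdir="results/run")
schema = load_schema()
cohort = read_feature_matrix("results/run/cohort_videos.csv", schema)

noise_info = json.load(open("results/run/manifest.json"))["noise"]
severity = LatentSeverityModel.default(schema, cfg.severity_shift)
noise = RaterNoiseModel(**noise_info)
extra = generate_video_cohort(
    CohortConfig(seed=cfg.child_seed(103), **cfg.en_extra_videos),
    severity, noise, cfg.n_raters, schema,
)
extra["video_id"] = "extra_" + extra["video_id"]

out = cmd_en(cfg, cohort, extra)
model, rep = out["model"], out["report"]
print(f"selected hyperparameters: alpha={model.alpha}, l1_ratio={model.l1_ratio}")
print(
    f"held-out test ({rep.n_affected + rep.n_unaffected} rater-rows): "
    f"AUC={rep.auc:.3f} (95% CI {rep.auc_ci[0]:.3f}-{rep.auc_ci[1]:.3f}), "
    f"accuracy={rep.accuracy:.3f}"
)
print(f"nonzero features: {len(model.ranking)} of 30; top 8 by |coefficient|:")
for fid in model.ranking[:8]:
    print(f"  {fid}")
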