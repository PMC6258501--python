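"""Majority-rules consensus of 3 raters, per model, with age-stratified metrics.

Recalibrates the rater-noise level so that the 3 raters agree unanimously on
~72% of videos under the 5-feature logistic model, regenerates the video
cohorts at that level, then classifies the 162-video analysis cohort with
every model and reports sensitivity/specificity/UAR/IRA overall and by age
bin.  Run 01 and 02 first.
"""

import pandas as pd

from vidphen import load_schema
from vidphen.models import REGISTRY_NAMES, load_model
from vidphen.pipeline import RunConfig, _recalibrated_cohorts, cmd_consensus

cfg = RunConfig(seed=1, outdir="results/run")
schema = load_schema()
registry = {n: load_model(f"results/run/model_{n}.json") for n in REGISTRY_NAMES}

cohorts, noise = _recalibrated_cohorts(cfg, schema, registry)
print(f"calibrated rater noise: error_rate={noise.error_rate:.3f}, "
      f"missing_rate={noise.missing_rate}")

out = cmd_consensus(cfg, registry, cohorts["cohort_videos"])
print("\noverall metrics on the 162-video cohort (3-rater majority):")
print(f"{'model':8s} {'sens':>6s} {'spec':>6s} {'acc':>6s} {'UAR':>6s} {'IRA':>6s}")
for name in REGISTRY_NAMES:
    rep = out[name]["metrics"]["overall"]
    print(
        f"{name:8s} {rep.sensitivity:6.3f} {rep.specificity:6.3f} "
        f"{rep.accuracy:6.3f} {rep.uar:6.3f} {rep.ira:6.3f}"
    )
print("\nper-age-bin tables written to results/run/metrics_<model>.csv")
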