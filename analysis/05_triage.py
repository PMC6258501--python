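"""Inconclusive-band triage of the validation cohort.

Videos whose pooled 5-feature-logistic probability falls in [0.4, 0.6] are
flagged inconclusive (referred for clinical follow-up) rather than given a
binary call; metrics are reported before and after excluding them.
Run 01-03 first.
"""

from vidphen import load_schema
from vidphen.matrixio import read_feature_matrix
from vidphen.models import load_model
from vidphen.pipeline import RunConfig, cmd_triage

cfg = RunConfig(seed=1, outdir="results/run")
schema = load_schema()
registry = {"LR5": load_model("results/run/model_LR5.json")}
cohort = read_feature_matrix("results/run/cohort_validation.csv", schema)

out = cmd_triage(cfg, registry, cohort)
n = len(out["frame"])
print(f"validation cohort: {n} videos; "
      f"{out['n_inconclusive']} fell in the inconclusive band [0.4, 0.6]")
for key in ("all", "conclusive_only"):
    rep = out[key]
    if rep is None:
        continue
    print(
        f"  {key:16s} sens={rep.sensitivity:.3f} spec={rep.specificity:.3f} "
        f"acc={rep.accuracy:.3f} UAR={rep.uar:.3f}"
    )
print("full table in results/run/triage_metrics.csv")
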