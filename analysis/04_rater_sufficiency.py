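"""How many raters are enough?  Sample-with-replacement rater bootstrap.

On the 50-video cohort tagged by all 9 raters, rater identities are drawn
with replacement (1,000 trials per count k = 1..9) and the 8-feature
alternating decision tree's majority-consensus accuracy is measured per
trial.  The difference between 3 and 9 raters is then tested with a
percentile-bootstrap confidence interval.  Run 01-03 first.
"""

from vidphen import load_schema
from vidphen.matrixio import read_feature_matrix
from vidphen.models import load_model
from vidphen.pipeline import RunConfig, cmd_sufficiency

cfg = RunConfig(seed=1, outdir="results/run")
schema = load_schema()
registry = {"ADTree8": load_model("results/run/model_ADTree8.json")}
cohort = read_feature_matrix("results/run/cohort_sufficiency.csv", schema)

out = cmd_sufficiency(cfg, registry, cohort)
print("bootstrap accuracy by number of raters (1,000 draws each):")
print(out["summary"].to_string(index=False, float_format=lambda x: f"{x:.3f}"))
c = out["comparison"]
verdict = "significant" if c["significant"] else "not significant"
print(
    f"\n3 vs 9 raters: difference in mean accuracy = {c['difference']:+.4f} "
    f"(95% CI {c['ci_low']:+.4f} to {c['ci_high']:+.4f}) -> {verdict} "
    f"at alpha={c['alpha']}"
)
if c["significant"]:
    print(
        "the bootstrap flags this (tiny) difference as nonzero; judge practical "
        "relevance by its magnitude relative to the per-draw SD above."
    )
else:
    print("no detectable gain beyond 3 raters: 3 is the minimally viable count.")
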