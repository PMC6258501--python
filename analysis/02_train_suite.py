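"""Train the eight-classifier suite on the simulated score sheets.

Each named model (ADTree7, ADTree8, SVM5, LR5, LR9, SVM12, SVM10, LR10)
is trained on its own cohort with its protocol: inverse-class-size weighting,
cross-validated regularization for the linear models, boosted Z-criterion
growth for the alternating decision trees.  Run 01_simulate.py first.
"""

import numpy as np

from vidphen import confusion_metrics, load_schema
from vidphen.matrixio import read_feature_matrix
from vidphen.pipeline import RunConfig, cmd_train

cfg = RunConfig(seed=1, outdir="results/run")
registry = cmd_train(cfg)
schema = load_schema()

print("trained classifier suite (training-set fit):")
print(f"{'model':8s} {'archetype':11s} {'#feat':5s} {'sens':>6s} {'spec':>6s} {'UAR':>6s}")
for name, model in registry.items():
    sheets = read_feature_matrix(f"results/run/sheets_{name}.csv", schema)
    X = sheets[list(model.feature_ids)].to_numpy(float)
    rep = confusion_metrics(model.predict(X), sheets["label"].to_numpy(int))
    print(
        f"{name:8s} {model.archetype:11s} {len(model.feature_ids):5d} "
        f"{rep.sensitivity:6.3f} {rep.specificity:6.3f} {rep.uar:6.3f}"
    )
print("\nmodels serialized to results/run/model_<name>.json")
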