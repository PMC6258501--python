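"""Boosted alternating decision trees (ADTree) over ordinal score vectors.

An alternating decision tree interleaves *prediction nodes* (real-valued
margin contributions) with *splitter nodes* (a threshold test on one feature).
Classification of a score vector sums the root prediction and the prediction
value of every branch the vector reaches; the class is the sign of that
margin.  Unlike an ordinary decision tree, several paths are active at once:
every splitter whose parent prediction node is reached contributes.

Training is boosting in the style of Freund & Mason's Z-criterion: each round
adds one splitter (with its two prediction children) under an existing
prediction node, chosen to minimize

    Z = 2·(√(W₊(c∧p)W₋(c∧p)) + √(W₊(c∧¬p)W₋(c∧¬p))) + W(¬c)

over preconditions c (reachable prediction nodes), split features and
thresholds, where W±(·) are current boosting weights of positive/negative
samples satisfying a condition.  The two new prediction values are the usual
half-log-odds of the weighted class masses, and weights are multiplied by
exp(−y·a) for samples receiving contribution a, so the weighted loss Σw is
non-increasing round over round.

Ordinal scores in {0,1,2,3} admit only the thresholds {0.5, 1.5, 2.5}, which
makes the per-round exhaustive candidate search cheap.  Boosting handles class
imbalance; optionally the initial weights are inverse class sizes and/or the
minority class is bootstrap up-sampled to parity before training.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

THRESHOLDS = (0.5, 1.5, 2.5)
_EPS = 1e-8


class TrainingError(ValueError):
    """Training data cannot support the requested model (e.g. single class)."""


@dataclass(frozen=True)
class ADTreeRule:
    """One splitter with its two prediction children.

    ``parent`` is the prediction-node id the splitter hangs under (0 is the
    root; rule i creates prediction nodes 2i+1 for the below branch and 2i+2
    for the above branch).
    """

    parent: int
    feature: int
    threshold: float
    pred_below: float
    pred_above: float


@dataclass
class ADTreeModel:
    """A fitted alternating decision tree: root prediction plus rules."""

    root_prediction: float
    rules: list[ADTreeRule] = field(default_factory=list)

    @property
    def features_used(self) -> tuple[int, ...]:
        return tuple(sorted({r.feature for r in self.rules}))

    def margin(self, x) -> float:
        """Sum of root and all reached prediction values for one vector."""
        x = np.asarray(x, dtype=float)
        reached = {0}
        total = self.root_prediction
        for i, rule in enumerate(self.rules):
            if rule.parent in reached:
                if x[rule.feature] < rule.threshold:
                    total += rule.pred_below
                    reached.add(2 * i + 1)
                else:
                    total += rule.pred_above
                    reached.add(2 * i + 2)
        return total

    def margins(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        n = X.shape[0]
        out = np.full(n, self.root_prediction)
        reach = {0: np.ones(n, dtype=bool)}
        for i, rule in enumerate(self.rules):
            parent = reach.get(rule.parent, np.zeros(n, dtype=bool))
            below = parent & (X[:, rule.feature] < rule.threshold)
            above = parent & ~(X[:, rule.feature] < rule.threshold)
            out += np.where(below, rule.pred_below, 0.0)
            out += np.where(above, rule.pred_above, 0.0)
            reach[2 * i + 1] = below
            reach[2 * i + 2] = above
        return out

    def to_dict(self) -> dict:
        return {
            "root_prediction": self.root_prediction,
            "rules": [
                {
                    "parent": r.parent,
                    "feature": r.feature,
                    "threshold": r.threshold,
                    "pred_below": r.pred_below,
                    "pred_above": r.pred_above,
                }
                for r in self.rules
            ],
        }

    @classmethod
    def from_dict(cls, raw: dict) -> "ADTreeModel":
        return cls(
            root_prediction=float(raw["root_prediction"]),
            rules=[
                ADTreeRule(
                    parent=int(r["parent"]),
                    feature=int(r["feature"]),
                    threshold=float(r["threshold"]),
                    pred_below=float(r["pred_below"]),
                    pred_above=float(r["pred_above"]),
                )
                for r in raw["rules"]
            ],
        )


def _half_log_odds(w_pos: float, w_neg: float) -> float:
    return 0.5 * np.log((w_pos + _EPS) / (w_neg + _EPS))


def fit_adtree(
    X,
    y,
    target_n_features: int,
    class_weighting: str = "inverse_class_size",
    upsample_to_parity: bool = False,
    seed: int = 0,
    max_rounds: int | None = None,
    loss_trace: list | None = None,
) -> ADTreeModel:
    """Grow an alternating decision tree by boosted Z-criterion search.

    Rounds continue until the number of distinct split features reaches
    ``target_n_features`` or no candidate improves the weighted loss.  If
    ``loss_trace`` is a list, the weighted loss after the root and after each
    round is appended to it.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    classes = np.unique(y)
    if len(classes) < 2:
        raise TrainingError("ADTree training requires both classes present")
    ysign = np.where(y > 0, 1.0, -1.0)
    if upsample_to_parity:
        rng = np.random.default_rng(seed)
        pos, neg = np.flatnonzero(ysign > 0), np.flatnonzero(ysign < 0)
        minority, majority = (pos, neg) if len(pos) < len(neg) else (neg, pos)
        extra = rng.choice(minority, size=len(majority) - len(minority), replace=True)
        keep = np.concatenate([np.arange(len(ysign)), extra])
        X, ysign = X[keep], ysign[keep]
    n = len(ysign)
    if class_weighting == "inverse_class_size":
        n_pos = int((ysign > 0).sum())
        n_neg = n - n_pos
        w = np.where(ysign > 0, 0.5 / n_pos, 0.5 / n_neg)
    else:
        w = np.full(n, 1.0 / n)

    root = _half_log_odds(w[ysign > 0].sum(), w[ysign < 0].sum())
    w = w * np.exp(-ysign * root)
    model = ADTreeModel(root_prediction=float(root))
    if loss_trace is not None:
        loss_trace.append(float(w.sum()))

    reach = {0: np.ones(n, dtype=bool)}
    if max_rounds is None:
        max_rounds = 4 * target_n_features
    n_feat = X.shape[1]
    for _ in range(max_rounds):
        used = set(model.features_used)
        allow_new = len(used) < target_n_features
        total = w.sum()
        best = None
        for node_id, mask in reach.items():
            if not mask.any():
                continue
            w_out = total - w[mask].sum()
            for f in range(n_feat):
                if not allow_new and f not in used:
                    continue
                for t in THRESHOLDS:
                    below = mask & (X[:, f] < t)
                    above = mask & ~(X[:, f] < t)
                    wp1 = w[below & (ysign > 0)].sum()
                    wn1 = w[below & (ysign < 0)].sum()
                    wp2 = w[above & (ysign > 0)].sum()
                    wn2 = w[above & (ysign < 0)].sum()
                    z = 2.0 * (np.sqrt(wp1 * wn1) + np.sqrt(wp2 * wn2)) + w_out
                    if best is None or z < best[0]:
                        best = (z, node_id, f, t, wp1, wn1, wp2, wn2)
        if best is None:
            break
        z, node_id, f, t, wp1, wn1, wp2, wn2 = best
        if z >= total - 1e-12:
            break  # no candidate reduces the weighted loss
        a_below = _half_log_odds(wp1, wn1)
        a_above = _half_log_odds(wp2, wn2)
        mask = reach[node_id]
        below = mask & (X[:, f] < t)
        above = mask & ~(X[:, f] < t)
        w = np.where(below, w * np.exp(-ysign * a_below), w)
        w = np.where(above, w * np.exp(-ysign * a_above), w)
        i = len(model.rules)
        model.rules.append(
            ADTreeRule(
                parent=node_id,
                feature=f,
                threshold=t,
                pred_below=float(a_below),
                pred_above=float(a_above),
            )
        )
        reach[2 * i + 1] = below
        reach[2 * i + 2] = above
        if loss_trace is not None:
            loss_trace.append(float(w.sum()))
        if len(model.features_used) >= target_n_features:
            break
    return model
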