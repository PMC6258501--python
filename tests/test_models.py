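"""Classifier suite: training protocols, probability links, imputation."""

import numpy as np
import pytest

import vidphen as v
from vidphen.models import REGISTRY_NAMES, TrainedModel, registry_specs


@pytest.fixture(scope="module")
def registry(schema, sheets_small):
    training = {name: sheets_small for name in REGISTRY_NAMES}
    return v.train_registry(training, schema, seed=0)


def test_registry_names_and_feature_counts(registry, schema):
    want = {"ADTree7": 7, "ADTree8": 8, "SVM5": 5, "LR5": 5, "LR9": 9,
            "SVM12": 12, "SVM10": 10, "LR10": 10}
    assert set(registry) == set(want)
    for name, n in want.items():
        assert len(registry[name].feature_ids) == n
        assert registry[name].feature_ids == schema.model_subsets[name]


def test_registry_missing_training_set_raises(schema, sheets_small):
    training = {name: sheets_small for name in REGISTRY_NAMES if name != "LR9"}
    with pytest.raises(KeyError, match="LR9"):
        v.train_registry(training, schema, seed=0)


def test_lr5_sparsity(registry):
    coef = np.asarray(registry["LR5"].params["coef"])
    assert coef.shape == (5,)
    assert np.count_nonzero(coef) <= 5


def test_separable_data_trains_to_perfection(schema):
    strong = v.LatentSeverityModel.default(schema, severity_shift=6.0,
                                           base=(0.97, 0.01, 0.01, 0.01))
    sheets = v.generate_training_sheets(
        v.CohortConfig(n_affected=150, n_unaffected=150, seed=13), strong, schema
    )
    training = {name: sheets for name in REGISTRY_NAMES}
    registry = v.train_registry(training, schema, seed=0)
    y = sheets["label"].to_numpy()
    for name, model in registry.items():
        X = sheets[list(model.feature_ids)].to_numpy(float)
        pred = model.predict(X)
        rep = v.confusion_metrics(pred, y)
        assert rep.sensitivity == 1.0 and rep.specificity == 1.0, name


def test_logistic_probability_closed_form(schema):
    ids = schema.model_subsets["LR5"]
    model = TrainedModel(
        name="LR5", archetype="logreg", feature_ids=ids,
        params={"coef": np.array([0.5, -1.0, 0.25, 0.0, 2.0]),
                "intercept": -0.3,
                "scaler_mean": np.zeros(5), "scaler_scale": np.ones(5),
                "feature_modes": np.zeros(5)},
    )
    x = np.array([1.0, 2.0, 3.0, 0.0, 1.0])
    z = -0.3 + 0.5 * 1 - 1.0 * 2 + 0.25 * 3 + 2.0 * 1
    assert model.predict_proba(x)[0] == pytest.approx(1 / (1 + np.exp(-z)))
    # all-zero coefficients and intercept -> indifference
    model.params["coef"] = np.zeros(5)
    model.params["intercept"] = 0.0
    assert model.predict_proba(x)[0] == 0.5
    assert model.predict(x)[0] == 1  # tie at 0.5 classifies as affected


def test_adtree_zero_margin_is_half(schema):
    from vidphen.adtree import ADTreeModel

    ids = schema.model_subsets["ADTree7"]
    model = TrainedModel(
        name="ADTree7", archetype="adtree", feature_ids=ids,
        params={"adtree": ADTreeModel(root_prediction=0.0).to_dict(),
                "feature_modes": np.zeros(7)},
    )
    assert model.predict_proba(np.zeros(7))[0] == 0.5


def test_probability_link_monotone_in_margin(registry):
    for name in ("SVM5", "SVM12", "ADTree8"):
        model = registry[name]
        rng = np.random.default_rng(5)
        X = rng.integers(0, 4, size=(60, len(model.feature_ids))).astype(float)
        m = model.margins(X)
        p = model.predict_proba(X)
        order = np.argsort(m)
        assert (np.diff(p[order]) >= -1e-12).all(), name


def test_predict_vector_validation(lr5_small):
    with pytest.raises(ValueError, match="length 5"):
        lr5_small.predict_proba(np.zeros(4))
    bad = np.array([0, 1, v.UNSCORABLE, 2, 3], dtype=float)
    with pytest.raises(ValueError, match="impute"):
        lr5_small.predict_proba(bad)


def test_impute_policies():
    clean = np.array([0.0, 1, 2, 3, 0])
    out, dropped = v.impute_missing(clean, "zero")
    assert np.array_equal(out, clean) and not dropped
    holey = np.array([0.0, 8, 2, 8, 0])
    out, dropped = v.impute_missing(holey, "zero")
    assert np.array_equal(out, [0, 0, 2, 0, 0]) and not dropped
    out, dropped = v.impute_missing(
        holey, "feature_mode_from_training", feature_modes=[1, 3, 1, 2, 1]
    )
    assert np.array_equal(out, [0, 3, 2, 2, 0]) and not dropped
    _, dropped = v.impute_missing(holey, "drop_rater")
    assert dropped
    _, dropped = v.impute_missing(
        np.full(5, 8.0), "feature_mode_from_training", feature_modes=np.ones(5)
    )
    assert dropped  # nothing observed: unusable
    with pytest.raises(ValueError):
        v.impute_missing(clean, "no_such_policy")


@pytest.mark.parametrize("name", ["LR5", "SVM5", "SVM12", "ADTree7"])
def test_model_serialization_roundtrip(registry, tmp_path, name):
    model = registry[name]
    path = tmp_path / f"{name}.json"
    v.save_model(model, path)
    again = v.load_model(path)
    rng = np.random.default_rng(6)
    X = rng.integers(0, 4, size=(25, len(model.feature_ids))).astype(float)
    assert np.allclose(model.predict_proba(X), again.predict_proba(X))
    assert again.feature_ids == model.feature_ids


def test_class_weighting_equivalent_to_duplication(schema, severity):
    """Inverse-class-size weighting ~ duplicating the minority to parity."""
    sheets = v.generate_training_sheets(
        v.CohortConfig(n_affected=240, n_unaffected=80, seed=17), severity, schema
    )
    dup = sheets[sheets.label == 0]
    import pandas as pd

    duplicated = pd.concat([sheets] + [dup] * 2, ignore_index=True)  # 240 vs 240
    ids = schema.model_subsets["LR10"]
    spec_w = v.ModelSpec(name="w", archetype="logreg", penalty="l2",
                         target_n_features=10, class_weighting="inverse_class_size",
                         cv_folds=2, seed=0)
    spec_d = v.ModelSpec(name="d", archetype="logreg", penalty="l2",
                         target_n_features=10, class_weighting="none",
                         cv_folds=2, seed=0)
    mw = v.train_model(sheets, spec_w, ids)
    md = v.train_model(duplicated, spec_d, ids)
    a = np.asarray(mw.params["coef"])
    b = np.asarray(md.params["coef"])
    cos = a @ b / (np.linalg.norm(a) * np.linalg.norm(b))
    assert cos > 0.95


def test_backward_selection_constant_feature_removed_first(schema, sheets_small):
    df = sheets_small.copy()
    const_id = schema.feature_ids[0]
    df[const_id] = 2
    spec = v.ModelSpec(name="sel", archetype="logreg", target_n_features=2,
                       cv_folds=3, seed=0)
    out = v.backward_feature_select(df, spec, [const_id, schema.feature_ids[1]])
    assert out["removal_order"][0] == const_id
    assert out["ranking"][0] == schema.feature_ids[1]


def test_backward_selection_full_ranking_keeps_all_features(sheets_small, schema):
    feats = list(schema.feature_ids[:6])
    spec = v.ModelSpec(name="sel", archetype="logreg", target_n_features=6,
                       cv_folds=3, seed=0)
    out = v.backward_feature_select(sheets_small, spec, feats)
    assert sorted(out["ranking"]) == sorted(feats)
    assert len(out["per_size"]) == 5  # sizes 6..2 were cross-validated


def test_backward_selection_prefers_informative_features(schema):
    """Planted informative features outrank pure-noise features."""
    wins = 0
    n_seeds = 10
    informative = list(schema.feature_ids[:3])
    feats = list(schema.feature_ids[:10])
    for seed in range(n_seeds):
        model = v.LatentSeverityModel.planted(schema, informative, shift=1.2)
        df = v.generate_training_sheets(
            v.CohortConfig(n_affected=150, n_unaffected=150, seed=100 + seed),
            model, schema,
        )
        spec = v.ModelSpec(name="sel", archetype="logreg", target_n_features=3,
                           cv_folds=5, seed=seed)
        out = v.backward_feature_select(df, spec, feats)
        if set(out["ranking"][:3]) == set(informative):
            wins += 1
    assert wins >= 8
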