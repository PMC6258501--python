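"""Elastic-net video-feature classifier: splits, grid search, evaluation."""

import numpy as np
import pandas as pd
import pytest

import vidphen as v


@pytest.fixture(scope="module")
def cohort176(schema, severity):
    noise = v.RaterNoiseModel(error_rate=0.2, missing_rate=0.0)
    cfg = v.CohortConfig(n_affected=121, n_unaffected=55, seed=41)
    return v.generate_video_cohort(cfg, severity, noise, 3, schema)


def test_split_is_exactly_stratified(schema, severity):
    noise = v.RaterNoiseModel(error_rate=0.1, missing_rate=0.0)
    cfg = v.CohortConfig(n_affected=100, n_unaffected=50, seed=42)
    cohort = v.generate_video_cohort(cfg, severity, noise, 3, schema)
    train, test = v.split_train_test(cohort, v.ENConfig(seed=0))
    test_videos = test.groupby("video_id")["label"].first()
    assert int((test_videos == 1).sum()) == 20
    assert int((test_videos == 0).sum()) == 10


def test_split_deterministic_and_video_integral(cohort176):
    cfg = v.ENConfig(seed=3)
    t1 = v.split_train_test(cohort176, cfg)
    t2 = v.split_train_test(cohort176, cfg)
    pd.testing.assert_frame_equal(t1[0], t2[0])
    assert len(cohort176) == 528 and cohort176["video_id"].nunique() == 176
    train, test = t1
    assert not set(train["video_id"]) & set(test["video_id"])
    assert len(train) + len(test) == 528


def test_split_refuses_to_empty_a_class(schema, severity):
    noise = v.RaterNoiseModel(error_rate=0.0, missing_rate=0.0)
    tiny = v.generate_video_cohort(
        v.CohortConfig(n_affected=2, n_unaffected=1, seed=1), severity, noise, 3, schema
    )
    with pytest.raises(v.SplitError):
        v.split_train_test(tiny, v.ENConfig(test_fraction=0.2, seed=0))


def test_single_pair_grid_returns_that_pair(cohort176, schema):
    cfg = v.ENConfig(alpha_grid=(0.05,), l1_ratio_grid=(0.7,), cv_folds=3, seed=0)
    train, _ = v.split_train_test(cohort176, cfg)
    alpha, l1_ratio, table = v.grid_search_en(train, cfg, schema)
    assert (alpha, l1_ratio) == (0.05, 0.7)
    assert len(table) == 1


def test_full_shrinkage_zeroes_every_coefficient(cohort176, schema):
    cfg = v.ENConfig(seed=0)
    train, _ = v.split_train_test(cohort176, cfg)
    model = v.train_en(train, alpha=1e4, l1_ratio=1.0, schema=schema, config=cfg)
    assert np.count_nonzero(model.coefficients) == 0
    assert model.ranking == []


def test_vanishing_penalty_approaches_unpenalized_fit(schema):
    from sklearn.linear_model import LogisticRegression

    # weak-signal cohort: the unpenalized optimum is finite and well-conditioned
    weak = v.LatentSeverityModel.default(schema, severity_shift=0.3)
    noise = v.RaterNoiseModel(error_rate=0.3, missing_rate=0.0)
    cohort = v.generate_video_cohort(
        v.CohortConfig(n_affected=80, n_unaffected=80, seed=45), weak, noise, 3, schema
    )
    cfg = v.ENConfig(seed=0, max_iter=50000, tol=1e-7)
    train, _ = v.split_train_test(cohort, cfg)
    model = v.train_en(train, alpha=1e-6, l1_ratio=0.5, schema=schema, config=cfg)
    feats = list(schema.feature_ids)
    X = train[feats].to_numpy(float)
    Z = (X - model.scaler_mean) / model.scaler_scale
    ref = LogisticRegression(C=np.inf, class_weight="balanced", max_iter=20000)
    ref.fit(Z, train["label"].to_numpy(int))
    assert np.allclose(model.coefficients, ref.coef_[0], atol=0.05)


def test_ranking_orders_nonzero_coefficients(cohort176, schema):
    cfg = v.ENConfig(seed=0)
    train, _ = v.split_train_test(cohort176, cfg)
    model = v.train_en(train, alpha=0.1, l1_ratio=1.0, schema=schema, config=cfg)
    nnz = np.count_nonzero(model.coefficients)
    assert len(model.ranking) == nnz
    mags = [abs(model.coefficients[model.feature_ids.index(f)]) for f in model.ranking]
    assert all(a >= b for a, b in zip(mags, mags[1:]))


def test_sparsity_nonincreasing_in_alpha(cohort176, schema):
    cfg = v.ENConfig(seed=0)
    train, _ = v.split_train_test(cohort176, cfg)
    sizes = []
    for alpha in (0.01, 0.1, 0.5, 2.0, 10.0):
        model = v.train_en(train, alpha=alpha, l1_ratio=1.0, schema=schema, config=cfg)
        sizes.append(np.count_nonzero(model.coefficients))
    assert all(b <= a for a, b in zip(sizes, sizes[1:]))


def test_evaluation_refuses_training_videos(cohort176, schema):
    cfg = v.ENConfig(seed=0)
    train, test = v.split_train_test(cohort176, cfg)
    model = v.train_en(train, alpha=0.1, l1_ratio=0.6, schema=schema, config=cfg)
    with pytest.raises(v.LeakageError):
        v.evaluate_en(model, train, schema)
    rep, detail = v.evaluate_en(model, test, schema, n_boot=50)
    assert 0.0 <= rep.auc <= 1.0
    assert len(detail) == len(test)


def test_heldout_auc_matches_pair_counting_on_small_fixture(cohort176, schema):
    import itertools

    def brute_force_auc(probs, truths):
        pos = [p for p, t in zip(probs, truths) if t == 1]
        neg = [p for p, t in zip(probs, truths) if t == 0]
        wins = sum(
            1.0 if a > b else 0.5 if a == b else 0.0
            for a, b in itertools.product(pos, neg)
        )
        return wins / (len(pos) * len(neg))

    cfg = v.ENConfig(seed=0)
    train, test = v.split_train_test(cohort176, cfg)
    model = v.train_en(train, alpha=0.1, l1_ratio=0.6, schema=schema, config=cfg)
    small = test[test["video_id"].isin(sorted(set(test["video_id"]))[:4])]
    assert len(small) == 12
    if small["label"].nunique() == 2:
        rep, detail = v.evaluate_en(model, small, schema, n_boot=20)
        assert rep.auc == pytest.approx(
            brute_force_auc(detail["probability"], detail["label"])
        )


def test_perfect_signal_yields_auc_one(schema):
    strong = v.LatentSeverityModel.default(
        schema, severity_shift=6.0, base=(0.97, 0.01, 0.01, 0.01)
    )
    noise = v.RaterNoiseModel(error_rate=0.0, missing_rate=0.0)
    cohort = v.generate_video_cohort(
        v.CohortConfig(n_affected=40, n_unaffected=40, seed=43), strong, noise, 3, schema
    )
    cfg = v.ENConfig(seed=0)
    train, test = v.split_train_test(cohort, cfg)
    model = v.train_en(train, alpha=0.01, l1_ratio=0.6, schema=schema, config=cfg)
    rep, _ = v.evaluate_en(model, test, schema, n_boot=20)
    assert rep.auc == 1.0


def test_null_signal_gives_chance_auc(schema):
    null = v.LatentSeverityModel.default(schema, severity_shift=0.0)
    noise = v.RaterNoiseModel(error_rate=0.0, missing_rate=0.0)
    cohort = v.generate_video_cohort(
        v.CohortConfig(n_affected=150, n_unaffected=150, seed=44), null, noise, 3, schema
    )
    cfg = v.ENConfig(seed=0)
    train, test = v.split_train_test(cohort, cfg)
    model = v.train_en(train, alpha=0.5, l1_ratio=0.9, schema=schema, config=cfg)
    rep, _ = v.evaluate_en(model, test, schema, n_boot=20)
    assert abs(rep.auc - 0.5) < 0.15
    assert np.abs(model.coefficients).max() < 0.2
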