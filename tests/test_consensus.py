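"""Majority-rules voting, tie-breaks and interrater agreement."""

import itertools

import numpy as np
import pytest

import vidphen as v
from vidphen.matrixio import AFFECTED, UNAFFECTED


class EnumRNG:
    """Deterministic stand-in rng returning a fixed draw index."""

    def __init__(self, value):
        self.value = value

    def integers(self, n):
        assert self.value < n
        return self.value


def oracle_vote(votes, reserve_fraction_affected=None):
    """Exhaustive-enumeration oracle: P(majority == affected) for a pattern."""
    n = len(votes)
    n_aff = sum(votes)
    if n % 2 == 1:
        return 1.0 if 2 * n_aff > n else 0.0
    if 2 * n_aff > n:
        return 1.0
    if 2 * n_aff < n:
        return 0.0
    return reserve_fraction_affected  # even tie -> reserve rater decides


def test_vote_matches_enumeration_for_all_patterns_k_le_5():
    policy_seedless = dict()
    for k in range(1, 6):
        for pattern in itertools.product([0, 1], repeat=k):
            policy = v.ConsensusPolicy(n_raters=k, seed=0)
            reserve = [AFFECTED, UNAFFECTED]  # one of each; tie -> 50/50
            expected = oracle_vote(list(pattern), reserve_fraction_affected=0.5)
            if expected in (0.0, 1.0):
                maj, unanimous, tb = v.vote(list(pattern), policy, reserve=reserve)
                assert maj == int(expected)
                assert unanimous == (len(set(pattern)) == 1)
                assert not tb
            else:
                # enumerate every equally likely reserve draw
                outcomes = [
                    v.vote(list(pattern), policy, reserve=reserve, rng=EnumRNG(i))[0]
                    for i in range(len(reserve))
                ]
                assert np.mean(outcomes) == pytest.approx(expected)


def test_tiebreak_draw_distribution_four_sevenths():
    """[A, N] with a 7-vote reserve of which 4 are A -> P(A) = 4/7 exactly."""
    policy = v.ConsensusPolicy(n_raters=2, seed=0)
    reserve = [AFFECTED] * 4 + [UNAFFECTED] * 3
    outcomes = [
        v.vote([AFFECTED, UNAFFECTED], policy, reserve=reserve, rng=EnumRNG(i))
        for i in range(7)
    ]
    assert all(tb for _, _, tb in outcomes)
    assert sum(maj == AFFECTED for maj, _, _ in outcomes) == 4


def test_two_rater_agreement_needs_no_tiebreak():
    policy = v.ConsensusPolicy(n_raters=2, seed=0)
    assert policy.rule == "unanimity_for_two"
    maj, unanimous, tb = v.vote([1, 1], policy)
    assert (maj, unanimous, tb) == (1, True, False)


def test_even_tie_without_reserve_errors():
    policy = v.ConsensusPolicy(n_raters=2, seed=0)
    with pytest.raises(v.ConsensusError, match="reserve"):
        v.vote([1, 0], policy, reserve=[])


def test_vote_length_mismatch_errors():
    with pytest.raises(v.ConsensusError):
        v.vote([1, 1], v.ConsensusPolicy(n_raters=3))


def test_vote_permutation_invariance():
    policy = v.ConsensusPolicy(n_raters=5, seed=0)
    for pattern in itertools.product([0, 1], repeat=5):
        base = v.vote(list(pattern), policy)[0]
        for perm in itertools.permutations(pattern):
            assert v.vote(list(perm), policy)[0] == base


def test_flip_toward_affected_never_decreases_majority_probability():
    for k in range(1, 6):
        for pattern in itertools.product([0, 1], repeat=k):
            p = oracle_vote(list(pattern), reserve_fraction_affected=0.5)
            for i, vote_i in enumerate(pattern):
                if vote_i == 0:
                    flipped = list(pattern)
                    flipped[i] = 1
                    assert oracle_vote(flipped, 0.5) >= p


def test_noiseless_cohort_is_unanimous(schema, severity, lr5_small):
    cfg = v.CohortConfig(n_affected=15, n_unaffected=15, seed=31)
    noise = v.RaterNoiseModel(error_rate=0.0, missing_rate=0.0)
    cohort = v.generate_video_cohort(cfg, severity, noise, 3, schema)
    results, skipped = v.classify_cohort(
        cohort, lr5_small, v.ConsensusPolicy(n_raters=3, seed=0), schema
    )
    assert not skipped
    assert all(r.unanimous for r in results)
    assert v.interrater_agreement(results) == 1.0


def test_short_staffed_videos_are_skipped_not_crashed(schema, severity, lr5_small):
    cfg = v.CohortConfig(n_affected=6, n_unaffected=6, seed=32)
    noise = v.RaterNoiseModel(error_rate=0.1, missing_rate=0.0)
    cohort = v.generate_video_cohort(cfg, severity, noise, 3, schema)
    first = cohort["video_id"].iloc[0]
    cohort = cohort[
        ~((cohort.video_id == first) & (cohort.rater_id == "rater3"))
    ]
    results, skipped = v.classify_cohort(
        cohort, lr5_small, v.ConsensusPolicy(n_raters=3, seed=0), schema
    )
    assert [s["video_id"] for s in skipped] == [first]
    assert len(results) == 11


def test_interrater_agreement_values():
    def res(unanimous):
        return v.ConsensusResult(
            video_id="x", votes=(1, 1, 1), probabilities=(0.9, 0.9, 0.9),
            majority_class=1, unanimous=unanimous, pooled_probability=0.9,
        )

    assert v.interrater_agreement([res(True)] * 3) == 1.0
    assert v.interrater_agreement([res(False)] * 3) == 0.0
    with pytest.raises(ValueError):
        v.interrater_agreement([])


def test_three_rater_majority_matches_binomial_closed_form():
    """iid per-rater accuracy q: majority accuracy = q^3 + 3q^2(1-q)."""
    q = 0.8
    rng = np.random.default_rng(33)
    n_videos = 4000
    truths = rng.integers(0, 2, n_videos)
    correct = rng.random((n_videos, 3)) < q
    votes = np.where(correct, truths[:, None], 1 - truths[:, None])
    policy = v.ConsensusPolicy(n_raters=3, seed=0)
    maj = [v.vote(list(votes[i]), policy)[0] for i in range(n_videos)]
    acc = np.mean(np.asarray(maj) == truths)
    expected = q**3 + 3 * q**2 * (1 - q)
    assert acc == pytest.approx(expected, abs=0.02)


def test_pooled_probability_is_mean_of_rater_probabilities(
    schema, severity, lr5_small
):
    cfg = v.CohortConfig(n_affected=8, n_unaffected=8, seed=34)
    noise = v.RaterNoiseModel(error_rate=0.2, missing_rate=0.0)
    cohort = v.generate_video_cohort(cfg, severity, noise, 3, schema)
    results, _ = v.classify_cohort(
        cohort, lr5_small, v.ConsensusPolicy(n_raters=3, seed=0), schema
    )
    for r in results:
        assert r.pooled_probability == pytest.approx(np.mean(r.probabilities))
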