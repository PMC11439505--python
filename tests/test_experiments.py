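"""Metrics, significance tests, and the three-arm protocol machinery."""

import itertools

import numpy as np
import pytest
from scipy import stats

import adherence_da as ad


# ---------------------------------------------------------------- metrics

def test_metrics_perfect_prediction():
    ms = ad.compute_metrics([1, 0, 1, 0], [1, 0, 1, 0])
    assert (ms.accuracy, ms.precision, ms.recall, ms.f1) == (1, 1, 1, 1)


def test_metrics_hand_confusion_matrix():
    # TP=2 FP=2 FN=0 TN=0
    ms = ad.compute_metrics([1, 0, 1, 0], [1, 1, 1, 1])
    assert ms.accuracy == 0.5
    assert ms.precision == 0.5
    assert ms.recall == 1.0
    assert ms.f1 == pytest.approx(2 / 3)


def test_metrics_zero_denominators_flagged():
    ms = ad.compute_metrics([0, 0], [0, 0])
    assert ms.accuracy == 1.0
    assert ms.precision == 0.0 and ms.recall == 0.0
    assert {"precision", "recall"} <= set(ms.undefined)


def test_metrics_random_against_hand_counts():
    rng = np.random.default_rng(0)
    y, p = rng.integers(0, 2, 50), rng.integers(0, 2, 50)
    tp = ((y == 1) & (p == 1)).sum()
    fp = ((y == 0) & (p == 1)).sum()
    fn = ((y == 1) & (p == 0)).sum()
    ms = ad.compute_metrics(y, p)
    assert ms.precision == pytest.approx(tp / (tp + fp))
    assert ms.recall == pytest.approx(tp / (tp + fn))
    assert ms.f1 == pytest.approx(2 * tp / (2 * tp + fp + fn))


def test_metrics_macro_average_is_mean_of_classes():
    y = np.array([1, 0, 1, 0, 1])
    p = np.array([1, 1, 0, 0, 1])
    binary1 = ad.compute_metrics(y, p)
    binary0 = ad.compute_metrics(1 - y, 1 - p)
    macro = ad.compute_metrics(y, p, average="macro")
    assert macro.precision == pytest.approx((binary0.precision + binary1.precision) / 2)
    assert macro.f1 == pytest.approx((binary0.f1 + binary1.f1) / 2)


def test_metrics_reject_bad_input():
    with pytest.raises(ValueError):
        ad.compute_metrics([], [])
    with pytest.raises(ValueError):
        ad.compute_metrics([1], [1, 0])


# --------------------------------------------------------------- sign test

def test_sign_test_all_positive():
    r = ad.sign_test(np.arange(1, 9), np.zeros(8))
    assert r.p_value == pytest.approx(2 * 0.5**8)  # 0.0078125
    assert r.n_effective == 8 and r.n_positive == 8


def test_sign_test_all_ties_flagged():
    r = ad.sign_test([1.0, 2.0], [1.0, 2.0])
    assert r.p_value == 1.0 and r.all_ties


def brute_force_sign_p(n_pos, n):
    """Two-sided exact binomial tail by enumerating all 2^n sign patterns."""
    observed = abs(n_pos - n / 2)
    count = sum(1 for signs in itertools.product([0, 1], repeat=n)
                if abs(sum(signs) - n / 2) >= observed - 1e-12)
    return count / 2**n


@pytest.mark.parametrize("n_pos,n", [(5, 9), (2, 9), (7, 12), (6, 12)])
def test_sign_test_matches_exhaustive_enumeration(n_pos, n):
    a = np.concatenate([np.ones(n_pos), -np.ones(n - n_pos)])
    r = ad.sign_test(a, np.zeros(n))
    assert r.p_value == pytest.approx(brute_force_sign_p(n_pos, n), abs=1e-12)


def test_sign_test_drops_ties_before_counting():
    a = np.array([1.0, 1.0, 1.0, 5.0, 5.0])
    b = np.array([0.0, 0.0, 0.0, 5.0, 5.0])
    r = ad.sign_test(a, b)
    assert r.n_effective == 3 and r.n_positive == 3
    assert r.p_value == pytest.approx(2 * 0.5**3)


# ------------------------------------------------------------ RM-ANOVA

def test_rm_anova_identical_columns():
    M = np.tile(np.random.default_rng(1).normal(size=(6, 1)), (1, 3))
    r = ad.repeated_measures_anova(M)
    assert r.F == 0.0 and r.p_value == 1.0


def test_rm_anova_two_conditions_equals_paired_t_squared():
    rng = np.random.default_rng(2)
    M = rng.normal(size=(12, 2))
    r = ad.repeated_measures_anova(M)
    t = stats.ttest_rel(M[:, 0], M[:, 1])
    assert r.F == pytest.approx(t.statistic**2, abs=1e-9)
    assert r.p_value == pytest.approx(t.pvalue, abs=1e-9)


def test_rm_anova_three_conditions_hand_sums_of_squares():
    # classic worked dataset: 5 subjects x 3 conditions
    M = np.array([[8.0, 7.0, 6.0],
                  [9.0, 9.0, 8.0],
                  [6.0, 6.0, 4.0],
                  [5.0, 4.0, 2.0],
                  [7.0, 6.0, 5.0]])
    n, k = M.shape
    grand = M.mean()
    ss_cond = n * ((M.mean(axis=0) - grand) ** 2).sum()
    ss_subj = k * ((M.mean(axis=1) - grand) ** 2).sum()
    ss_err = ((M - grand) ** 2).sum() - ss_cond - ss_subj
    F_hand = (ss_cond / (k - 1)) / (ss_err / ((n - 1) * (k - 1)))
    r = ad.repeated_measures_anova(M)
    assert r.F == pytest.approx(F_hand, abs=1e-9)
    assert r.df_condition == 2 and r.df_error == 8


def test_rm_anova_rejects_incomplete_matrix():
    M = np.ones((4, 2))
    M[0, 0] = np.nan
    with pytest.raises(ValueError):
        ad.repeated_measures_anova(M)
    with pytest.raises(ValueError):
        ad.repeated_measures_anova(np.ones((1, 3)))


# ------------------------------------------------------------- protocol

@pytest.fixture(scope="module")
def mini_result():
    """Three-arm within-study run on a small mixed cohort (fast config)."""
    logs = ad.make_benchmark_pair(8, shift=0.8, seed=5)
    cfg = ad.ExperimentConfig(K=2,
                              cnn=ad.CNNConfig(epochs=25, early_stop_patience=8),
                              dann=ad.DANNConfig(lambda_=1.0))
    return ad.run_within_study(logs, cfg, seed=5)


def test_all_arms_share_identical_test_labels(mini_result):
    for pid, by_arm in mini_result.runs.items():
        ys = [by_arm[a].y_true for a in ad.ARMS]
        for y in ys[1:]:
            np.testing.assert_array_equal(ys[0], y)


def test_normalization_never_sees_test_days(mini_result):
    for pid, by_arm in mini_result.runs.items():
        for a in ad.ARMS:
            lo, hi = by_arm[a].scaler_day_range
            assert lo >= 1 and hi <= 30


def test_aggregate_mean_matches_hand_average(mini_result):
    agg = mini_result.aggregate()
    for arm in ad.ARMS:
        hand = np.mean([ms.accuracy for ms in
                        (mini_result.per_participant[p][arm]
                         for p in mini_result.per_participant)])
        assert agg[arm]["accuracy"][0] == pytest.approx(hand)


def test_summary_reports_percentages(mini_result):
    s = mini_result.summary(percent=True)
    agg = mini_result.aggregate()
    for arm in ad.ARMS:
        assert s[arm]["accuracy"]["mean"] == pytest.approx(
            100 * agg[arm]["accuracy"][0], abs=0.01)


def test_cross_study_sources_come_from_other_study():
    logs_a, logs_b = ad.make_benchmark_pair(6, shift=0.5, seed=9,
                                            cross_study=True)
    cfg = ad.ExperimentConfig(K=2,
                              cnn=ad.CNNConfig(epochs=10, early_stop_patience=5))
    res = ad.run_cross_study(logs_a, logs_b, cfg, seed=9)
    assign = res.assignment
    for pid in res.per_participant:
        own_study = assign.study_ids[pid]
        pool = ad.source_pool(assign, pid, restrict_study=own_study)
        assert all(assign.study_ids[s] != own_study for s in pool)


def test_within_study_rejects_mixed_cohort():
    logs_a, logs_b = ad.make_benchmark_pair(4, seed=1, cross_study=True)
    with pytest.raises(ValueError):
        ad.run_within_study(list(logs_a) + list(logs_b))


def test_run_arm_unknown_arm_rejected(mini_result):
    with pytest.raises(ValueError):
        ad.run_arm("with_magic", "x", mini_result.assignment, {},
                   ad.ExperimentConfig())
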