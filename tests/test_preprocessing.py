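"""Labeling, splitting, FFT window selection, normalization, windowing."""

import numpy as np
import pytest

import adherence_da as ad
from adherence_da.cohort import DayRecord, ParticipantLog
from adherence_da.errors import ShortLogError
from adherence_da.preprocessing import WindowConfig


def _log_from_durations(durs, pid="p", study="study1"):
    days = [DayRecord(i + 1, float(v), int(v > 0), 0, int(v > 0))
            for i, v in enumerate(durs)]
    return ParticipantLog(pid, study, days)


@pytest.mark.parametrize("duration,expected", [
    (10.0, 1),   # exactly at the 10-minute criterion counts as adherent
    (0.0, 0),
    (9.99, 0),
    (45.0, 1),
])
def test_adherence_threshold_sides(duration, expected):
    log = _log_from_durations([duration])
    assert ad.label_adherence(log)[0] == expected


def test_split_is_first_30_next_30():
    log = _log_from_durations(range(1, 61))
    train, test = ad.split_train_test(log)
    assert [d.day_index for d in train.days] == list(range(1, 31))
    assert [d.day_index for d in test.days] == list(range(31, 61))


def test_split_short_log_names_participant():
    log = _log_from_durations(range(59), pid="short_one")
    with pytest.raises(ShortLogError, match="short_one"):
        ad.split_train_test(log)


def test_split_ignores_days_beyond_60():
    log = _log_from_durations(range(70))
    train, test = ad.split_train_test(log)
    assert train.days[-1].day_index == 30
    assert test.days[-1].day_index == 60


def test_window_size_pure_sinusoid():
    t = np.arange(28)
    assert ad.select_window_size(np.sin(2 * np.pi * t / 7)) == 7


def test_window_size_prescribed_schedule(schedule_series_30):
    assert ad.select_window_size(schedule_series_30) == 7


def test_window_size_constant_series_falls_back():
    with pytest.warns(UserWarning, match="flat"):
        assert ad.select_window_size(np.full(30, 45.0)) == 7
    with pytest.warns(UserWarning):
        assert ad.select_window_size(np.full(30, 45.0),
                                     WindowConfig(fallback_N=5)) == 5


def test_window_size_too_short_series_errors():
    with pytest.raises(ValueError):
        ad.select_window_size(np.ones(10))


def _naive_dft_period(series, pad_factor=8):
    """O(n^2) DFT oracle: argmax amplitude over candidate periods."""
    series = np.asarray(series, float)
    T = len(series)
    x = np.concatenate([series - series.mean(), np.zeros((pad_factor - 1) * T)])
    n = len(x)
    best, best_amp = None, -1.0
    for k in range(1, n // 2 + 1):
        re = sum(x[t] * np.cos(-2 * np.pi * k * t / n) for t in range(n))
        im = sum(x[t] * np.sin(-2 * np.pi * k * t / n) for t in range(n))
        period = n / k
        if not (2.0 <= period <= T / 2.0):
            continue
        amp = np.hypot(re, im)
        if amp > best_amp:
            best, best_amp = period, amp
    return int(round(best))


@pytest.mark.parametrize("seed", [0, 1, 2])
def test_window_size_matches_naive_dft_oracle(seed):
    rng = np.random.default_rng(seed)
    series = rng.uniform(0, 60, size=24)
    assert ad.select_window_size(series) == _naive_dft_period(series)


def test_normalization_zero_variance_and_closed_form():
    train = np.column_stack([np.full(10, 45.0),
                             np.array([20.0] * 5 + [30.0] * 5),
                             np.arange(10.0), np.arange(10.0)])
    z, _, scaler = ad.normalize_features(train)
    assert (z[:, 0] == 0).all()               # constant column maps to zero
    # column mean 25, sd 5 -> value 30 standardizes to 1
    assert z[5, 1] == pytest.approx(1.0)


def test_normalization_round_trip():
    rng = np.random.default_rng(4)
    train = rng.uniform(0, 60, size=(20, 4))
    z, _, scaler = ad.normalize_features(train)
    np.testing.assert_allclose(scaler.inverse_transform(z), train, atol=1e-12)


def test_normalization_no_leakage():
    """Test-set statistics must not influence the transform."""
    rng = np.random.default_rng(5)
    train = rng.uniform(0, 60, size=(30, 4))
    test_a = rng.uniform(0, 60, size=(30, 4))
    test_b = test_a + 1000.0  # wildly different test data
    za, _, _ = ad.normalize_features(train, test_a)
    zb, _, _ = ad.normalize_features(train, test_b)
    np.testing.assert_array_equal(za, zb)


def test_make_windows_counts_and_alignment():
    D, N = 30, 7
    features = np.arange(D * 4, dtype=float).reshape(D, 4)
    labels = np.arange(D) % 2
    ds = ad.make_windows(features, labels, N)
    assert len(ds) == D - N == 23
    # window k covers days k+1..k+N and is labeled by day k+N+1
    np.testing.assert_array_equal(ds.X[0], features[:7])
    assert ds.y[0] == labels[7]
    np.testing.assert_array_equal(ds.X[-1], features[D - N - 1:D - 1])
    assert ds.y[-1] == labels[-1]


def test_make_windows_boundaries():
    features = np.zeros((8, 4))
    ds = ad.make_windows(features, np.zeros(8), 7)
    assert len(ds) == 1
    with pytest.raises(ValueError):
        ad.make_windows(np.zeros((7, 4)), np.zeros(7), 7)


def test_label_shift_changes_every_window_label():
    rng = np.random.default_rng(6)
    D, N = 40, 7
    features = rng.normal(size=(D, 4))
    labels = np.arange(D)  # unique labels make shifts visible
    base = ad.make_windows(features, labels, N)
    shifted = ad.make_windows(features, labels + 1, N)
    assert (base.y != shifted.y).all()


def test_participant_windows_scaler_fitted_on_train_days_only(small_cohort):
    log = small_cohort[0]
    _, _, scaler = ad.participant_windows(log, 7)
    assert scaler.fit_day_range == (1, 30)
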