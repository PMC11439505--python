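"""From daily play logs to labeled sliding-window datasets.

The prediction task: given the four play variables for ``N`` consecutive
days, predict whether the participant meets the minimal adherence
criterion (at least 10 minutes of play) on day ``N+1``.  This module
provides adherence labeling, the chronological 30/30 train/test split,
FFT-based selection of the window size ``N`` from the dominant cyclic
period of the play-time series, leakage-free feature standardization, and
window construction.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

from .cohort import ParticipantLog
from .errors import ConfigurationError, ShortLogError

log = logging.getLogger(__name__)

__all__ = [
    "AdherenceCriterion",
    "SplitConfig",
    "WindowConfig",
    "WindowedDataset",
    "FeatureScaler",
    "label_adherence",
    "split_train_test",
    "select_window_size",
    "normalize_features",
    "make_windows",
    "participant_windows",
]


@dataclass(frozen=True)
class AdherenceCriterion:
    """Daily adherence = played for at least ``threshold_minutes``."""

    threshold_minutes: float = 10.0

    def __post_init__(self):
        if self.threshold_minutes <= 0:
            raise ConfigurationError("threshold_minutes must be > 0")


@dataclass(frozen=True)
class SplitConfig:
    """Chronological split: first ``train_days`` for training, next
    ``test_days`` for testing; any later days are unused."""

    train_days: int = 30
    test_days: int = 30


@dataclass(frozen=True)
class WindowConfig:
    """Window-size selection parameters.

    ``pad_factor`` zero-pads the series before the FFT so the dominant
    period is located on a grid fine enough to resolve a weekly cycle in
    a 30-day record; ``fallback_N`` is returned when the centered series
    has no spectral peak (e.g. a constant series).
    """

    N: int | None = None  # fixed window size; None = select via FFT
    fallback_N: int = 7
    pad_factor: int = 8
    amplitude_tol: float = 1e-9


@dataclass
class WindowedDataset:
    """Paired (N-day feature window, next-day adherence label) samples.

    ``X`` has shape (n_windows, N, 4); ``y`` is the binary adherence of
    the day following each window; ``domain`` optionally tags each window
    0 (target) / 1 (source) for the adversarial trainer.
    """

    X: np.ndarray
    y: np.ndarray
    domain: np.ndarray | None = None
    participant_ids: list[str] = field(default_factory=list)

    def __post_init__(self):
        self.X = np.asarray(self.X, dtype=float)
        self.y = np.asarray(self.y, dtype=np.int64)
        if self.X.ndim != 3:
            raise ValueError(f"X must be 3-D (windows, N, features), got {self.X.shape}")
        if len(self.X) != len(self.y):
            raise ValueError("window/label count mismatch")
        if self.domain is not None and len(self.domain) != len(self.y):
            raise ValueError("domain tag count mismatch")

    def __len__(self) -> int:
        return len(self.y)

    @property
    def window_size(self) -> int:
        return self.X.shape[1]

    def with_domain(self, tag: int) -> "WindowedDataset":
        return WindowedDataset(self.X, self.y, np.full(len(self.y), tag, dtype=np.int64),
                               self.participant_ids)

    @staticmethod
    def concatenate(parts: list["WindowedDataset"]) -> "WindowedDataset":
        parts = [p for p in parts if len(p) > 0]
        if not parts:
            raise ValueError("nothing to concatenate")
        dom = None
        if all(p.domain is not None for p in parts):
            dom = np.concatenate([p.domain for p in parts])
        ids = [pid for p in parts for pid in (p.participant_ids or [""] * len(p))]
        return WindowedDataset(np.concatenate([p.X for p in parts]),
                               np.concatenate([p.y for p in parts]), dom, ids)


def label_adherence(log_: ParticipantLog,
                    criterion: AdherenceCriterion = AdherenceCriterion()) -> np.ndarray:
    """Binary adherence per day: 1 iff duration >= threshold (default 10 min)."""
    if log_.n_days == 0:
        raise ValueError("empty participant log")
    return (log_.durations() >= criterion.threshold_minutes).astype(np.int64)


def split_train_test(log_: ParticipantLog,
                     cfg: SplitConfig = SplitConfig()
                     ) -> tuple[ParticipantLog, ParticipantLog]:
    """First ``train_days`` / next ``test_days``; raises ShortLogError otherwise."""
    need = cfg.train_days + cfg.test_days
    if log_.n_days < need:
        raise ShortLogError(log_.participant_id, log_.n_days, need)
    first = log_.days[0].day_index
    train = log_.slice_days(first, first + cfg.train_days - 1)
    test = log_.slice_days(first + cfg.train_days, first + need - 1)
    return train, test


def _amplitude_spectrum(series: np.ndarray, n_fft: int) -> tuple[np.ndarray, np.ndarray]:
    """|DFT| of the mean-centered series zero-padded to ``n_fft``, with periods."""
    centered = series - series.mean()
    amp = np.abs(np.fft.rfft(centered, n=n_fft))
    freqs = np.fft.rfftfreq(n_fft, d=1.0)
    periods = np.full_like(freqs, np.inf)
    periods[1:] = 1.0 / freqs[1:]
    return amp, periods


def select_window_size(series: np.ndarray,
                       cfg: WindowConfig = WindowConfig()) -> int:
    """Dominant cyclic period of a daily play-time series, in days.

    The mean-centered series is zero-padded (``pad_factor`` times its
    length), the nonzero frequency with maximum amplitude is located, and
    its period is rounded to the nearest integer day.  Candidate periods
    are restricted to [2, T/2]: the mean is not a periodicity and periods
    longer than half the record are unresolvable.  A flat spectrum falls
    back to ``fallback_N`` (one week) with a warning.  Applied to a
    5-days-on / 2-days-off prescribed schedule this yields 7.
    """
    series = np.asarray(series, dtype=float)
    T = len(series)
    if T < 2 * cfg.fallback_N:
        raise ValueError(
            f"series of length {T} too short for period selection "
            f"(need >= {2 * cfg.fallback_N})")
    amp, periods = _amplitude_spectrum(series, cfg.pad_factor * T)
    mask = (periods >= 2.0) & (periods <= T / 2.0)
    scale = max(float(np.abs(series - series.mean()).max()), 1.0)
    if not mask.any() or amp[mask].max() <= cfg.amplitude_tol * scale * T:
        warnings.warn("flat amplitude spectrum; falling back to "
                      f"N={cfg.fallback_N}", stacklevel=2)
        return cfg.fallback_N
    idx = np.flatnonzero(mask)[int(np.argmax(amp[mask]))]
    return int(round(periods[idx]))


class FeatureScaler:
    """Per-feature standardization fitted on training days only.

    Zero-variance features map to 0 so a constant predictor column cannot
    inject NaNs.  The fitted day range is recorded so leakage audits can
    assert that no test-day value influenced the transform.
    """

    def __init__(self):
        self.mean_: np.ndarray | None = None
        self.scale_: np.ndarray | None = None
        self.fit_day_range: tuple[int, int] | None = None

    def fit(self, features: np.ndarray, day_range: tuple[int, int] | None = None
            ) -> "FeatureScaler":
        features = np.asarray(features, dtype=float)
        if features.size == 0:
            raise ValueError("cannot fit scaler on empty features")
        flat = features.reshape(-1, features.shape[-1])
        self.mean_ = flat.mean(axis=0)
        sd = flat.std(axis=0, ddof=0)
        self.scale_ = np.where(sd > 0, sd, 1.0)
        self._zero_var = sd == 0
        self.fit_day_range = day_range
        return self

    def transform(self, features: np.ndarray) -> np.ndarray:
        if self.mean_ is None:
            raise ValueError("scaler not fitted")
        out = (np.asarray(features, dtype=float) - self.mean_) / self.scale_
        if self._zero_var.any():
            out[..., self._zero_var] = 0.0
        return out

    def inverse_transform(self, features: np.ndarray) -> np.ndarray:
        if self.mean_ is None:
            raise ValueError("scaler not fitted")
        return np.asarray(features, dtype=float) * self.scale_ + self.mean_


def normalize_features(train: np.ndarray, test: np.ndarray | None = None):
    """Standardize with statistics from ``train`` only; same transform on ``test``.

    Returns ``(train_z, test_z, scaler)`` (``test_z`` is None when no test
    array is given).
    """
    scaler = FeatureScaler().fit(train)
    train_z = scaler.transform(train)
    test_z = scaler.transform(test) if test is not None else None
    return train_z, test_z, scaler


def make_windows(features: np.ndarray, labels: np.ndarray, N: int,
                 participant_id: str = "") -> WindowedDataset:
    """Slide an N-day window over per-day features; label with day N+1.

    Window ``k`` (0-based) covers days ``k+1..k+N`` and carries the
    adherence label of day ``k+N+1``; a D-day record yields ``D - N``
    windows.
    """
    features = np.asarray(features, dtype=float)
    labels = np.asarray(labels)
    D = len(features)
    if len(labels) != D:
        raise ValueError("features/labels length mismatch")
    if D < N + 1:
        raise ValueError(f"need at least N+1={N + 1} days to form a window, got {D}")
    X = np.stack([features[k:k + N] for k in range(D - N)])
    y = labels[N:]
    return WindowedDataset(X, y, participant_ids=[participant_id] * (D - N))


def participant_windows(log_: ParticipantLog, N: int,
                        criterion: AdherenceCriterion = AdherenceCriterion(),
                        split: SplitConfig = SplitConfig()
                        ) -> tuple[WindowedDataset, WindowedDataset, FeatureScaler]:
    """Full per-participant pipeline: split, label, normalize, window.

    The feature scaler is fitted on the participant's training days only
    and then applied to both halves, so no test-day statistic leaks into
    the transform.  Returns (train windows, test windows, scaler).
    """
    train_log, test_log = split_train_test(log_, split)
    scaler = FeatureScaler().fit(
        train_log.features(),
        day_range=(train_log.days[0].day_index, train_log.days[-1].day_index))
    tr = make_windows(scaler.transform(train_log.features()),
                      label_adherence(train_log, criterion), N,
                      log_.participant_id)
    te = make_windows(scaler.transform(test_log.features()),
                      label_adherence(test_log, criterion), N,
                      log_.participant_id)
    return tr, te, scaler
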