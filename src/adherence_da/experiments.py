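"""Three-arm experimental protocol, metrics, and significance tests.

For every participant in a cohort (the *target*), three models are
trained and evaluated on that participant's held-out 30 test days:

``no_source_no_da``
    only the target's own 30 training days;
``with_source_no_da``
    target plus same-cluster source participants' training windows,
    pooled directly;
``with_source_with_da``
    the same pooled data with adversarial domain adaptation.

Clusters come from K-means on GAF-image features, so sources share the
target's playing pattern.  In the cross-study protocol both cohorts are
clustered jointly but a target's sources must come from the *other*
study.  Per-arm precision/recall/F1/accuracy are averaged over
participants; paired differences are assessed with an exact sign test
and one-way repeated-measures ANOVA on the per-participant F1 scores.
"""

from __future__ import annotations

import dataclasses
import logging
import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .clustering import ClusterAssignment, cluster_participants, extract_features, source_pool
from .cohort import ParticipantLog
from .gaf import participant_gaf
from .models import (CNNConfig, DANNConfig, predict_adherence, train_baseline,
                     train_dann, train_pooled)
from .preprocessing import (AdherenceCriterion, SplitConfig, WindowedDataset,
                            participant_windows)

log = logging.getLogger(__name__)

__all__ = [
    "ARMS", "MetricSet", "ExperimentConfig", "ExperimentResult",
    "compute_metrics", "run_arm", "run_within_study", "run_cross_study",
    "sign_test", "repeated_measures_anova", "SignTestResult", "AnovaResult",
]

#: The three experimental arms, in increasing order of machinery.
ARMS = ("no_source_no_da", "with_source_no_da", "with_source_with_da")


@dataclass(frozen=True)
class MetricSet:
    """Accuracy, precision, recall and F1 with class 1 (adherent) positive."""

    accuracy: float
    precision: float
    recall: float
    f1: float
    undefined: frozenset = frozenset()  # metrics with a zero denominator

    def as_dict(self) -> dict[str, float]:
        return {"accuracy": self.accuracy, "precision": self.precision,
                "recall": self.recall, "f1": self.f1}


def compute_metrics(y_true: np.ndarray, y_pred: np.ndarray,
                    average: str = "binary") -> MetricSet:
    """Confusion-matrix metrics; zero-denominator cases score 0 and are flagged.

    ``average="binary"`` treats class 1 as positive; ``average="macro"``
    averages the per-class precision/recall/F1.
    """
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if len(y_true) == 0 or len(y_true) != len(y_pred):
        raise ValueError("labels must be nonempty and of equal length")

    def _prf(pos):
        tp = int(((y_true == pos) & (y_pred == pos)).sum())
        fp = int(((y_true != pos) & (y_pred == pos)).sum())
        fn = int(((y_true == pos) & (y_pred != pos)).sum())
        flags = set()
        if tp + fp == 0:
            precision = 0.0
            flags.add("precision")
        else:
            precision = tp / (tp + fp)
        if tp + fn == 0:
            recall = 0.0
            flags.add("recall")
        else:
            recall = tp / (tp + fn)
        f1 = 0.0 if precision + recall == 0 else 2 * precision * recall / (precision + recall)
        if precision + recall == 0:
            flags.add("f1")
        return precision, recall, f1, flags

    accuracy = float((y_true == y_pred).mean())
    if average == "binary":
        p, r, f, flags = _prf(1)
    elif average == "macro":
        p0, r0, f0, fl0 = _prf(0)
        p1, r1, f1_, fl1 = _prf(1)
        p, r, f, flags = (p0 + p1) / 2, (r0 + r1) / 2, (f0 + f1_) / 2, fl0 | fl1
    else:
        raise ValueError(f"unknown averaging mode {average!r}")
    return MetricSet(accuracy, float(p), float(r), float(f), frozenset(flags))


@dataclass(frozen=True)
class ExperimentConfig:
    """Everything needed to run the protocol on a cohort."""

    criterion: AdherenceCriterion = AdherenceCriterion()
    split: SplitConfig = SplitConfig()
    window_size: int = 7
    K: int = 4
    gaf_span: str = "full"
    extractor: str = "flatten-pca"
    pca_components: int = 16
    cnn: CNNConfig = field(default_factory=CNNConfig)
    dann: DANNConfig = field(default_factory=DANNConfig)
    metric_average: str = "binary"


@dataclass
class ArmRun:
    """One (target, arm) evaluation with the arrays needed for audits."""

    metrics: MetricSet
    y_true: np.ndarray
    y_pred: np.ndarray
    scores: np.ndarray
    n_source_windows: int
    scaler_day_range: tuple[int, int] | None
    fallback_to_baseline: bool


@dataclass
class ExperimentResult:
    """Per-participant and aggregated metrics for one protocol run."""

    protocol: str
    per_participant: dict[str, dict[str, MetricSet]]
    runs: dict[str, dict[str, ArmRun]]
    assignment: ClusterAssignment
    config: ExperimentConfig
    seed: int

    def metric_vector(self, arm: str, metric: str) -> np.ndarray:
        """One value per participant, in sorted participant order."""
        return np.array([getattr(self.per_participant[p][arm], metric)
                         for p in sorted(self.per_participant)])

    def aggregate(self) -> dict[str, dict[str, tuple[float, float]]]:
        """arm -> metric -> (mean, SD) across participants."""
        out: dict[str, dict[str, tuple[float, float]]] = {}
        for arm in ARMS:
            out[arm] = {}
            for m in ("accuracy", "precision", "recall", "f1"):
                v = self.metric_vector(arm, m)
                out[arm][m] = (float(v.mean()),
                               float(v.std(ddof=1)) if len(v) > 1 else 0.0)
        return out

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for pid in sorted(self.per_participant):
            for arm, ms in self.per_participant[pid].items():
                rows.append({"participant_id": pid, "arm": arm, **ms.as_dict()})
        return pd.DataFrame(rows)

    def summary(self, percent: bool = True) -> dict:
        """Table-style summary: arm x metric, mean (SD), optionally in %."""
        scale = 100.0 if percent else 1.0
        agg = self.aggregate()
        return {arm: {m: {"mean": round(mu * scale, 2), "sd": round(sd * scale, 2)}
                      for m, (mu, sd) in agg[arm].items()}
                for arm in ARMS}


def _target_seed(seed: int, pid: str) -> int:
    """Stable per-target training seed below 2**31 (process-independent)."""
    h = np.random.SeedSequence([seed, zlib.crc32(pid.encode())])
    return int(h.generate_state(1)[0] % (2**31))


def _prepare_sources(pool: list[str], logs: dict[str, ParticipantLog],
                     cfg: ExperimentConfig) -> WindowedDataset | None:
    parts = []
    for pid in pool:
        tr, _, _ = participant_windows(logs[pid], cfg.window_size,
                                       cfg.criterion, cfg.split)
        parts.append(tr.with_domain(1))
    if not parts:
        return None
    return WindowedDataset.concatenate(parts)


def run_arm(arm: str, target: str, assignment: ClusterAssignment,
            logs: dict[str, ParticipantLog], cfg: ExperimentConfig,
            seed: int | None = None,
            restrict_study: str | None = None) -> ArmRun:
    """Train one arm for one target and evaluate on its test windows.

    All arms for a target share the test windows and labels (the split,
    labeling and normalization are deterministic functions of the target
    log), and the per-arm training seed is shared so the arms differ only
    in the data and objective they train with.
    """
    if arm not in ARMS:
        raise ValueError(f"unknown arm {arm!r}")
    train_ds, test_ds, scaler = participant_windows(
        logs[target], cfg.window_size, cfg.criterion, cfg.split)
    run_seed = _target_seed(seed, target) if seed is not None else cfg.cnn.seed
    cnn_cfg = dataclasses.replace(cfg.cnn, seed=run_seed)

    source_ds = None
    if arm != "no_source_no_da":
        pool = source_pool(assignment, target, restrict_study=restrict_study)
        source_ds = _prepare_sources(pool, logs, cfg)

    fallback = arm != "no_source_no_da" and (source_ds is None or len(source_ds) == 0)
    if arm == "no_source_no_da":
        tm = train_baseline(train_ds, cnn_cfg)
    elif arm == "with_source_no_da":
        tm = train_pooled(train_ds, source_ds, cnn_cfg)
    else:
        dann_cfg = dataclasses.replace(cfg.dann, base=cnn_cfg)
        tm = train_dann(train_ds, source_ds, dann_cfg)

    y_pred, scores = predict_adherence(tm, test_ds)
    ms = compute_metrics(test_ds.y, y_pred, average=cfg.metric_average)
    return ArmRun(ms, test_ds.y.copy(), y_pred, scores,
                  0 if source_ds is None else len(source_ds),
                  scaler.fit_day_range, fallback)


def _cluster_cohort(logs: dict[str, ParticipantLog], cfg: ExperimentConfig,
                    seed: int) -> ClusterAssignment:
    mats = {pid: participant_gaf(lg, cfg.gaf_span, cfg.split)
            for pid, lg in logs.items()}
    feats = extract_features(mats, cfg.extractor, cfg.pca_components, seed=seed)
    study_ids = {pid: lg.study_id for pid, lg in logs.items()}
    return cluster_participants(feats, K=cfg.K, seed=seed, study_ids=study_ids)


def _run_protocol(logs: dict[str, ParticipantLog], cfg: ExperimentConfig,
                  seed: int, protocol: str) -> ExperimentResult:
    assignment = _cluster_cohort(logs, cfg, seed)
    per_participant: dict[str, dict[str, MetricSet]] = {}
    runs: dict[str, dict[str, ArmRun]] = {}
    for pid in sorted(logs):
        restrict = logs[pid].study_id if protocol == "cross_study" else None
        per_participant[pid] = {}
        runs[pid] = {}
        for arm in ARMS:
            ar = run_arm(arm, pid, assignment, logs, cfg, seed=seed,
                         restrict_study=restrict)
            per_participant[pid][arm] = ar.metrics
            runs[pid][arm] = ar
    return ExperimentResult(protocol, per_participant, runs, assignment, cfg, seed)


def run_within_study(logs: list[ParticipantLog] | dict[str, ParticipantLog],
                     cfg: ExperimentConfig = ExperimentConfig(),
                     seed: int = 0) -> ExperimentResult:
    """Cluster one cohort and run all three arms for every participant."""
    if not isinstance(logs, dict):
        logs = {lg.participant_id: lg for lg in logs}
    studies = {lg.study_id for lg in logs.values()}
    if len(studies) > 1:
        raise ValueError(f"within-study protocol expects one study_id, got {studies}")
    return _run_protocol(logs, cfg, seed, "within_study")


def run_cross_study(logs_a: list[ParticipantLog], logs_b: list[ParticipantLog],
                    cfg: ExperimentConfig = ExperimentConfig(),
                    seed: int = 0) -> ExperimentResult:
    """Joint clustering of two cohorts; sources restricted to the other study.

    No model is ever trained on the union of both cohorts as such: each
    target's model sees only its own training windows plus the
    other-study members of its cluster.
    """
    logs = {lg.participant_id: lg for lg in list(logs_a) + list(logs_b)}
    studies = {lg.study_id for lg in logs.values()}
    if len(studies) != 2:
        raise ValueError(f"cross-study protocol expects two study_ids, got {studies}")
    return _run_protocol(logs, cfg, seed, "cross_study")


@dataclass(frozen=True)
class SignTestResult:
    p_value: float
    n_effective: int
    n_positive: int
    all_ties: bool


def sign_test(paired_scores_a: np.ndarray,
              paired_scores_b: np.ndarray) -> SignTestResult:
    """Exact two-sided binomial sign test on paired scores; ties dropped."""
    a = np.asarray(paired_scores_a, dtype=float)
    b = np.asarray(paired_scores_b, dtype=float)
    if len(a) != len(b) or len(a) == 0:
        raise ValueError("paired score vectors must be nonempty and equal length")
    diff = a - b
    nz = diff[diff != 0]
    n = len(nz)
    if n == 0:
        return SignTestResult(1.0, 0, 0, True)
    n_pos = int((nz > 0).sum())
    p = stats.binomtest(n_pos, n, 0.5, alternative="two-sided").pvalue
    return SignTestResult(float(p), n, n_pos, False)


@dataclass(frozen=True)
class AnovaResult:
    F: float
    p_value: float
    df_condition: int
    df_error: int


def repeated_measures_anova(scores_by_condition: np.ndarray) -> AnovaResult:
    """One-way repeated-measures ANOVA from the sums-of-squares decomposition.

    Rows are participants (subjects, the blocking factor), columns are
    conditions; the matrix must be complete.  With two conditions the F
    statistic equals the squared paired t statistic.  No sphericity
    correction is applied.
    """
    M = np.asarray(scores_by_condition, dtype=float)
    if M.ndim != 2 or M.shape[0] < 2 or M.shape[1] < 2:
        raise ValueError("need a complete (participants x conditions) matrix, "
                         "at least 2x2")
    if not np.isfinite(M).all():
        raise ValueError("incomplete matrix: non-finite entries present")
    n, k = M.shape
    grand = M.mean()
    ss_cond = n * ((M.mean(axis=0) - grand) ** 2).sum()
    ss_subj = k * ((M.mean(axis=1) - grand) ** 2).sum()
    ss_total = ((M - grand) ** 2).sum()
    ss_err = ss_total - ss_cond - ss_subj
    df_cond = k - 1
    df_err = (n - 1) * (k - 1)
    ms_cond = ss_cond / df_cond
    ms_err = ss_err / df_err
    if ms_cond <= 1e-300:
        return AnovaResult(0.0, 1.0, df_cond, df_err)
    if ms_err <= 0:
        return AnovaResult(float("inf"), 0.0, df_cond, df_err)
    F = ms_cond / ms_err
    p = float(stats.f.sf(F, df_cond, df_err))
    return AnovaResult(float(F), p, df_cond, df_err)
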