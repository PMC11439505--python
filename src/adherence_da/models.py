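"""Per-participant adherence classifiers: 1D-CNN and its adversarial variant.

The base classifier is a small convolutional network over an N-day window
of the four daily play variables: two convolution + max-pooling blocks, a
flatten, a dense layer and a 2-class softmax output.  A separate model is
trained per participant on their first 30 days.

The domain-adversarial variant (DANN) augments the same feature extractor
(the layers before the flatten output of the dense trunk) with a second
head that classifies each window's domain (target participant vs source
participants).  The domain head is connected through a gradient-reversal
layer: identity in the forward pass, multiplication by ``-lambda`` in the
backward pass.  Minimizing the domain loss through the reversal trains
the extractor to *confuse* the domain classifier, driving the source and
target window representations toward a shared distribution so the
source participants' labeled windows transfer to the target.

Both heads see labeled windows: the target's 30 training days are labeled,
so the label loss runs over target and source windows alike (supervised
domain adaptation), while the domain loss runs over the same union with
domain tags.
"""

from __future__ import annotations

import copy
import logging
from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigurationError, ShapeError
from .nn import (Adam, Conv1D, Dense, Flatten, MaxPool1D, Param, ReLU,
                 Sequential, softmax, softmax_cross_entropy)
from .preprocessing import WindowedDataset

log = logging.getLogger(__name__)

__all__ = [
    "CNNConfig", "DANNConfig", "TrainedModel", "build_cnn",
    "train_baseline", "train_pooled", "train_dann", "predict_adherence",
    "grl_backward", "dann_objective_gradients",
]


@dataclass(frozen=True)
class CNNConfig:
    """Architecture and training hyperparameters of the base classifier.

    Defaults are sized to N=7 windows and ~23 training windows per
    participant: kernel 2, pool 2 and filters (8, 16) leave a single
    post-pooling position, i.e. the convolutional trunk summarizes the
    week into one 16-channel descriptor before the dense layer.
    """

    kernel_size: int = 2
    pool_size: int = 2
    filters: tuple[int, int] = (8, 16)
    dense_units: int = 16
    epochs: int = 200
    batch_size: int = 8
    learning_rate: float = 1e-3
    early_stop_patience: int = 20
    val_fraction: float = 0.2
    class_weighting: bool = False
    seed: int = 0


@dataclass(frozen=True)
class DANNConfig:
    """Adversarial-training hyperparameters on top of a base CNNConfig.

    ``lambda_`` weights the reversed domain gradient; ``lambda_schedule``
    is either "fixed" or "annealed" (ramp 2/(1+exp(-10 p)) - 1 over
    training progress p, scaled by ``lambda_``).  ``source_weight`` is the
    relative weight of source windows in the label loss.
    """

    base: CNNConfig = field(default_factory=CNNConfig)
    lambda_: float = 1.0
    lambda_schedule: str = "fixed"
    domain_head_units: int = 8
    source_weight: float = 1.0

    def __post_init__(self):
        if self.lambda_ < 0:
            raise ConfigurationError("lambda_ must be >= 0")
        if self.lambda_schedule not in ("fixed", "annealed"):
            raise ConfigurationError(
                f"unknown lambda_schedule {self.lambda_schedule!r}")


class AdherenceCNN:
    """Feature extractor + label head (+ optional domain head)."""

    def __init__(self, extractor: Sequential, label_head: Sequential,
                 domain_head: Sequential | None, input_shape: tuple):
        self.extractor = extractor
        self.label_head = label_head
        self.domain_head = domain_head
        self.input_shape = input_shape  # (N, n_features)

    def params(self) -> list[Param]:
        ps = self.extractor.params() + self.label_head.params()
        if self.domain_head is not None:
            ps += self.domain_head.params()
        return ps

    def logits(self, X: np.ndarray) -> np.ndarray:
        return self.label_head.forward(self.extractor.forward(X))


@dataclass
class TrainedModel:
    """A fitted classifier with its config and training history."""

    model: AdherenceCNN
    config: CNNConfig | DANNConfig
    history: dict[str, list[float]]
    best_epoch: int
    arm: str = "baseline"


def grl_backward(upstream_gradient: np.ndarray, lambda_: float) -> np.ndarray:
    """Gradient-reversal layer backward rule: ``-lambda * upstream``.

    (The forward pass is the identity, so it needs no function.)
    """
    if lambda_ < 0:
        raise ConfigurationError("lambda_ must be >= 0")
    return -lambda_ * np.asarray(upstream_gradient)


def build_cnn(cfg: CNNConfig, N: int, n_features: int = 4,
              with_domain_head: bool = False,
              domain_head_units: int = 8) -> AdherenceCNN:
    """Construct the (untrained) network and validate its shapes for N.

    The architecture is conv -> maxpool -> conv -> maxpool -> flatten ->
    dense -> 2-unit output; with a domain head, a parallel dense -> 2-unit
    branch reads the same flattened features.  Initialization is fully
    determined by ``cfg.seed``; the optional domain head draws from its
    own seed stream so its presence never perturbs the base network's
    initial weights.
    """
    root = np.random.SeedSequence(cfg.seed)
    ss_ext, ss_label, ss_domain, _ = root.spawn(4)
    r_ext = np.random.default_rng(ss_ext)
    f1, f2 = cfg.filters
    extractor = Sequential([
        Conv1D(n_features, f1, cfg.kernel_size, r_ext, name="conv1"),
        ReLU(),
        MaxPool1D(cfg.pool_size, name="pool1"),
        Conv1D(f1, f2, cfg.kernel_size, r_ext, name="conv2"),
        ReLU(),
        MaxPool1D(cfg.pool_size, name="pool2"),
        Flatten(),
    ])
    feat_shape = extractor.out_shape((1, N, n_features))  # raises ShapeError if N too small
    feat_dim = feat_shape[1]
    r_label = np.random.default_rng(ss_label)
    label_head = Sequential([
        Dense(feat_dim, cfg.dense_units, r_label, name="dense"),
        ReLU(),
        Dense(cfg.dense_units, 2, r_label, name="output"),
    ])
    domain_head = None
    if with_domain_head:
        r_dom = np.random.default_rng(ss_domain)
        domain_head = Sequential([
            Dense(feat_dim, domain_head_units, r_dom, name="domain_dense"),
            ReLU(),
            Dense(domain_head_units, 2, r_dom, name="domain_output"),
        ])
    return AdherenceCNN(extractor, label_head, domain_head, (N, n_features))


def dann_objective_gradients(model: AdherenceCNN, X: np.ndarray, y: np.ndarray,
                             w: np.ndarray | None, d: np.ndarray | None,
                             lam: float,
                             domain_weight: np.ndarray | None = None
                             ) -> tuple[float, float]:
    """One forward/backward pass of the joint adversarial objective.

    Accumulates into each parameter's ``grad``: the label head receives
    d(label CE)/d(theta), the domain head d(domain CE)/d(theta), and the
    shared extractor d(label CE - lambda * domain CE)/d(theta) -- the
    gradient-reversal rule.  ``domain_weight`` optionally weights the
    domain cross-entropy per sample (used to balance the two domains when
    source windows heavily outnumber the target's).  Returns (label loss,
    domain loss); the domain loss is NaN for a model without a domain head.
    """
    z = model.extractor.forward(X)
    logits = model.label_head.forward(z)
    loss, glogits = softmax_cross_entropy(logits, y, w)
    gz = model.label_head.backward(glogits)
    dloss = float("nan")
    if model.domain_head is not None:
        dlogits = model.domain_head.forward(z)
        dloss, gdlogits = softmax_cross_entropy(dlogits, d, domain_weight)
        gz_dom = model.domain_head.backward(gdlogits)
        if lam != 0.0:
            gz = gz + grl_backward(gz_dom, lam)
    model.extractor.backward(gz)
    return loss, dloss


def _chronological_val_split(ds: WindowedDataset, val_fraction: float
                             ) -> tuple[WindowedDataset, WindowedDataset]:
    """Final ``val_fraction`` of the target's training windows, in time order."""
    n = len(ds)
    if n < 2:
        raise ValueError("need at least 2 target training windows")
    n_val = min(max(1, int(round(val_fraction * n))), n - 1)
    cut = n - n_val
    return (WindowedDataset(ds.X[:cut], ds.y[:cut]),
            WindowedDataset(ds.X[cut:], ds.y[cut:]))


def _class_weights(y: np.ndarray) -> np.ndarray:
    w = np.ones(2)
    for c in (0, 1):
        n_c = int((y == c).sum())
        if n_c > 0:
            w[c] = len(y) / (2.0 * n_c)
    return w


def _fit(target_train: WindowedDataset, source_train: WindowedDataset | None,
         cfg: CNNConfig, dann: DANNConfig | None, arm: str) -> TrainedModel:
    """Shared training loop for all three arms.

    The RNG seed streams (weight init, batch shuffling) are identical
    across arms for a given seed, and with ``lambda_ = 0`` the reversed
    domain gradient into the shared extractor is exactly zero, so the
    pooled and adversarial arms then produce identical per-epoch label
    losses by construction.
    """
    N, n_feat = target_train.X.shape[1], target_train.X.shape[2]
    tr_t, val = _chronological_val_split(target_train, cfg.val_fraction)

    use_domain = dann is not None
    model = build_cnn(cfg, N, n_feat, with_domain_head=use_domain,
                      domain_head_units=dann.domain_head_units if use_domain else 8)

    X = tr_t.X
    y = tr_t.y
    w = np.ones(len(y))
    d = np.zeros(len(y), dtype=np.int64)
    if source_train is not None and len(source_train) > 0:
        sw = dann.source_weight if use_domain else 1.0
        X = np.concatenate([X, source_train.X])
        y = np.concatenate([y, source_train.y])
        w = np.concatenate([w, np.full(len(source_train), sw)])
        d = np.concatenate([d, np.ones(len(source_train), dtype=np.int64)])
    if len(np.unique(y)) < 2:
        log.warning("single-class training labels; model may be a constant predictor")
    if cfg.class_weighting:
        w = w * _class_weights(y)[y]
    # balance the adversarial game: source windows typically outnumber the
    # target's ~10:1, and an unweighted domain loss is then dominated by the
    # trivial always-source prediction
    dom_w = None
    if use_domain:
        counts = np.bincount(d, minlength=2)
        per_domain = np.where(counts > 0, len(d) / (2.0 * np.maximum(counts, 1)), 0.0)
        dom_w = per_domain[d]

    # seed stream 3 of the model's root sequence drives batch order, so the
    # order is shared across arms under a common seed
    shuffle_rng = np.random.default_rng(np.random.SeedSequence(cfg.seed).spawn(4)[3])
    opt = Adam(model.params(), lr=cfg.learning_rate)

    n = len(y)
    history: dict[str, list[float]] = {"train_loss": [], "val_loss": [],
                                       "domain_loss": []}
    best_val = np.inf
    best_epoch = -1
    best_params: list[np.ndarray] | None = None
    patience_left = cfg.early_stop_patience

    for epoch in range(cfg.epochs):
        if dann is not None:
            if dann.lambda_schedule == "annealed":
                p = epoch / max(cfg.epochs - 1, 1)
                lam = dann.lambda_ * (2.0 / (1.0 + np.exp(-10.0 * p)) - 1.0)
            else:
                lam = dann.lambda_
        perm = shuffle_rng.permutation(n)
        ep_loss = 0.0
        ep_dom = 0.0
        ep_n = 0
        for start in range(0, n, cfg.batch_size):
            idx = perm[start:start + cfg.batch_size]
            opt.zero_grad()
            loss, dloss = dann_objective_gradients(
                model, X[idx], y[idx], w[idx], d[idx],
                lam if use_domain else 0.0,
                domain_weight=dom_w[idx] if dom_w is not None else None)
            if use_domain:
                ep_dom += dloss * len(idx)
            opt.step()
            ep_loss += loss * len(idx)
            ep_n += len(idx)
        history["train_loss"].append(ep_loss / ep_n)
        history["domain_loss"].append(ep_dom / ep_n if use_domain else float("nan"))

        val_logits = model.logits(val.X)
        val_loss, _ = softmax_cross_entropy(val_logits, val.y)
        history["val_loss"].append(val_loss)

        if val_loss < best_val - 1e-12:
            best_val = val_loss
            best_epoch = epoch
            best_params = [p_.value.copy() for p_ in model.params()]
            patience_left = cfg.early_stop_patience
        else:
            patience_left -= 1
            if patience_left <= 0:
                break

    if best_params is not None:
        for p_, v in zip(model.params(), best_params):
            p_.value[...] = v
    return TrainedModel(model, dann if dann is not None else cfg,
                        history, best_epoch, arm=arm)


def train_baseline(target_train: WindowedDataset,
                   cfg: CNNConfig = CNNConfig()) -> TrainedModel:
    """Train on the target participant's own training windows only."""
    return _fit(target_train, None, cfg, None, arm="no_source_no_da")


def train_pooled(target_train: WindowedDataset,
                 source_train: WindowedDataset | None,
                 cfg: CNNConfig = CNNConfig()) -> TrainedModel:
    """Train on the union of target and same-cluster source windows,
    without any adaptation.  An empty source pool degrades to the
    baseline arm (with a warning)."""
    if source_train is None or len(source_train) == 0:
        log.warning("empty source pool: pooled arm degrades to baseline")
        tm = _fit(target_train, None, cfg, None, arm="with_source_no_da")
        return tm
    return _fit(target_train, source_train, cfg, None, arm="with_source_no_da")


def train_dann(target_train: WindowedDataset,
               source_train: WindowedDataset | None,
               cfg: DANNConfig = DANNConfig()) -> TrainedModel:
    """Adversarial domain adaptation from same-cluster source windows.

    Label cross-entropy is minimized on target + source windows while the
    domain head, fed through the gradient-reversal layer, pushes the
    extractor toward domain-invariant features.  The checkpoint with the
    best target-validation label loss is returned.
    """
    if source_train is None or len(source_train) == 0:
        log.warning("empty source pool: adversarial arm degrades to baseline")
        return _fit(target_train, None, cfg.base, None, arm="with_source_with_da")
    if source_train.domain is None:
        source_train = source_train.with_domain(1)
    tm = _fit(target_train, source_train, cfg.base, cfg, arm="with_source_with_da")
    return tm


def predict_adherence(trained: TrainedModel, windows: WindowedDataset
                      ) -> tuple[np.ndarray, np.ndarray]:
    """Predicted class (argmax; tie breaks to class 0) and class-1 scores."""
    expected = trained.model.input_shape
    got = windows.X.shape[1:]
    if tuple(got) != tuple(expected):
        raise ShapeError(f"window shape {got} does not match model input {expected}")
    probs = softmax(trained.model.logits(windows.X))
    return probs.argmax(axis=1), probs[:, 1]
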