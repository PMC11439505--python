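"""CNN/DANN engine: convolution, shapes, gradients, training contracts."""

import dataclasses

import numpy as np
import pytest

import adherence_da as ad
from adherence_da.errors import ShapeError
from adherence_da.models import build_cnn, dann_objective_gradients
from adherence_da.nn import softmax_cross_entropy
from adherence_da.preprocessing import WindowedDataset


# ---------------------------------------------------------------- convolve1d

def brute_force_convolution(f, g):
    """Direct evaluation of the sliding sum sum_j g(j) f(i-j+m/2) with the
    kernel sliding from the start of the series to its end (1-based,
    centered index resolved by floor; valid positions only)."""
    n, m = len(f), len(g)
    out = []
    half = m // 2
    for i in range(1, n + 2):  # scan candidate centers, keep fully valid ones
        vals = []
        ok = True
        for j in range(1, m + 1):
            idx = i - j + half  # 1-based position into f
            if not (1 <= idx <= n):
                ok = False
                break
            vals.append(g[j - 1] * f[idx - 1])
        if ok:
            out.append(sum(vals))
    return np.array(out)


@pytest.mark.parametrize("f,g,expected", [
    ([1, 2, 3, 4], [1], [1, 2, 3, 4]),
    ([1, 2, 3], [1, 1], [3, 5]),
    ([0, 0, 0, 0], [2, 5], [0, 0, 0]),
])
def test_convolve1d_examples(f, g, expected):
    np.testing.assert_allclose(ad.convolve1d(f, g), expected)


@pytest.mark.parametrize("seed", range(5))
def test_convolve1d_matches_brute_force(seed):
    rng = np.random.default_rng(seed)
    f = rng.normal(size=rng.integers(5, 20))
    g = rng.normal(size=rng.integers(1, 5))
    np.testing.assert_allclose(ad.convolve1d(f, g),
                               brute_force_convolution(list(f), list(g)),
                               atol=1e-12)


def test_convolve1d_kernel_longer_than_input():
    with pytest.raises(ValueError):
        ad.convolve1d([1, 2], [1, 2, 3])


# ------------------------------------------------------------- architecture

def test_build_cnn_shape_arithmetic_n7():
    # floor(( floor((7-2+1)/2) - 2 + 1 ) / 2) = 1 position after block 2
    model = build_cnn(ad.CNNConfig(), N=7)
    assert model.extractor.out_shape((1, 7, 4)) == (1, 16)


def test_build_cnn_too_small_window_names_layer():
    with pytest.raises(ShapeError, match="conv2|pool2"):
        build_cnn(ad.CNNConfig(), N=3)


def test_build_cnn_seeded_init_reproducible():
    m1 = build_cnn(ad.CNNConfig(seed=3), N=7)
    m2 = build_cnn(ad.CNNConfig(seed=3), N=7)
    for p1, p2 in zip(m1.params(), m2.params()):
        np.testing.assert_array_equal(p1.value, p2.value)
    m3 = build_cnn(ad.CNNConfig(seed=4), N=7)
    assert any(not np.array_equal(p1.value, p3.value)
               for p1, p3 in zip(m1.params(), m3.params()))


def test_domain_head_does_not_perturb_base_init():
    plain = build_cnn(ad.CNNConfig(seed=5), N=7)
    with_dom = build_cnn(ad.CNNConfig(seed=5), N=7, with_domain_head=True)
    n_base = len(plain.params())
    for p1, p2 in zip(plain.params(), with_dom.params()[:n_base]):
        np.testing.assert_array_equal(p1.value, p2.value)


# ------------------------------------------------------------------ GRL

def test_grl_backward_rules():
    g = np.array([1.0, -2.0, 3.0])
    np.testing.assert_array_equal(ad.grl_backward(g, 1.0), -g)
    np.testing.assert_array_equal(ad.grl_backward(g, 0.0), np.zeros(3))
    np.testing.assert_allclose(ad.grl_backward(g, 0.5), -0.5 * g)


def test_dann_gradients_match_finite_differences():
    """Measured gradient of the adversarial objective vs analytic backprop.

    The extractor's analytic gradient must equal the finite-difference
    gradient of (label CE - lambda * domain CE); the label head's that of
    the label CE; the domain head's that of the domain CE.
    """
    rng = np.random.default_rng(0)
    lam = 0.7
    X = rng.normal(size=(6, 7, 4))
    y = rng.integers(0, 2, size=6)
    d = np.array([0, 0, 0, 1, 1, 1])
    w = np.ones(6)
    model = build_cnn(ad.CNNConfig(filters=(3, 4), dense_units=5, seed=1),
                      N=7, with_domain_head=True, domain_head_units=3)

    def losses():
        z = model.extractor.forward(X)
        l_lab, _ = softmax_cross_entropy(model.label_head.forward(z), y, w)
        l_dom, _ = softmax_cross_entropy(model.domain_head.forward(z), d)
        return l_lab, l_dom

    for p in model.params():
        p.grad[...] = 0.0
    dann_objective_gradients(model, X, y, w, d, lam)

    n_ext = len(model.extractor.params())
    n_lab = len(model.label_head.params())
    eps = 1e-6
    for pi, p in enumerate(model.params()):
        flat = p.value.ravel()
        for j in rng.choice(flat.size, size=min(4, flat.size), replace=False):
            orig = flat[j]
            flat[j] = orig + eps
            lab_p, dom_p = losses()
            flat[j] = orig - eps
            lab_m, dom_m = losses()
            flat[j] = orig
            if pi < n_ext:
                expected = ((lab_p - lab_m) - lam * (dom_p - dom_m)) / (2 * eps)
            elif pi < n_ext + n_lab:
                expected = (lab_p - lab_m) / (2 * eps)
            else:
                expected = (dom_p - dom_m) / (2 * eps)
            assert p.grad.ravel()[j] == pytest.approx(expected, abs=1e-5)


# ------------------------------------------------------------- training

def _separable_windows(n, seed, N=7):
    """Windows whose mean first-feature (duration) level determines the label.

    A window-average signal suits the conv+pool trunk, which summarizes
    the window translation-invariantly before classification.
    """
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n, N, 4))
    y = rng.integers(0, 2, size=n)
    X[:, :, 0] += np.where(y == 1, 1.2, -1.2)[:, None]
    return WindowedDataset(X, y)


def test_training_learns_separable_data(fast_cnn_cfg):
    cfg = dataclasses.replace(fast_cnn_cfg, epochs=60, early_stop_patience=60)
    train = _separable_windows(80, seed=0)
    tm = ad.train_baseline(train, cfg)
    pred_tr, _ = ad.predict_adherence(tm, train)
    assert (pred_tr == train.y).mean() >= 0.95
    held_out = _separable_windows(50, seed=1)
    pred_te, _ = ad.predict_adherence(tm, held_out)
    assert (pred_te == held_out.y).mean() >= 0.9


def test_single_class_labels_yield_constant_predictor(fast_cnn_cfg):
    train = _separable_windows(20, seed=2)
    train = WindowedDataset(train.X, np.zeros(len(train), dtype=int))
    tm = ad.train_baseline(train, fast_cnn_cfg)
    pred, _ = ad.predict_adherence(tm, train)
    assert (pred == 0).all()


def test_training_is_deterministic(target_and_sources, fast_cnn_cfg):
    tr, _, _ = target_and_sources
    h1 = ad.train_baseline(tr, fast_cnn_cfg).history
    h2 = ad.train_baseline(tr, fast_cnn_cfg).history
    assert h1["val_loss"] == h2["val_loss"]
    assert h1["train_loss"] == h2["train_loss"]


def test_empty_source_pooled_equals_baseline(target_and_sources, fast_cnn_cfg):
    tr, _, _ = target_and_sources
    tb = ad.train_baseline(tr, fast_cnn_cfg)
    tp = ad.train_pooled(tr, None, fast_cnn_cfg)
    assert tb.history["train_loss"] == tp.history["train_loss"]
    assert tb.history["val_loss"] == tp.history["val_loss"]


def test_lambda_zero_reduces_dann_to_pooled(target_and_sources, fast_cnn_cfg):
    """With lambda=0 the reversed gradient vanishes, so the label-training
    trajectory of the adversarial arm matches pooled training exactly."""
    tr, _, src = target_and_sources
    tp = ad.train_pooled(tr, src, fast_cnn_cfg)
    td = ad.train_dann(tr, src, ad.DANNConfig(base=fast_cnn_cfg, lambda_=0.0))
    assert td.history["train_loss"] == tp.history["train_loss"]
    assert td.history["val_loss"] == tp.history["val_loss"]


def test_dann_with_positive_lambda_diverges_from_pooled(target_and_sources,
                                                        fast_cnn_cfg):
    tr, _, src = target_and_sources
    tp = ad.train_pooled(tr, src, fast_cnn_cfg)
    td = ad.train_dann(tr, src, ad.DANNConfig(base=fast_cnn_cfg, lambda_=1.0))
    assert td.history["train_loss"] != tp.history["train_loss"]


def test_same_distribution_sources_help_on_average(fast_cnn_cfg):
    """Pooling sources drawn from the target's own distribution should not
    hurt test accuracy, on average over seeds; inverted-label sources
    should do worse than same-distribution ones."""
    diffs, inv_diffs = [], []
    for seed in range(10):
        cfg = dataclasses.replace(fast_cnn_cfg, seed=seed)
        target_tr = _separable_windows(25, seed=100 + seed)
        test = _separable_windows(40, seed=200 + seed)
        src = _separable_windows(120, seed=300 + seed)
        src_inv = WindowedDataset(src.X, 1 - src.y)
        base = ad.train_baseline(target_tr, cfg)
        pooled = ad.train_pooled(target_tr, src.with_domain(1), cfg)
        pooled_inv = ad.train_pooled(target_tr, src_inv.with_domain(1), cfg)
        acc = {}
        for name, tm in [("b", base), ("p", pooled), ("i", pooled_inv)]:
            pred, _ = ad.predict_adherence(tm, test)
            acc[name] = (pred == test.y).mean()
        diffs.append(acc["p"] - acc["b"])
        inv_diffs.append(acc["i"] - acc["p"])
    assert np.mean(diffs) >= 0.0
    assert np.mean(inv_diffs) < 0.0


def test_domain_invariance_probe(target_and_sources, fast_cnn_cfg):
    """A domain probe refit on frozen features should be closer to chance
    for adversarially trained features than for pooled features."""
    from sklearn.linear_model import LogisticRegression
    tr, _, src = target_and_sources
    tp = ad.train_pooled(tr, src, fast_cnn_cfg)
    td = ad.train_dann(tr, src, ad.DANNConfig(base=fast_cnn_cfg, lambda_=2.0))
    X = np.concatenate([tr.X, src.X])
    dom = np.concatenate([np.zeros(len(tr)), np.ones(len(src))])

    def probe_acc(tm):
        Z = tm.model.extractor.forward(X)
        clf = LogisticRegression(max_iter=2000).fit(Z, dom)
        return clf.score(Z, dom)

    chance = max(dom.mean(), 1 - dom.mean())
    assert abs(probe_acc(td) - chance) <= abs(probe_acc(tp) - chance) + 0.05


def test_predict_argmax_consistency_and_shape_check(target_and_sources,
                                                    fast_cnn_cfg):
    tr, te, _ = target_and_sources
    tm = ad.train_baseline(tr, fast_cnn_cfg)
    pred, scores = ad.predict_adherence(tm, te)
    np.testing.assert_array_equal(pred, (scores > 0.5).astype(int))
    bad = WindowedDataset(np.zeros((3, 5, 4)), np.zeros(3, dtype=int))
    with pytest.raises(ShapeError):
        ad.predict_adherence(tm, bad)
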