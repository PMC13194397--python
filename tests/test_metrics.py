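"""Faithfulness and validation metrics."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from acamspeech.metrics import (FaithfulnessConfig, adcc, adcc_composite,
                                baseline_map, binarize_map,
                                deletion_insertion, frame_iou_dice,
                                group_stats, make_baseline, spearman)


class LinearStub:
    """f = softmax(W @ sum over a fixed per-class weighting of bins)."""

    def __init__(self, shape, n_classes=3, seed=0):
        rng = np.random.default_rng(seed)
        self.w = rng.normal(size=(n_classes,) + shape)

    def predict_proba(self, x, severity):
        scores = (self.w * x[None]).sum(axis=(1, 2))
        e = np.exp(scores - scores.max())
        return e / e.sum()


# ---------------------------------------------------------------------------
# deletion / insertion
# ---------------------------------------------------------------------------

def test_curve_endpoint_identities():
    stub = LinearStub((4, 4))
    rng = np.random.default_rng(1)
    x = rng.normal(size=(4, 4))
    rel = rng.normal(size=(4, 4))
    cfg = FaithfulnessConfig(n_steps=4)
    B = make_baseline(x, cfg.baseline)
    dele, ins = deletion_insertion(stub, x, 50.0, rel, 1, cfg)
    f_x = stub.predict_proba(x, 50.0)[1]
    f_b = stub.predict_proba(B, 50.0)[1]
    assert dele.probabilities[0] == pytest.approx(f_x)
    assert dele.probabilities[-1] == pytest.approx(f_b)
    assert ins.probabilities[0] == pytest.approx(f_b)
    assert ins.probabilities[-1] == pytest.approx(f_x)
    assert 0.0 <= dele.aupc <= 1.0
    assert 0.0 <= ins.aupc <= 1.0


def test_curves_match_a_brute_force_enumeration():
    """Independent oracle: rank the 16 bins by (relevance, -index), build
    each step's mask exhaustively, query the stub directly."""
    stub = LinearStub((4, 4), seed=3)
    rng = np.random.default_rng(5)
    x = rng.normal(size=(4, 4))
    rel = rng.normal(size=(4, 4))
    rel.ravel()[3] = rel.ravel()[7]  # force a tie for the tie-break rule
    cfg = FaithfulnessConfig(n_steps=8, baseline="zeros")
    dele, ins = deletion_insertion(stub, x, 0.0, rel, 2, cfg)

    flat = rel.ravel()
    order = sorted(range(16), key=lambda i: (-flat[i], i))
    for k in range(cfg.n_steps + 1):
        n_top = int(round(16 * k / cfg.n_steps))
        top = set(order[:n_top])
        x_del = np.array([0.0 if i in top else x.ravel()[i]
                          for i in range(16)]).reshape(4, 4)
        x_ins = np.array([x.ravel()[i] if i in top else 0.0
                          for i in range(16)]).reshape(4, 4)
        assert dele.probabilities[k] == pytest.approx(
            stub.predict_proba(x_del, 0.0)[2], abs=1e-12)
        assert ins.probabilities[k] == pytest.approx(
            stub.predict_proba(x_ins, 0.0)[2], abs=1e-12)


def test_uniform_relevance_is_deterministic():
    stub = LinearStub((3, 3))
    x = np.arange(9.0).reshape(3, 3)
    rel = np.ones((3, 3))
    a = deletion_insertion(stub, x, 0.0, rel, 0)
    b = deletion_insertion(stub, x, 0.0, rel, 0)
    assert np.array_equal(a[0].probabilities, b[0].probabilities)
    assert np.array_equal(a[1].probabilities, b[1].probabilities)


def test_grid_mismatch_rejected():
    stub = LinearStub((3, 3))
    with pytest.raises(ValueError, match="grid"):
        deletion_insertion(stub, np.zeros((3, 3)), 0.0, np.zeros((2, 3)), 0)


# ---------------------------------------------------------------------------
# ADCC
# ---------------------------------------------------------------------------

def test_adcc_composite_closed_forms():
    assert adcc_composite(1.0, 0.0, 0.0) == pytest.approx(1.0)
    assert adcc_composite(0.5, 0.5, 0.5) == pytest.approx(0.5)
    expect = 3.0 / (1 / 0.8 + 1 / 0.8 + 1 / 0.9)
    assert adcc_composite(0.8, 0.2, 0.1) == pytest.approx(expect)
    assert adcc_composite(0.0, 0.2, 0.1) == 0.0


def test_adcc_components_are_bounded():
    stub = LinearStub((4, 4), seed=2)
    rng = np.random.default_rng(9)
    x = rng.normal(size=(4, 4))
    m = rng.uniform(size=(4, 4))
    rep = adcc(stub, x, 0.0, m, 1)
    for v in (rep.average_drop, rep.coherency, rep.complexity, rep.adcc):
        assert 0.0 <= v <= 1.0
    assert rep.adcc == pytest.approx(adcc_composite(
        rep.coherency, rep.complexity, rep.average_drop))


def test_adcc_rejects_out_of_range_display_map():
    stub = LinearStub((2, 2))
    with pytest.raises(ValueError, match=r"\[0, 1\]"):
        adcc(stub, np.zeros((2, 2)), 0.0, np.full((2, 2), 1.5), 0)


# ---------------------------------------------------------------------------
# binarization
# ---------------------------------------------------------------------------

def test_mean_binarization_examples():
    assert np.array_equal(binarize_map(np.array([0., 0., 1., 1.])),
                          [0, 0, 1, 1])
    assert not binarize_map(np.full(5, 0.3)).any()  # strict inequality


def test_otsu_splits_a_bimodal_map():
    v = np.concatenate([np.full(50, 0.1), np.full(50, 0.9)])
    mask = binarize_map(v, method="otsu")
    assert mask.sum() == 50
    assert mask[50:].all()
    # exhaustive sweep oracle: the chosen split maximizes between-class
    # variance over all candidate thresholds
    def between_var(thr):
        lo, hi = v[v <= thr], v[v > thr]
        if len(lo) == 0 or len(hi) == 0:
            return 0.0
        w0, w1 = len(lo) / len(v), len(hi) / len(v)
        return w0 * w1 * (lo.mean() - hi.mean()) ** 2
    best = max(np.linspace(0, 1, 400), key=between_var)
    assert 0.1 < best < 0.9


def test_otsu_on_constant_map_warns_and_zeroes():
    with pytest.warns(UserWarning, match="constant"):
        mask = binarize_map(np.full(10, 0.4), method="otsu")
    assert not mask.any()


# ---------------------------------------------------------------------------
# IoU / Dice
# ---------------------------------------------------------------------------

def test_iou_dice_examples():
    a = np.zeros(20, dtype=int); a[0:10] = 1
    b = np.zeros(20, dtype=int); b[5:15] = 1
    iou, dice = frame_iou_dice(a, b)
    assert iou == pytest.approx(1 / 3)
    assert dice == pytest.approx(0.5)
    assert frame_iou_dice(a, a) == (1.0, 1.0)
    c = np.zeros(20, dtype=int); c[15:] = 1
    assert frame_iou_dice(a, c) == (0.0, 0.0)
    assert frame_iou_dice(np.zeros(5), np.zeros(5)) == (1.0, 1.0)


@settings(max_examples=100, deadline=None, derandomize=True)
@given(st.lists(st.booleans(), min_size=1, max_size=40),
       st.data())
def test_dice_is_a_monotone_function_of_iou(a, data):
    b = data.draw(st.lists(st.booleans(), min_size=len(a), max_size=len(a)))
    iou, dice = frame_iou_dice(np.array(a), np.array(b))
    assert dice == pytest.approx(2 * iou / (1 + iou))
    assert iou <= dice + 1e-12


def test_iou_rejects_length_mismatch():
    with pytest.raises(ValueError, match="shapes"):
        frame_iou_dice(np.zeros(3), np.zeros(4))


# ---------------------------------------------------------------------------
# group statistics
# ---------------------------------------------------------------------------

def test_identical_groups_have_zero_effect():
    gs = group_stats([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
    assert gs.cohens_d == 0.0
    assert gs.activation_ratio == pytest.approx(1.0)


def test_disjoint_groups_rank_sum():
    gs = group_stats([1.0, 2.0, 3.0], [4.0, 5.0, 6.0])
    assert gs.u_statistic == 0.0   # no a-value exceeds any b-value
    assert gs.cohens_d < 0


def test_location_shift_moves_d_by_its_pooled_sd_multiple():
    rng = np.random.default_rng(3)
    a = rng.normal(size=30)
    b = rng.normal(size=25)
    base = group_stats(a, b)
    shifted = group_stats(a + 1.0, b)
    na, nb = len(a), len(b)
    pooled = np.sqrt(((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1))
                     / (na + nb - 2))
    assert shifted.cohens_d - base.cohens_d == pytest.approx(1.0 / pooled)


def test_groups_need_two_values_each():
    with pytest.raises(ValueError, match="n >= 2"):
        group_stats([1.0], [2.0, 3.0])


# ---------------------------------------------------------------------------
# Spearman
# ---------------------------------------------------------------------------

def test_spearman_perfect_correlations():
    x = [1.0, 2.0, 3.0, 4.0]
    assert spearman(x, x)[0] == pytest.approx(1.0)
    assert spearman(x, [-v for v in x])[0] == pytest.approx(-1.0)


def test_spearman_matches_the_rank_formula():
    x = [3.0, 1.0, 4.0, 1.5, 5.0]
    y = [2.0, 0.5, 1.0, 3.0, 4.0]
    rho, _ = spearman(x, y)
    rx = np.argsort(np.argsort(x))
    ry = np.argsort(np.argsort(y))
    d2 = np.sum((rx - ry) ** 2)
    n = 5
    assert rho == pytest.approx(1 - 6 * d2 / (n * (n ** 2 - 1)))


def test_spearman_rejects_constant_input():
    with pytest.raises(ValueError, match="constant"):
        spearman([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


# ---------------------------------------------------------------------------
# baseline maps
# ---------------------------------------------------------------------------

def test_energy_baselines_on_silence():
    silence = 0.0005 * np.random.default_rng(0).standard_normal(16_000)
    e = baseline_map("energy", waveform=silence, n_frames=100, n_mels=8)
    inv = baseline_map("inverted-energy", waveform=silence, n_frames=100,
                       n_mels=8)
    assert e.max() < 0.01
    assert inv.min() > 0.99


def test_random_baseline_shuffle_invariance_and_determinism(rng):
    const = np.full((20, 4), 1.3)
    out = baseline_map("random", reference_map=const,
                       rng=np.random.default_rng(5), n_trials=3)
    assert np.allclose(out, 1.3)
    ref = rng.normal(size=(20, 4))
    a = baseline_map("random", reference_map=ref,
                     rng=np.random.default_rng(8), n_trials=5)
    b = baseline_map("random", reference_map=ref,
                     rng=np.random.default_rng(8), n_trials=5)
    assert np.array_equal(a, b)
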