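"""Attribution core: perturbation, normalization, filtering, segmentation,
aggregation, end-to-end identities."""

import dataclasses

import numpy as np
import pytest

from acamspeech import acam
from acamspeech.acam import (PerturbationConfig, SegmentConfig,
                             accumulate_gradients, aggregate_cams,
                             dual_filter, gate_with_filter,
                             gradcam_baseline, normalize_gradients,
                             segment_cam, segment_cam_banded, segment_indices,
                             segment_weights)

EPS = 1e-5


@pytest.fixture(scope="module")
def setup(tiny_model, clean_utterance):
    x = tiny_model.input_features(clean_utterance.waveform)
    return tiny_model, clean_utterance, x


# ---------------------------------------------------------------------------
# gradient accumulation
# ---------------------------------------------------------------------------

def test_zero_perturbations_reduce_to_the_base_gradient(setup):
    model, utt, x = setup
    cfg = PerturbationConfig(n_perturbations=0)
    g_dyn, traces = accumulate_gradients(model, x, utt.severity, 2, cfg)
    base = model.class_gradient(x, utt.severity, 2)
    for branch in ("prediction", "impairment"):
        assert np.array_equal(g_dyn[branch], base[branch].values)
        assert traces[branch].sigmas == []


def test_zero_step_size_freezes_the_magnitude_track(setup):
    model, utt, x = setup
    cfg = PerturbationConfig(n_perturbations=3, sigma0=0.02, step_size=0.0)
    _, traces = accumulate_gradients(model, x, utt.severity, 1, cfg)
    for branch in ("prediction", "impairment"):
        assert traces[branch].sigmas == [0.02, 0.02, 0.02]


def test_accumulation_matches_an_explicit_loop(setup):
    """Bit-for-bit agreement with an independently coded add-noise /
    forward / backward / accumulate loop."""
    model, utt, x = setup
    cfg = PerturbationConfig(n_perturbations=2, sigma0=0.01,
                             step_size=0.01, p_max=0.1, seed=5)
    g_dyn, traces = accumulate_gradients(model, x, utt.severity, 3, cfg)
    for bi, branch in enumerate(("prediction", "impairment")):
        rng = np.random.default_rng([cfg.seed, bi])
        sigma = cfg.sigma0
        expect = model.class_gradient(x, utt.severity, 3)[branch].values.copy()
        sigmas = []
        for _ in range(cfg.n_perturbations):
            xp = x + rng.normal(0.0, sigma, size=x.shape)
            gp = model.class_gradient(xp, utt.severity, 3)[branch].values
            expect += gp
            sigmas.append(sigma)
            sigma = min(cfg.p_max, sigma + cfg.step_size
                        * float(np.mean(np.abs(gp))))
        assert np.array_equal(g_dyn[branch], expect)
        assert traces[branch].sigmas == sigmas
        assert all(a <= b + 1e-15 for a, b in
                   zip(traces[branch].sigmas, traces[branch].sigmas[1:]))


def test_noop_perturbations_warn(setup):
    model, utt, x = setup
    cfg = PerturbationConfig(n_perturbations=1, sigma0=0.0, step_size=0.0)
    with pytest.warns(UserWarning, match="no-ops"):
        accumulate_gradients(model, x, utt.severity, 0, cfg)


# ---------------------------------------------------------------------------
# normalization and filtering
# ---------------------------------------------------------------------------

def test_normalize_zero_map_stays_zero():
    assert np.array_equal(normalize_gradients(np.zeros((3, 4))),
                          np.zeros((3, 4)))


def test_normalize_single_element_closed_form():
    out = normalize_gradients(np.array([2.0]))
    assert out[0] == pytest.approx(2.0 / (4.0 + EPS), rel=1e-12)


def test_normalize_scaling_matches_recomputation(rng):
    g = rng.normal(size=(5, 3))
    c = 3.7
    direct = (c * g) / (np.mean((c * g) ** 2) + EPS)
    assert np.allclose(normalize_gradients(c * g), direct, atol=1e-15)


def test_dual_filter_elementwise(rng):
    g = rng.normal(size=(5, 4))
    f = rng.normal(size=(5, 4))
    out = dual_filter(g, f)
    for t in range(5):
        for k in range(4):
            expect = g[t, k] if (f[t, k] > 0 and g[t, k] > 0) else 0.0
            assert out[t, k] == expect
    assert (out >= 0).all()
    assert np.array_equal(dual_filter(-np.abs(g), f), np.zeros_like(g))
    assert np.array_equal(dual_filter(np.abs(g) + 1, np.abs(f) + 1),
                          np.abs(g) + 1)


def test_dual_filter_rejects_shape_mismatch():
    with pytest.raises(ValueError, match="mismatch"):
        dual_filter(np.zeros((3, 4)), np.zeros((4, 3)))


def test_gating_nullity_identity_and_linearity(rng):
    g = np.abs(rng.normal(size=(6, 3)))
    assert not gate_with_filter(g, np.zeros(6)).any()
    assert np.array_equal(gate_with_filter(g, np.ones(6)), g)
    assert np.allclose(gate_with_filter(g, np.full(6, 2.5)), 2.5 * g)
    with pytest.raises(ValueError, match="length"):
        gate_with_filter(g, np.ones(5))


# ---------------------------------------------------------------------------
# segmentation
# ---------------------------------------------------------------------------

def test_segment_starts_follow_the_overlap_formula():
    spans = segment_indices(25, SegmentConfig(t_seg=10, overlap=0.5))
    assert [s for s, _ in spans] == [0, 5, 10, 15, 20]
    assert spans[-1][1] == 25


def test_single_segment_covers_everything():
    assert segment_indices(30, SegmentConfig(t_seg=30, overlap=0.0)) \
        == [(0, 30)]
    assert segment_indices(7, SegmentConfig(t_seg=40, overlap=0.0)) \
        == [(0, 7)]


def test_no_overlap_tiles_without_gaps():
    spans = segment_indices(47, SegmentConfig(t_seg=10, overlap=0.0))
    covered = sorted(frame for s, e in spans for frame in range(s, e))
    assert covered == list(range(47))


def test_segment_weights_and_cam_oracles(rng):
    seg = rng.normal(size=(4, 3))
    assert np.allclose(segment_weights(seg), seg.mean(axis=0))
    assert np.allclose(segment_weights(np.full((5, 2), 1.7)), 1.7)
    alpha = rng.normal(size=3)
    F = rng.normal(size=(4, 3))
    assert np.allclose(segment_cam(alpha, F), F @ alpha)
    e1 = np.array([0.0, 1.0, 0.0])
    assert np.allclose(segment_cam(e1, F), F[:, 1])
    assert not segment_cam(np.zeros(3), F).any()


def test_banded_cam_sums_back_to_the_plain_cam(rng):
    alpha = rng.normal(size=6)
    F = rng.normal(size=(5, 6))
    band_map = np.array([0, 0, 1, 1, 2, 2])
    banded = segment_cam_banded(alpha, F, band_map)
    assert banded.shape == (5, 3)
    assert np.allclose(banded.sum(axis=1), segment_cam(alpha, F))


# ---------------------------------------------------------------------------
# aggregation
# ---------------------------------------------------------------------------

IDENT_GRID = ((10.0, 0.0), (10.0, 0.0, 8))  # tap grid == output grid, T=8


def test_overlap_frames_average_coverage(rng):
    cfg = SegmentConfig(t_seg=6, overlap=0.5, smoothing_width=0.0)
    a = rng.normal(size=6)
    b = rng.normal(size=5)   # second segment clipped at T = 8
    out = aggregate_cams([a, b], [(0, 6), (3, 8)], 8, cfg,
                         *IDENT_GRID, n_mels=4)
    col = out[:, 0]
    assert np.allclose(col[:3], a[:3])
    assert np.allclose(col[3:6], (a[3:6] + b[:3]) / 2)
    assert np.allclose(col[6:8], b[3:5])


def test_constant_segments_aggregate_to_a_constant(rng):
    cfg = SegmentConfig(t_seg=5, overlap=0.4, smoothing_width=3.0)
    cams = [np.full(5, 2.5), np.full(5, 2.5), np.full(3, 2.5)]
    out = aggregate_cams(cams, [(0, 5), (3, 8), (5, 8)], 8, cfg,
                         *IDENT_GRID, n_mels=4)
    assert np.allclose(out, 2.5)


def test_empty_cam_list_rejected():
    with pytest.raises(ValueError, match="no segment"):
        aggregate_cams([], [], 8, SegmentConfig(), *IDENT_GRID)


# ---------------------------------------------------------------------------
# end-to-end identities
# ---------------------------------------------------------------------------

def _explain(model, utt, **kw):
    kw.setdefault("perturbation", PerturbationConfig(n_perturbations=2,
                                                     seed=9))
    kw.setdefault("segments", SegmentConfig(t_seg=8, overlap=0.5))
    return acam.explain(model, utt, target=1, **kw)


def test_zero_filter_nullifies_the_impairment_map_only(setup):
    model, utt, _ = setup
    zero = _explain(model, utt, af_override=np.array(0.0))
    one = _explain(model, utt, af_override=np.array(1.0))
    assert not zero.impairment.raw.any()
    assert np.array_equal(zero.prediction.raw, one.prediction.raw)
    assert one.impairment.raw.any()


def test_constant_filter_scales_the_raw_impairment_map(setup):
    model, utt, _ = setup
    one = _explain(model, utt, af_override=np.array(1.0))
    scaled = _explain(model, utt, af_override=np.array(2.5))
    assert np.allclose(scaled.impairment.raw, 2.5 * one.impairment.raw,
                       rtol=1e-10, atol=1e-12)


def test_explain_is_deterministic_given_seed(setup):
    model, utt, _ = setup
    a = _explain(model, utt)
    b = _explain(model, utt)
    assert np.array_equal(a.prediction.raw, b.prediction.raw)
    assert np.array_equal(a.impairment.raw, b.impairment.raw)


def test_explain_requires_annotations_for_the_impairment_branch(setup):
    model, utt, _ = setup
    bare = dataclasses.replace(utt, word_tier=[])
    with pytest.raises(ValueError, match="word_tier"):
        acam.explain(model, bare, target=0)


def test_relevance_maps_are_non_negative_and_display_normalized(setup):
    model, utt, _ = setup
    exp = _explain(model, utt)
    for m in (exp.prediction, exp.impairment):
        assert (m.raw >= 0).all()
        assert 0.0 <= m.display.min() and m.display.max() <= 1.0
        assert np.unravel_index(np.argmax(m.raw), m.raw.shape) \
            == np.unravel_index(np.argmax(m.display), m.display.shape)


def test_gradcam_reduction_chain(setup):
    """With no perturbation, the dual filter replaced by the terminal ReLU
    and one global unsmoothed segment, the pipeline equals plain Grad-CAM
    up to the scalar gradient normalization."""
    model, utt, x = setup
    target = 4
    out = model.forward(x, utt.severity)
    tap = out.taps["prediction"]
    g = model.class_gradient(x, utt.severity, target)["prediction"].values
    scale = float(np.mean(g ** 2) + EPS)

    g_norm = normalize_gradients(g)
    alpha = segment_weights(g_norm)
    cam = segment_cam_banded(alpha, tap.values, tap.band_map)
    cfg = SegmentConfig(t_seg=tap.values.shape[0], overlap=0.0,
                        smoothing_width=0.0)
    fps, t0 = model.input_grid()
    raw = aggregate_cams([cam], [(0, tap.values.shape[0])],
                         tap.values.shape[0], cfg, (tap.fps, tap.t0),
                         (fps, t0, x.shape[0]), n_mels=model.config.n_mels)
    raw = np.maximum(raw, 0.0)

    base = gradcam_baseline(model, x, utt.severity, target,
                            branch="prediction")
    assert np.allclose(raw, base.raw / scale, rtol=1e-10, atol=1e-12)
    zero = gradcam_baseline(model, x, utt.severity, target,
                            branch="impairment")
    assert (zero.raw >= 0).all()
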