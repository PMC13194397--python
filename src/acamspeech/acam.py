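"""Dual-stream class-activation attribution for disordered speech.

Produces two complementary relevance maps from one classifier pass:

* a **prediction** map from the CNN tap, showing which spectro-temporal
  regions support the keyword decision, and
* an **impairment** map from the transformer tap, gated by the aphasia
  filter so relevance concentrates on clinically abnormal segments.

The pipeline, per branch:

1. *adaptive perturbation with gradient accumulation* — the class gradient
   at the clean input plus gradients at N noise-perturbed inputs, where the
   Gaussian noise magnitude grows with the mean absolute gradient of the
   previous perturbation (clipped at ``p_max``); each branch keeps its own
   magnitude track;
2. *normalization* — division by (mean squared gradient + 1e-5); the
   divisor is the mean square, not the root mean square, an unusual but
   deliberate scaling kept as printed in the construction this follows;
3. *dual filtering* — only coordinates where both the activation and the
   normalized gradient are positive survive;
4. *aphasia-filter gating* (impairment branch only) — per-frame
   multiplication by AF_W resampled onto the tap grid;
5. *segment-wise CAM* — overlapping temporal segments; per-segment channel
   weights are segment means of the gated gradient; the segment CAM is the
   weight-contracted feature map;
6. *aggregation* — per-segment Gaussian smoothing, placement on a
   full-length canvas with per-frame coverage averaging (which reduces to a
   plain mean over segments when all segments share one support), linear
   resampling to the spectrogram time axis, and expansion over the 128-bin
   frequency axis (the prediction branch paints each retained frequency
   band back onto its own mel bins; the impairment branch is temporal and
   broadcasts).  A terminal ReLU guarantees non-negative raw maps; a
   min-max normalized display copy is kept separately so linearity
   properties remain assertable on the raw map.

A plain Grad-CAM baseline (global-average-pooled gradient weights, ReLU,
no perturbation / dual filter / AF) is included for comparison.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import warnings

import numpy as np
from scipy.ndimage import gaussian_filter1d

from . import afilter as af_mod
from .model import AqFilmClassifier, FeatureTap

EPSILON = 1e-5


@dataclasses.dataclass(frozen=True)
class PerturbationConfig:
    n_perturbations: int = 8
    sigma0: float = 0.01
    p_max: float = 0.1
    step_size: float = 0.01
    noise: str = "gaussian"
    epsilon: float = EPSILON
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_perturbations < 0:
            raise ValueError("n_perturbations must be >= 0")
        if not 0 <= self.sigma0 <= self.p_max:
            raise ValueError("need 0 <= sigma0 <= p_max")
        if self.step_size < 0 or self.epsilon <= 0:
            raise ValueError("step_size >= 0 and epsilon > 0 required")


@dataclasses.dataclass
class PerturbationTrace:
    sigmas: list[float]
    grad_norms: list[float]


@dataclasses.dataclass(frozen=True)
class SegmentConfig:
    t_seg: int = 25
    overlap: float = 0.5
    smoothing_width: float = 5.0   # frames; Gaussian sigma = width / 2

    def __post_init__(self) -> None:
        if self.t_seg < 1:
            raise ValueError("t_seg must be >= 1")
        if not 0 <= self.overlap < 1:
            raise ValueError("overlap must be in [0, 1)")


@dataclasses.dataclass
class RelevanceMap:
    branch: str
    raw: np.ndarray        # (T_out, n_mels), >= 0
    display: np.ndarray    # min-max normalized copy in [0, 1]
    fps: float
    t0: float
    target_class: int
    config_hash: str

    def temporal(self, raw: bool = True) -> np.ndarray:
        m = self.raw if raw else self.display
        return m.mean(axis=1)


@dataclasses.dataclass
class DualExplanation:
    prediction: RelevanceMap | None
    impairment: RelevanceMap | None
    composite_filter: af_mod.CompositeFilter | None
    predicted_class: int
    predicted_prob: float


# ---------------------------------------------------------------------------
# pipeline operations
# ---------------------------------------------------------------------------

def accumulate_gradients(model: AqFilmClassifier, x: np.ndarray,
                         severity: float, target: int,
                         config: PerturbationConfig = PerturbationConfig(),
                         ) -> tuple[dict[str, np.ndarray],
                                    dict[str, PerturbationTrace]]:
    """G_dynamic = base gradient + sum of N perturbed-input gradients.

    Each branch keeps an independent noise stream and magnitude track; the
    magnitude update after perturbation p is
    ``sigma <- min(p_max, sigma + step_size * mean(|G(p)|))`` with the mean
    over all elements of that perturbation's gradient for the branch.
    """
    if (config.n_perturbations > 0 and config.sigma0 == 0
            and config.step_size == 0):
        warnings.warn("perturbations requested with sigma0 = step_size = 0; "
                      "they are no-ops", stacklevel=2)
    base = model.class_gradient(x, severity, target)
    out: dict[str, np.ndarray] = {}
    traces: dict[str, PerturbationTrace] = {}
    for bi, branch in enumerate(("prediction", "impairment")):
        rng = np.random.default_rng([config.seed, bi])
        sigma = config.sigma0
        g_dyn = base[branch].values.copy()
        trace = PerturbationTrace(sigmas=[], grad_norms=[])
        for _ in range(config.n_perturbations):
            xp = x + rng.normal(0.0, sigma, size=x.shape)
            gp = model.class_gradient(xp, severity, target)[branch].values
            g_dyn = g_dyn + gp
            mean_abs = float(np.mean(np.abs(gp)))
            trace.sigmas.append(sigma)
            trace.grad_norms.append(mean_abs)
            sigma = min(config.p_max, sigma + config.step_size * mean_abs)
        out[branch] = g_dyn
        traces[branch] = trace
    return out, traces


def normalize_gradients(g_dynamic: np.ndarray,
                        epsilon: float = EPSILON) -> np.ndarray:
    """G / (mean(G^2) + epsilon): a scalar divisor, shape preserved."""
    g = np.asarray(g_dynamic, dtype=np.float64)
    return g / (np.mean(g ** 2) + epsilon)


def dual_filter(g_norm: np.ndarray, features: np.ndarray) -> np.ndarray:
    """Keep only coordinates where both activation and gradient are > 0."""
    g = np.asarray(g_norm, dtype=np.float64)
    f = np.asarray(features, dtype=np.float64)
    if g.shape != f.shape:
        raise ValueError(f"shape mismatch: gradients {g.shape} vs "
                         f"features {f.shape}")
    return g * (f > 0) * (g > 0)


def gate_with_filter(g_gd: np.ndarray, af_values: np.ndarray) -> np.ndarray:
    """Per-frame multiplication by AF, broadcast over channels."""
    g = np.asarray(g_gd, dtype=np.float64)
    af = np.asarray(af_values, dtype=np.float64)
    if len(af) != g.shape[0]:
        raise ValueError(f"AF length {len(af)} does not match the tap's "
                         f"{g.shape[0]} frames")
    return g * af[:, None]


def segment_indices(T: int, config: SegmentConfig) -> list[tuple[int, int]]:
    """Segment spans [j_m, min(j_m + t_seg, T)) with
    j_m = round(m * t_seg * (1 - overlap)); the smallest count covering T."""
    if T < 1:
        raise ValueError("T must be >= 1")
    spans = []
    m = 0
    while True:
        j = int(round(m * config.t_seg * (1.0 - config.overlap)))
        if j >= T:
            break
        spans.append((j, min(j + config.t_seg, T)))
        if config.t_seg * (1.0 - config.overlap) < 0.5:
            break  # degenerate stride: one segment only
        m += 1
    return spans


def segment_weights(g_segment: np.ndarray) -> np.ndarray:
    """Per-channel mean of the gated gradient over the segment's frames."""
    g = np.asarray(g_segment, dtype=np.float64)
    if g.shape[0] == 0:
        raise ValueError("empty segment")
    return g.mean(axis=0)


def segment_cam(alpha: np.ndarray, f_segment: np.ndarray) -> np.ndarray:
    """CAM_m[t] = sum_k alpha_k F[t, k]."""
    return np.asarray(f_segment, dtype=np.float64) @ np.asarray(
        alpha, dtype=np.float64)


def segment_cam_banded(alpha: np.ndarray, f_segment: np.ndarray,
                       band_map: np.ndarray) -> np.ndarray:
    """Band-resolved segment CAM for taps with a retained frequency axis:
    out[t, b] = sum over channels of band b of alpha_k F[t, k].  Summing
    over bands recovers :func:`segment_cam`."""
    weighted = np.asarray(f_segment, dtype=np.float64) * np.asarray(
        alpha, dtype=np.float64)[None, :]
    n_bands = int(band_map.max()) + 1
    out = np.zeros((weighted.shape[0], n_bands))
    np.add.at(out.T, band_map, weighted.T)
    return out


def aggregate_cams(cams: list[np.ndarray], spans: list[tuple[int, int]],
                   T: int, config: SegmentConfig,
                   tap_grid: tuple[float, float],
                   out_grid: tuple[float, float, int],
                   n_mels: int = 128) -> np.ndarray:
    """Smooth, place and average segment CAMs, then resample to the output
    time grid and expand over frequency.  Returns the raw (T_out, n_mels)
    canvas (no ReLU, no display normalization -- callers do that)."""
    if not cams:
        raise ValueError("no segment CAMs to aggregate")
    first = np.atleast_2d(np.asarray(cams[0], dtype=np.float64).T).T
    width = first.shape[1] if first.ndim == 2 else 1
    canvas = np.zeros((T, width))
    coverage = np.zeros(T)
    for cam, (j, end) in zip(cams, spans):
        cam = np.asarray(cam, dtype=np.float64)
        if cam.ndim == 1:
            cam = cam[:, None]
        if config.smoothing_width > 0:
            cam = gaussian_filter1d(cam, sigma=config.smoothing_width / 2.0,
                                    axis=0, mode="nearest")
        canvas[j:end] += cam
        coverage[j:end] += 1.0
    canvas /= np.maximum(coverage, 1.0)[:, None]

    tap_fps, tap_t0 = tap_grid
    out_fps, out_t0, n_out = out_grid
    tap_centers = tap_t0 + np.arange(T) / tap_fps
    out_centers = out_t0 + np.arange(n_out) / out_fps
    resampled = np.stack([np.interp(out_centers, tap_centers, canvas[:, c])
                          for c in range(canvas.shape[1])], axis=1)
    if canvas.shape[1] == 1:
        return np.tile(resampled, (1, n_mels))
    reps = n_mels // canvas.shape[1]
    return np.repeat(resampled, reps, axis=1)


def _display(raw: np.ndarray) -> np.ndarray:
    lo, hi = raw.min(), raw.max()
    if hi - lo <= 0:
        return np.zeros_like(raw)
    return (raw - lo) / (hi - lo)


def _config_hash(*cfgs) -> str:
    blob = json.dumps([dataclasses.asdict(c) if dataclasses.is_dataclass(c)
                       else c for c in cfgs], sort_keys=True, default=str)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


# ---------------------------------------------------------------------------
# branch assembly and the public explain()
# ---------------------------------------------------------------------------

def _branch_map(model: AqFilmClassifier, tap: FeatureTap,
                g_branch: np.ndarray, target: int,
                seg_cfg: SegmentConfig, out_grid, cfg_hash: str,
                af_values: np.ndarray | None = None,
                use_dual_filter: bool = True) -> RelevanceMap:
    F = tap.values
    g_norm = normalize_gradients(g_branch)
    g_gd = dual_filter(g_norm, F) if use_dual_filter else g_norm
    if af_values is not None:
        g_gd = gate_with_filter(g_gd, af_values)
    spans = segment_indices(F.shape[0], seg_cfg)
    cams = []
    for j, end in spans:
        alpha = segment_weights(g_gd[j:end])
        if tap.band_map is not None:
            cams.append(segment_cam_banded(alpha, F[j:end], tap.band_map))
        else:
            cams.append(segment_cam(alpha, F[j:end]))
    raw = aggregate_cams(cams, spans, F.shape[0], seg_cfg,
                         (tap.fps, tap.t0), out_grid,
                         n_mels=model.config.n_mels)
    raw = np.maximum(raw, 0.0)
    return RelevanceMap(branch=tap.branch, raw=raw, display=_display(raw),
                        fps=out_grid[0], t0=out_grid[1],
                        target_class=target, config_hash=cfg_hash)


def explain(model: AqFilmClassifier, utterance, target: int | None = None,
            perturbation: PerturbationConfig = PerturbationConfig(),
            segments: SegmentConfig = SegmentConfig(),
            weights: af_mod.FilterWeights = af_mod.FilterWeights(),
            vad: af_mod.VadConfig = af_mod.VadConfig(),
            boundary: af_mod.BoundaryConfig = af_mod.BoundaryConfig(),
            branches: tuple[str, ...] = ("prediction", "impairment"),
            use_dual_filter: bool = True,
            af_override: np.ndarray | None = None) -> DualExplanation:
    """Run the full dual-branch attribution pipeline on one utterance.

    ``utterance`` needs ``waveform``; the impairment branch additionally
    needs ``canonical_phonemes``, ``phoneme_tier`` and ``word_tier`` (the
    annotation tiers the aphasia filter consumes).  ``af_override``
    replaces the composite filter with an arbitrary per-tap-frame vector
    (used by ablations and linearity checks).
    """
    x = model.input_features(utterance.waveform)
    outputs = model.forward(x, utterance.severity)
    pred_class = int(np.argmax(outputs.probabilities))
    c = pred_class if target is None else int(target)

    g_dyn, _ = accumulate_gradients(model, x, utterance.severity, c,
                                    perturbation)
    out_fps, out_t0 = model.input_grid()
    out_grid = (out_fps, out_t0, x.shape[0])
    cfg_hash = _config_hash(perturbation, segments, weights, vad, boundary,
                            {"class": c, "dual_filter": use_dual_filter})

    pred_map = imp_map = None
    comp = None
    if "prediction" in branches:
        pred_map = _branch_map(model, outputs.taps["prediction"],
                               g_dyn["prediction"], c, segments, out_grid,
                               cfg_hash, use_dual_filter=use_dual_filter)
    if "impairment" in branches:
        tap = outputs.taps["impairment"]
        if af_override is not None:
            af_values = np.broadcast_to(
                np.asarray(af_override, dtype=np.float64),
                (tap.values.shape[0],)).copy()
        else:
            for tier in ("canonical_phonemes", "phoneme_tier", "word_tier"):
                if not getattr(utterance, tier, None):
                    raise ValueError(
                        f"impairment branch requires annotation tier "
                        f"'{tier}', which is missing or empty")
            comp = af_mod.build_filter(
                utterance.waveform, utterance.canonical_phonemes,
                utterance.phoneme_tier, utterance.word_tier,
                fps=out_fps, t0=0.0, vad=vad, boundary=boundary,
                weights=weights)
            comp = af_mod.resample_filter(comp, tap)
            af_values = comp.values
        imp_map = _branch_map(model, tap, g_dyn["impairment"], c, segments,
                              out_grid, cfg_hash, af_values=af_values,
                              use_dual_filter=use_dual_filter)
    return DualExplanation(prediction=pred_map, impairment=imp_map,
                           composite_filter=comp, predicted_class=pred_class,
                           predicted_prob=float(outputs.probabilities[c]))


def gradcam_baseline(model: AqFilmClassifier, x: np.ndarray, severity: float,
                     target: int, branch: str = "prediction",
                     out_grid: tuple[float, float, int] | None = None,
                     ) -> RelevanceMap:
    """Plain Grad-CAM: global-average-pooled gradient weights times the
    feature map, ReLU, resized to the spectrogram grid.  No perturbation,
    no dual filter, no aphasia filter."""
    outputs = model.forward(x, severity)
    grads = model.class_gradient(x, severity, target)
    tap = outputs.taps[branch]
    alpha = grads[branch].values.mean(axis=0)
    if tap.band_map is not None:
        cam = segment_cam_banded(alpha, tap.values, tap.band_map)
    else:
        cam = segment_cam(alpha, tap.values)
    if out_grid is None:
        fps, t0 = model.input_grid()
        out_grid = (fps, t0, x.shape[0])
    cfg = SegmentConfig(t_seg=max(1, tap.values.shape[0]), overlap=0.0,
                        smoothing_width=0.0)
    raw = aggregate_cams([cam], [(0, tap.values.shape[0])],
                         tap.values.shape[0], cfg, (tap.fps, tap.t0),
                         out_grid, n_mels=model.config.n_mels)
    raw = np.maximum(raw, 0.0)
    return RelevanceMap(branch=branch, raw=raw, display=_display(raw),
                        fps=out_grid[0], t0=out_grid[1], target_class=target,
                        config_hash="gradcam")
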