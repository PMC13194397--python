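"""Faithfulness and validation metrics for attribution maps.

Faithfulness: deletion / insertion perturbation curves with trapezoidal
area (AUPC), and the ADCC composite (harmonic mean of coherency,
1 - complexity, 1 - average confidence drop).  Masking follows the
baseline-blend convention

    x_masked = B + (x - B) * M

which for a binary M equals revealing the selected bins of ``x`` on top of
the baseline ``B`` and is also how soft saliency masks are applied for the
ADCC confidence drop.  B defaults to the per-mel-bin mean of the input (a
spectrally neutral baseline); zeros is offered as an alternative.

Validation: map binarization (utterance-mean or Otsu), frame-level
IoU / Dice against annotated error regions, two-group statistics
(Mann-Whitney U, Cohen's d with pooled SD, group-mean ratio) and Spearman
rank correlation — the machinery used to check that filter and impairment
maps respond to errors and track severity.  Simple energy / inverted-energy
/ shuffled-map baselines are provided for comparison.

Any object with ``predict_proba(x, severity) -> (n_classes,)`` works as the
model; the metrics never reach into model internals.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
from scipy import stats as sstats
from skimage.filters import threshold_otsu


@dataclasses.dataclass(frozen=True)
class FaithfulnessConfig:
    n_steps: int = 20
    baseline: str = "input-mean"      # or "zeros"

    def __post_init__(self) -> None:
        if self.n_steps < 2:
            raise ValueError("n_steps must be >= 2")
        if self.baseline not in ("input-mean", "zeros"):
            raise ValueError(f"unknown baseline recipe {self.baseline!r}")


@dataclasses.dataclass
class Curve:
    kind: str                  # deletion | insertion
    probabilities: np.ndarray  # length n_steps + 1, step 0 included
    aupc: float


@dataclasses.dataclass
class ADCCReport:
    average_drop: float
    coherency: float
    complexity: float
    adcc: float


def make_baseline(x: np.ndarray, recipe: str) -> np.ndarray:
    if recipe == "zeros":
        return np.zeros_like(x)
    return np.tile(x.mean(axis=0, keepdims=True), (x.shape[0], 1))


def _ranked_bins(relevance: np.ndarray) -> np.ndarray:
    """Flat bin indices by descending relevance; ties broken by grid order
    (ascending time, then frequency) for bit-for-bit reproducibility."""
    flat = relevance.ravel()
    order = np.lexsort((np.arange(flat.size), -flat))
    return order


def deletion_insertion(model, x: np.ndarray, severity: float,
                       relevance: np.ndarray, target: int,
                       config: FaithfulnessConfig = FaithfulnessConfig(),
                       ) -> tuple[Curve, Curve]:
    """Deletion and insertion probability curves plus trapezoidal AUPC.

    Deletion replaces the top k/K most relevant bins with the baseline;
    insertion starts from the baseline and restores them.  Step 0 is the
    full input (deletion) / pure baseline (insertion).
    """
    x = np.asarray(x, dtype=np.float64)
    relevance = np.asarray(relevance, dtype=np.float64)
    if relevance.shape != x.shape:
        raise ValueError(f"relevance grid {relevance.shape} does not match "
                         f"input grid {x.shape}")
    B = make_baseline(x, config.baseline)
    order = _ranked_bins(relevance)
    n_bins = x.size
    K = config.n_steps
    del_probs, ins_probs = [], []
    for k in range(K + 1):
        n_top = int(round(n_bins * k / K))
        mask = np.zeros(n_bins, dtype=bool)
        mask[order[:n_top]] = True
        mask = mask.reshape(x.shape)
        x_del = np.where(mask, B, x)
        x_ins = np.where(mask, x, B)
        del_probs.append(float(model.predict_proba(x_del, severity)[target]))
        ins_probs.append(float(model.predict_proba(x_ins, severity)[target]))
    fracs = np.arange(K + 1) / K
    deletion = Curve("deletion", np.array(del_probs),
                     float(np.trapezoid(del_probs, fracs)))
    insertion = Curve("insertion", np.array(ins_probs),
                      float(np.trapezoid(ins_probs, fracs)))
    return deletion, insertion


def adcc(model, x: np.ndarray, severity: float, display_map: np.ndarray,
         target: int, explainer=None,
         baseline: str = "input-mean") -> ADCCReport:
    """ADCC = harmonic mean of (coherency, 1 - complexity, 1 - avg drop).

    * average_drop: max(0, f_c(x) - f_c(x_masked)) / f_c(x);
    * complexity: mean absolute value of the display map (L1 / bin count);
    * coherency: Pearson correlation between the display map and the map
      recomputed on the masked input (clipped to [0, 1]).

    ``explainer`` maps (x, severity, target) -> display map; when omitted,
    coherency degenerates to the map's self-correlation (1.0).
    """
    m = np.asarray(display_map, dtype=np.float64)
    if m.min() < 0 or m.max() > 1:
        raise ValueError("ADCC consumes the display map in [0, 1]")
    B = make_baseline(np.asarray(x, dtype=np.float64), baseline)
    x_masked = B + (x - B) * m
    p_full = float(model.predict_proba(x, severity)[target])
    p_masked = float(model.predict_proba(x_masked, severity)[target])
    if p_full == 0.0:
        warnings.warn("f_c(x) = 0; average_drop defined as 0", stacklevel=2)
        average_drop = 0.0
    else:
        average_drop = max(0.0, p_full - p_masked) / p_full
    complexity = float(np.mean(np.abs(m)))
    if explainer is None:
        m2 = m
    else:
        m2 = np.asarray(explainer(x_masked, severity, target),
                        dtype=np.float64)
    if np.std(m) == 0 or np.std(m2) == 0:
        coherency = 0.0
    else:
        coherency = float(np.clip(
            np.corrcoef(m.ravel(), m2.ravel())[0, 1], 0.0, 1.0))
    return ADCCReport(average_drop=average_drop, coherency=coherency,
                      complexity=complexity,
                      adcc=adcc_composite(coherency, complexity, average_drop))


def adcc_composite(coherency: float, complexity: float,
                   average_drop: float) -> float:
    terms = np.array([coherency, 1.0 - complexity, 1.0 - average_drop])
    if np.any(terms <= 0):
        return 0.0
    return float(3.0 / np.sum(1.0 / terms))


# ---------------------------------------------------------------------------
# binarization and overlap
# ---------------------------------------------------------------------------

def binarize_map(values: np.ndarray, method: str = "utterance-mean",
                 ) -> np.ndarray:
    """Binary mask from a (possibly multi-dimensional) map.

    ``utterance-mean``: 1 iff value > the map's mean (strict).
    ``otsu``: 256-bin between-class-variance threshold; a constant map has
    no variance to split and yields all zeros with a warning.
    """
    v = np.asarray(values, dtype=np.float64)
    if v.size == 0:
        raise ValueError("empty map")
    if method == "utterance-mean":
        return (v > v.mean()).astype(np.int8)
    if method == "otsu":
        if np.ptp(v) == 0:
            warnings.warn("constant map under Otsu: no variance to split",
                          stacklevel=2)
            return np.zeros_like(v, dtype=np.int8)
        thr = threshold_otsu(v, nbins=256)
        return (v > thr).astype(np.int8)
    raise ValueError(f"unknown binarization method {method!r}")


def frame_iou_dice(mask_a: np.ndarray, mask_b: np.ndarray,
                   ) -> tuple[float, float]:
    """IoU and Dice of two equal-length binary masks; two empty masks are
    in perfect agreement (both scores 1)."""
    a = np.asarray(mask_a).astype(bool)
    b = np.asarray(mask_b).astype(bool)
    if a.shape != b.shape:
        raise ValueError(f"mask shapes differ: {a.shape} vs {b.shape}")
    inter = np.sum(a & b)
    union = np.sum(a | b)
    size_sum = np.sum(a) + np.sum(b)
    if union == 0:
        return 1.0, 1.0
    return float(inter / union), float(2.0 * inter / size_sum)


# ---------------------------------------------------------------------------
# group statistics
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class GroupStats:
    u_statistic: float
    p_value: float
    cohens_d: float
    activation_ratio: float


def group_stats(values_a, values_b) -> GroupStats:
    """Two-sided Mann-Whitney U, Cohen's d (pooled SD) and mean ratio of
    group a over group b."""
    a = np.asarray(values_a, dtype=np.float64)
    b = np.asarray(values_b, dtype=np.float64)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs n >= 2")
    u, p = sstats.mannwhitneyu(a, b, alternative="two-sided")
    na, nb = len(a), len(b)
    pooled_var = (((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1))
                  / (na + nb - 2))
    if pooled_var == 0:
        d = 0.0 if a.mean() == b.mean() else float("inf")
    else:
        d = float((a.mean() - b.mean()) / np.sqrt(pooled_var))
    ratio = float(a.mean() / b.mean()) if b.mean() != 0 else float("inf")
    return GroupStats(u_statistic=float(u), p_value=float(p), cohens_d=d,
                      activation_ratio=ratio)


def spearman(x, y) -> tuple[float, float]:
    """Rank correlation with average ranks for ties; two-sided p-value."""
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need equal lengths with n >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("rank correlation undefined for constant input")
    rho, p = sstats.spearmanr(x, y)
    return float(rho), float(p)


# ---------------------------------------------------------------------------
# baseline relevance maps
# ---------------------------------------------------------------------------

def baseline_map(kind: str, *, waveform: np.ndarray | None = None,
                 n_frames: int | None = None, n_mels: int = 128,
                 fps: float = 100.0,
                 reference_map: np.ndarray | None = None,
                 rng: np.random.Generator | None = None,
                 n_trials: int = 50, sr: int = 16_000) -> np.ndarray:
    """Simple comparison maps on the (n_frames, n_mels) grid.

    * ``energy``: per-frame waveform RMS (full-scale amplitude units, so
      silence maps to ~0) broadcast over frequency;
    * ``inverted-energy``: 1 - energy;
    * ``random``: a temporal shuffle of ``reference_map`` averaged over
      ``n_trials`` draws from ``rng``.
    """
    if kind in ("energy", "inverted-energy"):
        if waveform is None or n_frames is None:
            raise ValueError("energy baselines need waveform and n_frames")
        hop = int(round(sr / fps))
        frame = hop * 2
        x = np.asarray(waveform, dtype=np.float64)
        vals = np.empty(n_frames)
        for i in range(n_frames):
            seg = x[i * hop: i * hop + frame]
            vals[i] = np.sqrt(np.mean(seg ** 2)) if len(seg) else 0.0
        vals = np.clip(vals, 0.0, 1.0)
        if kind == "inverted-energy":
            vals = 1.0 - vals
        return np.tile(vals[:, None], (1, n_mels))
    if kind == "random":
        if reference_map is None or rng is None:
            raise ValueError("random baseline needs reference_map and rng")
        m = np.asarray(reference_map, dtype=np.float64)
        acc = np.zeros_like(m)
        for _ in range(n_trials):
            acc += m[rng.permutation(m.shape[0])]
        return acc / n_trials
    raise ValueError(f"unknown baseline kind {kind!r}")
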