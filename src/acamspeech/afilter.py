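"""Multimodal aphasia filter.

Detects three families of clinically meaningful anomalies in an annotated
utterance and combines them into one weighted temporal mask:

* **pauses** -- short-time log-energy voice-activity detection; maximal
  silent runs at least ``min_pause`` long are flagged;
* **phoneme mispronunciations** -- minimal-edit-distance alignment between
  the canonical phoneme sequence and the produced phoneme tier; the time
  spans of substitution / insertion / deletion operations are flagged;
* **word-boundary errors** -- inter-word tier gaps longer than ``max_gap``.

Each family is rasterized to a binary frame mask M_X[t] (frame-center
containment, half-open intervals) and the composite filter is the exact
weighted sum

    AF_W[t] = alpha_P * M_P[t] + alpha_M * M_M[t] + alpha_WB * M_WB[t]

with default weights (1.0, 1.2, 1.5): boundary disruptions weigh most,
then phoneme mismatches, then pauses (common even in typical speech).
The filter lives on a stated frame grid and can be resampled onto a
feature tap's grid by nearest-frame-center lookup.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np

from .model import FeatureTap


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclasses.dataclass(frozen=True)
class VadConfig:
    frame_s: float = 0.025
    hop_s: float = 0.010
    threshold_dbfs: float = -40.0
    min_pause_s: float = 0.25     # the pause threshold T_P

    def __post_init__(self) -> None:
        if self.min_pause_s <= 0:
            raise ValueError("min_pause_s must be positive")
        if self.hop_s > self.frame_s:
            raise ValueError("hop must not exceed frame length")


@dataclasses.dataclass(frozen=True)
class BoundaryConfig:
    max_gap_s: float = 0.30       # the boundary threshold T_B

    def __post_init__(self) -> None:
        if self.max_gap_s <= 0:
            raise ValueError("max_gap_s must be positive")


@dataclasses.dataclass(frozen=True)
class FilterWeights:
    alpha_p: float = 1.0
    alpha_m: float = 1.2
    alpha_wb: float = 1.5

    def __post_init__(self) -> None:
        if min(self.alpha_p, self.alpha_m, self.alpha_wb) < 0:
            raise ValueError("filter weights must be non-negative")


@dataclasses.dataclass(frozen=True)
class EditOp:
    kind: str                  # substitution | insertion | deletion | match
    canonical_index: int | None
    produced_index: int | None
    span: tuple[float, float]  # seconds


@dataclasses.dataclass
class AnomalyMask:
    anomaly: str               # Pause | Mispronunciation | Boundary
    values: np.ndarray         # binary, frame grid
    fps: float


@dataclasses.dataclass
class CompositeFilter:
    values: np.ndarray
    fps: float
    t0: float
    weights: FilterWeights
    masks: dict[str, AnomalyMask]


MIN_DELETION_SPAN_S = 0.01


# ---------------------------------------------------------------------------
# pause detection (energy VAD)
# ---------------------------------------------------------------------------

def detect_pauses(waveform: np.ndarray, config: VadConfig = VadConfig(),
                  sr: int = 16_000) -> list[tuple[float, float]]:
    """Maximal silent runs with duration >= min_pause_s, as (start, end) s."""
    x = np.asarray(waveform, dtype=np.float64)
    if len(x) == 0:
        raise ValueError("empty waveform")
    frame = int(round(config.frame_s * sr))
    hop = int(round(config.hop_s * sr))
    if len(x) < frame:
        x = np.pad(x, (0, frame - len(x)))
    n_frames = 1 + (len(x) - frame) // hop
    idx = np.arange(frame)[None, :] + hop * np.arange(n_frames)[:, None]
    rms = np.sqrt(np.mean(x[idx] ** 2, axis=1))
    db = 20.0 * np.log10(np.maximum(rms, 1e-10))
    silent = db < config.threshold_dbfs
    intervals = []
    i = 0
    dur_total = len(waveform) / sr
    while i < n_frames:
        if silent[i]:
            j = i
            while j + 1 < n_frames and silent[j + 1]:
                j += 1
            start = i * config.hop_s
            end = min(j * config.hop_s + config.frame_s, dur_total)
            if end - start >= config.min_pause_s:
                intervals.append((start, end))
            i = j + 1
        else:
            i += 1
    return intervals


# ---------------------------------------------------------------------------
# phoneme alignment (unit-cost edit distance over provided tiers)
# ---------------------------------------------------------------------------

def align_phonemes(canonical: Sequence[str],
                   produced_tier: Sequence[tuple[str, float, float]],
                   ) -> list[EditOp]:
    """Minimal-edit-distance alignment between the canonical phoneme
    sequence and the produced tier.

    Unit costs.  Tie-breaking is deterministic: substitution is preferred
    over an insertion+deletion pair, and among equal-cost paths the one
    advancing the canonical index first is taken.  Non-match operations
    carry the time span of the produced segment involved; deletions (no
    produced audio to point at) borrow the midpoint gap between the
    flanking produced segments, widened to at least 10 ms.
    """
    canonical = list(canonical)
    if not canonical:
        raise ValueError("canonical sequence must be non-empty")
    produced = [(sym, float(s), float(e)) for sym, s, e in produced_tier]
    n, m = len(canonical), len(produced)
    D = np.zeros((n + 1, m + 1), dtype=np.int64)
    D[:, 0] = np.arange(n + 1)
    D[0, :] = np.arange(m + 1)
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            sub = D[i - 1, j - 1] + (canonical[i - 1] != produced[j - 1][0])
            D[i, j] = min(sub, D[i - 1, j] + 1, D[i, j - 1] + 1)

    def deletion_span(j_next: int) -> tuple[float, float]:
        # gap midpoint between produced[j_next-1] and produced[j_next]
        left = produced[j_next - 1][2] if j_next >= 1 else None
        right = produced[j_next][1] if j_next < m else None
        if left is None and right is None:
            mid = 0.0
        elif left is None:
            mid = right
        elif right is None:
            mid = left
        else:
            mid = 0.5 * (left + right)
        half = MIN_DELETION_SPAN_S / 2
        return (max(0.0, mid - half), mid + half)

    ops: list[EditOp] = []
    i, j = n, m
    while i > 0 or j > 0:
        if i > 0 and j > 0 and D[i, j] == D[i - 1, j - 1] + (
                canonical[i - 1] != produced[j - 1][0]):
            kind = ("match" if canonical[i - 1] == produced[j - 1][0]
                    else "substitution")
            ops.append(EditOp(kind, i - 1, j - 1,
                              (produced[j - 1][1], produced[j - 1][2])))
            i, j = i - 1, j - 1
        elif i > 0 and D[i, j] == D[i - 1, j] + 1:
            # deletion: canonical index advances first on ties
            ops.append(EditOp("deletion", i - 1, None, deletion_span(j)))
            i -= 1
        else:
            ops.append(EditOp("insertion", None, j - 1,
                              (produced[j - 1][1], produced[j - 1][2])))
            j -= 1
    ops.reverse()
    return ops


def mispronunciation_intervals(ops: Sequence[EditOp]) -> list[tuple[float, float]]:
    return sorted(op.span for op in ops if op.kind != "match")


# ---------------------------------------------------------------------------
# boundary errors
# ---------------------------------------------------------------------------

def detect_boundary_errors(word_tier: Sequence[tuple[str, float, float]],
                           config: BoundaryConfig = BoundaryConfig(),
                           ) -> list[tuple[float, float]]:
    """Inter-word gaps longer than T_B, as (start, end) s."""
    out = []
    for (_, _, e_prev), (_, s_next, _) in zip(word_tier, word_tier[1:]):
        if s_next - e_prev > config.max_gap_s:
            out.append((e_prev, s_next))
    return out


# ---------------------------------------------------------------------------
# rasterization and composition
# ---------------------------------------------------------------------------

def intervals_to_mask(intervals: Sequence[tuple[float, float]],
                      fps: float, n_frames: int, anomaly: str,
                      t0: float = 0.0) -> AnomalyMask:
    """Frame t is 1 iff its center t0 + t/fps falls inside any half-open
    interval [start, end)."""
    for s, e in intervals:
        if s < 0 or e < 0:
            raise ValueError(f"negative interval endpoint: ({s}, {e})")
    centers = t0 + np.arange(n_frames) / fps
    vals = np.zeros(n_frames, dtype=np.int8)
    for s, e in intervals:
        vals |= ((centers >= s) & (centers < e)).astype(np.int8)
    return AnomalyMask(anomaly=anomaly, values=vals, fps=fps)


def build_composite_filter(masks: dict[str, AnomalyMask],
                           weights: FilterWeights = FilterWeights(),
                           t0: float = 0.0) -> CompositeFilter:
    """AF_W[t] = alpha_P*M_P + alpha_M*M_M + alpha_WB*M_WB, exact per frame."""
    m_p = masks["Pause"]
    m_m = masks["Mispronunciation"]
    m_wb = masks["Boundary"]
    lengths = {len(m.values) for m in (m_p, m_m, m_wb)}
    fpss = {m.fps for m in (m_p, m_m, m_wb)}
    if len(lengths) != 1 or len(fpss) != 1:
        raise ValueError("component masks must share one frame grid")
    af = (weights.alpha_p * m_p.values.astype(np.float64)
          + weights.alpha_m * m_m.values.astype(np.float64)
          + weights.alpha_wb * m_wb.values.astype(np.float64))
    return CompositeFilter(values=af, fps=m_p.fps, t0=t0,
                           weights=weights, masks=dict(masks))


def resample_filter(filt: CompositeFilter, target: FeatureTap) -> CompositeFilter:
    """Nearest-frame-center resampling of AF onto a tap's grid; mask values
    are carried over unchanged (no interpolation across anomaly borders)."""
    T = target.values.shape[0]
    if T == 0:
        raise ValueError("zero-length target tap")
    tc = target.t0 + np.arange(T) / target.fps
    src = np.clip(np.round((tc - filt.t0) * filt.fps).astype(int),
                  0, len(filt.values) - 1)
    return CompositeFilter(values=filt.values[src], fps=target.fps,
                           t0=target.t0, weights=filt.weights,
                           masks=filt.masks)


# ---------------------------------------------------------------------------
# convenience: whole-utterance filter
# ---------------------------------------------------------------------------

def build_filter(waveform: np.ndarray,
                 canonical: Sequence[str],
                 phoneme_tier: Sequence[tuple[str, float, float]],
                 word_tier: Sequence[tuple[str, float, float]],
                 fps: float = 100.0, t0: float = 0.0,
                 vad: VadConfig = VadConfig(),
                 boundary: BoundaryConfig = BoundaryConfig(),
                 weights: FilterWeights = FilterWeights(),
                 sr: int = 16_000) -> CompositeFilter:
    """Run all three detectors on one annotated utterance and compose AF_W
    on an ``fps`` frame grid spanning the waveform."""
    n_frames = int(np.ceil(len(waveform) / sr * fps))
    pauses = detect_pauses(waveform, vad, sr=sr)
    ops = align_phonemes(canonical, phoneme_tier)
    mis = mispronunciation_intervals(ops)
    bnd = detect_boundary_errors(word_tier, boundary)
    masks = {
        "Pause": intervals_to_mask(pauses, fps, n_frames, "Pause", t0),
        "Mispronunciation": intervals_to_mask(mis, fps, n_frames,
                                              "Mispronunciation", t0),
        "Boundary": intervals_to_mask(bnd, fps, n_frames, "Boundary", t0),
    }
    return build_composite_filter(masks, weights, t0)
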