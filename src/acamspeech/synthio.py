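"""Synthetic disordered-speech generator.

Produces seed-reproducible, Boston-Naming-Test-style isolated keyword
utterances with planted, ground-truth-annotated aphasic anomalies whose
rates are coupled to a continuous severity score (Aphasia Quotient, AQ;
lower = more severe).  The generator exists so that every downstream stage
(filter construction, classifier training, attribution, validation metrics)
can be exercised end-to-end without access to clinical recordings.

Acoustics are deliberately schematic: each phoneme is a short burst of
band-limited noise following a fixed spectral recipe (formant-like center
frequencies), which makes the 15 keyword classes separable for a small
classifier while keeping every spectro-temporal property controllable and
checkable.  This is not naturalistic speech synthesis.

Three anomaly families are planted, mirroring the error classes a clinical
filter targets:

* pauses  -- near-silent spans (Gaussian noise at -60 dBFS) inserted at
  phoneme junctions, so energy-based voice-activity detection is exercised
  non-trivially;
* mispronunciations -- phoneme substitutions, deletions and insertions,
  reflected both in the audio and in the produced phoneme tier;
* word-boundary shifts -- the inter-word gap is widened and filled with a
  low-level voiced filler hum (above the VAD silence floor, so boundary and
  pause detections stay disjoint).

Every planted edit is logged in ``truth_intervals`` with its time span, and
the utterance-level correctness flag is derived from those logs.
"""

from __future__ import annotations

import dataclasses
import json
import hashlib
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
from scipy import signal as sps
from scipy.io import wavfile

SR = 16_000
AQ_MIN, AQ_MAX = 20.5, 94.8

SPEECH_RMS = 0.10          # ~ -20 dBFS
PAUSE_RMS = 0.001          # -60 dBFS, per design: not digital zero
FILLER_RMS = 0.04          # ~ -28 dBFS: above a -40 dBFS VAD floor
EDGE_RAMP_S = 0.005
LEAD_GAP_S = 0.08
WORD_GAP_S = 0.08
TRAIL_GAP_S = 0.08
FILLER_WORD = "uh"
FILLER_PHONEME = "AH"
DELETION_TRUTH_HALF_WIDTH_S = 0.02

# ---------------------------------------------------------------------------
# Phoneme inventory: symbol -> (duration s, [(center Hz, bandwidth Hz, amp)])
# Two formant-like bands for vowels, one dominant band for consonants.
# Center frequencies are pairwise distinct across the inventory.
# ---------------------------------------------------------------------------
PHONEME_BANK: dict[str, tuple[float, tuple[tuple[float, float, float], ...]]] = {
    # vowels / diphthongs
    "IY": (0.14, ((330, 120, 1.0), (2600, 250, 0.45))),
    "IH": (0.12, ((420, 120, 1.0), (2200, 250, 0.45))),
    "EH": (0.13, ((580, 120, 1.0), (2000, 250, 0.45))),
    "AE": (0.14, ((700, 130, 1.0), (1800, 250, 0.45))),
    "AH": (0.12, ((640, 130, 1.0), (1300, 220, 0.45))),
    "AA": (0.14, ((780, 130, 1.0), (1150, 220, 0.45))),
    "AO": (0.14, ((560, 130, 1.0), (910, 200, 0.45))),
    "OW": (0.14, ((470, 120, 1.0), (1010, 200, 0.45))),
    "UH": (0.12, ((440, 120, 1.0), (1110, 200, 0.45))),
    "UW": (0.14, ((350, 120, 1.0), (860, 200, 0.45))),
    "ER": (0.13, ((500, 120, 1.0), (1460, 220, 0.45))),
    "AW": (0.15, ((720, 130, 1.0), (1260, 220, 0.45))),
    "AY": (0.15, ((740, 130, 1.0), (1710, 240, 0.45))),
    "EY": (0.14, ((480, 120, 1.0), (2110, 250, 0.45))),
    # consonants
    "B": (0.07, ((300, 180, 1.0),)),
    "P": (0.07, ((1000, 300, 1.0),)),
    "T": (0.07, ((4200, 600, 1.0),)),
    "D": (0.07, ((3500, 550, 1.0),)),
    "K": (0.08, ((1700, 350, 1.0),)),
    "M": (0.10, ((260, 100, 1.0),)),
    "N": (0.10, ((310, 100, 1.0),)),
    "NG": (0.10, ((390, 110, 1.0),)),
    "L": (0.10, ((3050, 450, 1.0),)),
    "R": (0.10, ((1250, 260, 1.0),)),
    "Y": (0.09, ((2700, 380, 1.0),)),
    "HH": (0.08, ((1500, 500, 1.0),)),
    "F": (0.09, ((4600, 700, 1.0),)),
    "V": (0.09, ((2850, 450, 1.0),)),
    "S": (0.10, ((5200, 700, 1.0),)),
    "SH": (0.10, ((3300, 550, 1.0),)),
    "TH": (0.09, ((5800, 750, 1.0),)),
    "CH": (0.09, ((3900, 600, 1.0),)),
}

KEYWORDS: tuple[str, ...] = (
    "beaver", "bench", "cactus", "canoe", "comb",
    "hammock", "house", "octopus", "palette", "sphinx",
    "stethoscope", "toothbrush", "tripod", "unicorn", "volcano",
)

KEYWORD_PHONEMES: dict[str, tuple[str, ...]] = {
    "beaver": ("B", "IY", "V", "ER"),
    "bench": ("B", "EH", "N", "CH"),
    "cactus": ("K", "AE", "K", "T", "AH", "S"),
    "canoe": ("K", "AH", "N", "UW"),
    "comb": ("K", "OW", "M"),
    "hammock": ("HH", "AE", "M", "AH", "K"),
    "house": ("HH", "AW", "S"),
    "octopus": ("AA", "K", "T", "AH", "P", "UH", "S"),
    "palette": ("P", "AE", "L", "AH", "T"),
    "sphinx": ("S", "F", "IH", "NG", "K", "S"),
    "stethoscope": ("S", "T", "EH", "TH", "AH", "S", "K", "OW", "P"),
    "toothbrush": ("T", "UW", "TH", "B", "R", "AH", "SH"),
    "tripod": ("T", "R", "AY", "P", "AA", "D"),
    "unicorn": ("Y", "UW", "N", "AH", "K", "AO", "R", "N"),
    "volcano": ("V", "AA", "L", "K", "EY", "N", "OW"),
}

SIDECAR_SCHEMA_VERSION = 1


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclasses.dataclass(frozen=True)
class KeywordSpec:
    """Recipe for one of the 15 keyword classes, optionally speaker-colored."""

    keyword_id: int
    keyword: str
    phonemes: tuple[str, ...]
    durations: tuple[float, ...]
    recipes: tuple[tuple[tuple[float, float, float], ...], ...]

    def __post_init__(self) -> None:
        if not 0 <= self.keyword_id <= 14:
            raise ValueError(f"keyword_id must be in [0, 14], got {self.keyword_id}")
        if len(self.phonemes) < 2:
            raise ValueError("a keyword needs at least 2 phonemes")
        if any(d <= 0 for d in self.durations):
            raise ValueError("phoneme durations must be positive")


@dataclasses.dataclass(frozen=True)
class AnomalySpec:
    """Per-utterance anomaly rates; produced by :func:`severity_to_anomaly`."""

    pause_rate: float
    pause_duration: tuple[float, float]
    substitution_prob: float
    deletion_prob: float
    insertion_prob: float
    boundary_shift_prob: float
    boundary_shift: tuple[float, float]
    severity: float

    def __post_init__(self) -> None:
        for name in ("substitution_prob", "deletion_prob", "insertion_prob",
                     "boundary_shift_prob"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.pause_rate < 0:
            raise ValueError("pause_rate must be non-negative")


@dataclasses.dataclass(frozen=True)
class CouplingConfig:
    """Linear severity->anomaly coupling.

    Each rate interpolates linearly in (AQ_MAX - severity) between its floor
    (mildest, AQ = 94.8) and ceiling (most severe, AQ = 20.5), which makes
    every rate a non-increasing function of severity by construction and is
    trivially invertible in tests.
    """

    pause_rate: tuple[float, float] = (0.0, 2.0)
    substitution_prob: tuple[float, float] = (0.0, 0.2)
    deletion_prob: tuple[float, float] = (0.0, 0.08)
    insertion_prob: tuple[float, float] = (0.0, 0.08)
    boundary_shift_prob: tuple[float, float] = (0.0, 0.6)
    pause_duration: tuple[float, float] = (0.3, 0.6)
    boundary_shift: tuple[float, float] = (0.35, 0.6)


DEFAULT_COUPLING = CouplingConfig()


@dataclasses.dataclass(frozen=True)
class Segment:
    """One contiguous span of the rendered waveform (internal plumbing)."""

    kind: str                 # phoneme | pause | gap | filler
    symbol: str | None
    duration: float
    bands: tuple[tuple[float, float, float], ...]
    noise_seed: int
    word_idx: int | None = None
    anomaly: str | None = None   # pause | substitution | insertion | boundary


@dataclasses.dataclass
class Utterance:
    """A rendered utterance plus all annotation tiers and planted truth."""

    waveform: np.ndarray
    sr: int
    canonical_phonemes: tuple[str, ...]
    phoneme_tier: list[tuple[str, float, float]]
    word_tier: list[tuple[str, float, float]]
    severity: float
    keyword_id: int
    correctness: bool
    truth_intervals: dict[str, list[tuple[float, float]]]
    deleted_canonical: tuple[int, ...] = ()
    segments: tuple[Segment, ...] = ()
    speaker_id: int = -1

    @property
    def duration(self) -> float:
        return len(self.waveform) / self.sr


@dataclasses.dataclass(frozen=True)
class ManifestEntry:
    audio_path: str
    annotation_path: str
    keyword_id: int
    severity: float
    correctness: bool
    split: str
    speaker_id: int


@dataclasses.dataclass
class DatasetManifest:
    entries: list[ManifestEntry]
    seed: int
    parameters: dict

    def to_jsonl(self) -> str:
        lines = [json.dumps({"__meta__": {"seed": self.seed,
                                          "parameters": self.parameters}},
                            sort_keys=True)]
        for e in self.entries:
            lines.append(json.dumps(dataclasses.asdict(e), sort_keys=True))
        return "\n".join(lines) + "\n"

    @classmethod
    def from_jsonl(cls, text: str) -> "DatasetManifest":
        lines = [ln for ln in text.splitlines() if ln.strip()]
        meta = json.loads(lines[0])["__meta__"]
        entries = [ManifestEntry(**json.loads(ln)) for ln in lines[1:]]
        return cls(entries=entries, seed=meta["seed"], parameters=meta["parameters"])


# ---------------------------------------------------------------------------
# severity -> anomaly coupling
# ---------------------------------------------------------------------------

def severity_to_anomaly(severity: float,
                        coupling: CouplingConfig = DEFAULT_COUPLING,
                        rng: np.random.Generator | None = None) -> AnomalySpec:
    """Map a severity score to per-utterance anomaly rates.

    Rates are non-increasing in severity: the mildest score (94.8) sits at
    each rate's configured floor, the most severe (20.5) at its ceiling.
    ``rng`` is accepted for interface symmetry; the mapping is deterministic.
    """
    if not np.isfinite(severity) or not AQ_MIN <= severity <= AQ_MAX:
        raise ValueError(
            f"severity must be in [{AQ_MIN}, {AQ_MAX}], got {severity!r}")
    t = (AQ_MAX - severity) / (AQ_MAX - AQ_MIN)

    def lerp(lohi: tuple[float, float]) -> float:
        floor, ceil = lohi
        return floor + t * (ceil - floor)

    return AnomalySpec(
        pause_rate=lerp(coupling.pause_rate),
        pause_duration=coupling.pause_duration,
        substitution_prob=lerp(coupling.substitution_prob),
        deletion_prob=lerp(coupling.deletion_prob),
        insertion_prob=lerp(coupling.insertion_prob),
        boundary_shift_prob=lerp(coupling.boundary_shift_prob),
        boundary_shift=coupling.boundary_shift,
        severity=severity,
    )


# ---------------------------------------------------------------------------
# waveform rendering
# ---------------------------------------------------------------------------

def _jitter_bands(bands, factor):
    return tuple((cf * factor, bw, amp) for cf, bw, amp in bands)


N_SUBSTITUTION_NEIGHBORS = 6


def substitution_choices(symbol: str,
                         k: int = N_SUBSTITUTION_NEIGHBORS) -> list[str]:
    """Plausible substitutes for a phoneme: its ``k`` nearest inventory
    neighbors by primary center frequency.

    Phonemic paraphasias are predominantly single-feature errors, so the
    produced sound sits acoustically near the target rather than being an
    arbitrary draw from the whole inventory.
    """
    cf0 = PHONEME_BANK[symbol][1][0][0]
    others = [(abs(PHONEME_BANK[p][1][0][0] - cf0), p)
              for p in sorted(PHONEME_BANK) if p != symbol]
    others.sort()
    return [p for _, p in others[:k]]


def make_keyword_spec(keyword_id: int, jitter: float = 1.0) -> KeywordSpec:
    """Build the spec for a keyword class; ``jitter`` scales all center
    frequencies (the +-5% speaker surrogate)."""
    keyword = KEYWORDS[keyword_id]
    phonemes = KEYWORD_PHONEMES[keyword]
    durations = tuple(PHONEME_BANK[p][0] for p in phonemes)
    recipes = tuple(_jitter_bands(PHONEME_BANK[p][1], jitter) for p in phonemes)
    return KeywordSpec(keyword_id, keyword, phonemes, durations, recipes)


def _render_segment(seg: Segment, sr: int = SR) -> np.ndarray:
    n = max(1, int(round(seg.duration * sr)))
    rng = np.random.default_rng(seg.noise_seed)
    if seg.kind == "phoneme" or seg.kind == "filler":
        out = np.zeros(n)
        for cf, bw, amp in seg.bands:
            noise = rng.standard_normal(n)
            lo = max(20.0, cf - bw)
            hi = min(sr / 2 - 20.0, cf + bw)
            sos = sps.butter(4, [lo, hi], btype="bandpass", fs=sr, output="sos")
            out += amp * sps.sosfilt(sos, noise)
        rms = np.sqrt(np.mean(out ** 2)) or 1.0
        target = SPEECH_RMS if seg.kind == "phoneme" else FILLER_RMS
        out *= target / rms
        ramp = min(n // 2, int(EDGE_RAMP_S * sr))
        if ramp > 0:
            w = 0.5 * (1 - np.cos(np.pi * np.arange(ramp) / ramp))
            out[:ramp] *= w
            out[-ramp:] *= w[::-1]
        return out
    # pause / gap: low-level Gaussian noise, never digital zero
    return PAUSE_RMS * rng.standard_normal(n)


def _assemble(segments: Sequence[Segment], canonical: tuple[str, ...],
              severity: float, keyword_id: int, deleted: tuple[int, ...],
              speaker_id: int = -1) -> Utterance:
    """Render segments and derive all tiers + truth intervals."""
    pieces, phoneme_tier = [], []
    truth: dict[str, list[tuple[float, float]]] = {
        "pause": [], "mispronunciation": [], "boundary": []}
    word_spans: dict[int, list[float]] = {}
    t = 0.0
    boundary_planted = False
    for seg in segments:
        wav = _render_segment(seg)
        dur = len(wav) / SR
        start, end = t, t + dur
        pieces.append(wav)
        if seg.kind == "phoneme":
            phoneme_tier.append((seg.symbol, start, end))
            span = word_spans.setdefault(seg.word_idx, [start, end])
            span[1] = end
            if seg.anomaly in ("substitution", "insertion"):
                truth["mispronunciation"].append((start, end))
        elif seg.kind == "pause":
            truth["pause"].append((start, end))
        elif seg.kind == "filler" and seg.anomaly == "boundary":
            boundary_planted = True
        t = end
    word_tier = [(FILLER_WORD if widx == 0 else KEYWORDS[keyword_id],
                  word_spans[widx][0], word_spans[widx][1])
                 for widx in sorted(word_spans)]
    # boundary truth: the whole inter-word tier gap when a shift was planted
    if boundary_planted and len(word_tier) == 2:
        truth["boundary"].append((word_tier[0][2], word_tier[1][1]))
    waveform = np.concatenate(pieces).astype(np.float64)
    correctness = (not truth["mispronunciation"] and not truth["boundary"]
                   and not deleted)
    utt = Utterance(
        waveform=waveform, sr=SR, canonical_phonemes=canonical,
        phoneme_tier=phoneme_tier, word_tier=word_tier, severity=severity,
        keyword_id=keyword_id, correctness=correctness,
        truth_intervals=truth, deleted_canonical=deleted,
        segments=tuple(segments), speaker_id=speaker_id)
    return utt


def _deletion_truth(utt: Utterance) -> None:
    """Mark deletion sites in the mispronunciation truth tier.

    A deleted phoneme leaves no produced audio; the truth interval is a
    narrow window at the junction between the flanking produced phonemes,
    mirroring how the edit-distance aligner localizes deletions.
    """
    if not utt.deleted_canonical:
        return
    phoneme_segs = [sg for sg in utt.segments if sg.kind == "phoneme"]
    produced = [(s, e) for (sym, s, e), seg in zip(utt.phoneme_tier, phoneme_segs)
                if seg.word_idx == 1]
    for ci in utt.deleted_canonical:
        # number of surviving canonical phonemes before ci
        n_before = sum(1 for j in range(1, ci) if j not in utt.deleted_canonical)
        if n_before == 0:
            anchor = produced[0][0] if produced else 0.0
        elif n_before >= len(produced):
            anchor = produced[-1][1]
        else:
            anchor = 0.5 * (produced[n_before - 1][1] + produced[n_before][0])
        lo = max(0.0, anchor - DELETION_TRUTH_HALF_WIDTH_S)
        hi = min(utt.duration, anchor + DELETION_TRUTH_HALF_WIDTH_S)
        utt.truth_intervals["mispronunciation"].append((lo, hi))
    utt.truth_intervals["mispronunciation"].sort()


def gen_keyword_waveform(spec: KeywordSpec,
                         rng: np.random.Generator,
                         severity: float = AQ_MAX,
                         speaker_id: int = -1) -> Utterance:
    """Render a clean (correct) utterance: lead gap, filler word 'uh',
    inter-word gap, the keyword, trailing gap."""
    if len(spec.phonemes) == 0:
        raise ValueError("empty phoneme list")

    def seed() -> int:
        return int(rng.integers(0, 2 ** 31 - 1))

    segs: list[Segment] = [
        Segment("gap", None, LEAD_GAP_S, (), seed()),
        Segment("phoneme", FILLER_PHONEME, 0.10,
                PHONEME_BANK[FILLER_PHONEME][1], seed(), word_idx=0),
        Segment("gap", None, WORD_GAP_S, (), seed()),
    ]
    for sym, dur, bands in zip(spec.phonemes, spec.durations, spec.recipes):
        segs.append(Segment("phoneme", sym, dur, bands, seed(), word_idx=1))
    segs.append(Segment("gap", None, TRAIL_GAP_S, (), seed()))
    canonical = (FILLER_PHONEME,) + spec.phonemes
    return _assemble(segs, canonical, severity, spec.keyword_id, (),
                     speaker_id=speaker_id)


def plant_anomalies(utt: Utterance, spec: AnomalySpec,
                    rng: np.random.Generator) -> Utterance:
    """Plant pauses, phoneme edits and a boundary shift into a clean
    utterance; every edit is logged in truth_intervals."""
    if not utt.correctness:
        raise ValueError("plant_anomalies expects a clean (correct) utterance")

    def seed() -> int:
        return int(rng.integers(0, 2 ** 31 - 1))

    inventory = sorted(PHONEME_BANK)
    old = list(utt.segments)
    # locate keyword phoneme segments
    kw_idx = [i for i, s in enumerate(old)
              if s.kind == "phoneme" and s.word_idx == 1]

    # --- phoneme edits (order: decide fate of each canonical phoneme) ---
    new_segs: list[Segment] = []
    deleted: list[int] = []
    n_kw = len(kw_idx)
    fates = []
    for j in range(n_kw):
        u = rng.random()
        if u < spec.deletion_prob:
            fates.append("delete")
        elif u < spec.deletion_prob + spec.substitution_prob:
            fates.append("substitute")
        else:
            fates.append("keep")
    if all(f == "delete" for f in fates):
        raise ValueError("anomaly spec would delete every phoneme; "
                         "at least one must survive")
    insert_after = [rng.random() < spec.insertion_prob for _ in range(n_kw)]

    pos_in_kw = 0
    for i, seg in enumerate(old):
        if i not in kw_idx:
            new_segs.append(seg)
            continue
        fate = fates[pos_in_kw]
        if fate == "delete":
            deleted.append(pos_in_kw + 1)   # +1: canonical index 0 is filler
        elif fate == "substitute":
            choices = substitution_choices(seg.symbol)
            sub = choices[int(rng.integers(len(choices)))]
            dur, bands = PHONEME_BANK[sub]
            new_segs.append(Segment("phoneme", sub, dur, bands, seed(),
                                    word_idx=1, anomaly="substitution"))
        else:
            new_segs.append(seg)
        if insert_after[pos_in_kw]:
            ins = inventory[int(rng.integers(len(inventory)))]
            dur, bands = PHONEME_BANK[ins]
            new_segs.append(Segment("phoneme", ins, dur, bands, seed(),
                                    word_idx=1, anomaly="insertion"))
        pos_in_kw += 1

    # --- pauses at keyword-internal junctions ---
    n_pauses = int(rng.poisson(spec.pause_rate))
    if n_pauses > 0:
        kw_positions = [i for i, s in enumerate(new_segs)
                        if s.kind == "phoneme" and s.word_idx == 1]
        junctions = kw_positions[1:]  # insert before these indices
        if junctions:
            picks = sorted(
                rng.choice(len(junctions), size=min(n_pauses, len(junctions)),
                           replace=False).tolist(), reverse=True)
            for jpick in picks:
                dur = float(rng.uniform(*spec.pause_duration))
                new_segs.insert(junctions[jpick],
                                Segment("pause", None, dur, (), seed(),
                                        anomaly="pause"))

    # --- boundary shift: widen the inter-word gap with voiced filler ---
    if rng.random() < spec.boundary_shift_prob:
        shift = float(rng.uniform(*spec.boundary_shift))
        # the inter-word gap is the gap segment right after word 0's phoneme
        for i, s in enumerate(new_segs):
            if s.kind == "gap" and i > 0 and any(
                    ss.kind == "phoneme" for ss in new_segs[:i]):
                filler = Segment("filler", None, shift,
                                 ((180.0, 80.0, 1.0),), seed(),
                                 anomaly="boundary")
                new_segs.insert(i + 1, filler)
                break

    out = _assemble(new_segs, utt.canonical_phonemes, spec.severity,
                    utt.keyword_id, tuple(deleted), speaker_id=utt.speaker_id)
    _deletion_truth(out)
    out.correctness = (not out.truth_intervals["mispronunciation"]
                       and not out.truth_intervals["boundary"])
    return out


# ---------------------------------------------------------------------------
# corpora and datasets
# ---------------------------------------------------------------------------

def default_severity_sampler(rng: np.random.Generator) -> float:
    return float(rng.uniform(AQ_MIN, AQ_MAX))


def gen_corpus(n_per_class: int, seed: int,
               severity_sampler: Callable[[np.random.Generator], float] | None = None,
               split_fracs: tuple[float, float, float] = (0.7, 0.1, 0.2),
               coupling: CouplingConfig = DEFAULT_COUPLING,
               ) -> tuple[list[Utterance], list[str]]:
    """Generate an in-memory corpus with speaker-disjoint splits.

    Speakers are surrogates: each carries a fixed +-5% recipe-frequency
    perturbation and a single severity score; speakers never span splits.
    Returns (utterances, split tag per utterance).
    """
    if n_per_class < 1:
        raise ValueError("n_per_class must be >= 1")
    if abs(sum(split_fracs) - 1.0) > 1e-9:
        raise ValueError("split fractions must sum to 1")
    sampler = severity_sampler or default_severity_sampler
    total = 15 * n_per_class
    n_speakers = max(5, total // 10)
    master = np.random.default_rng([seed, 917])
    jitters = 1.0 + master.uniform(-0.05, 0.05, size=n_speakers)
    severities = np.array([sampler(master) for _ in range(n_speakers)])
    # speaker-disjoint splits
    order = master.permutation(n_speakers)
    n_train = int(round(split_fracs[0] * n_speakers))
    n_val = int(round(split_fracs[1] * n_speakers))
    split_of_speaker = {}
    for rank, spk in enumerate(order):
        split_of_speaker[int(spk)] = ("train" if rank < n_train
                                      else "val" if rank < n_train + n_val
                                      else "test")
    utts, splits = [], []
    for idx in range(total):
        kw = idx % 15
        rng = np.random.default_rng([seed, idx])
        spk = int(rng.integers(n_speakers))
        spec = make_keyword_spec(kw, jitter=float(jitters[spk]))
        sev = float(severities[spk])
        clean = gen_keyword_waveform(spec, rng, severity=sev, speaker_id=spk)
        anom = severity_to_anomaly(sev, coupling)
        utts.append(plant_anomalies(clean, anom, rng))
        splits.append(split_of_speaker[spk])
    return utts, splits


def gen_dataset(out_dir: str | Path, n_per_class: int, seed: int,
                severity_sampler: Callable | None = None,
                split_fracs: tuple[float, float, float] = (0.7, 0.1, 0.2),
                coupling: CouplingConfig = DEFAULT_COUPLING) -> DatasetManifest:
    """Write a corpus to disk (WAV + TextGrid + JSON sidecar + JSONL manifest)."""
    from . import io as aio  # local import to avoid a cycle at import time

    out_dir = Path(out_dir)
    try:
        out_dir.mkdir(parents=True, exist_ok=True)
    except OSError as exc:
        raise OSError(f"cannot create output directory {out_dir}: {exc}") from exc
    utts, splits = gen_corpus(n_per_class, seed, severity_sampler,
                              split_fracs, coupling)
    entries = []
    for i, (utt, split) in enumerate(zip(utts, splits)):
        stem = f"utt_{i:05d}_{KEYWORDS[utt.keyword_id]}"
        wav_path = out_dir / f"{stem}.wav"
        ann_path = out_dir / f"{stem}.TextGrid"
        write_wav(wav_path, utt.waveform)
        aio.write_annotations(ann_path, utt)
        entries.append(ManifestEntry(
            audio_path=wav_path.name, annotation_path=ann_path.name,
            keyword_id=utt.keyword_id, severity=round(utt.severity, 6),
            correctness=utt.correctness, split=split,
            speaker_id=utt.speaker_id))
    params = {"n_per_class": n_per_class, "split_fracs": list(split_fracs),
              "coupling": dataclasses.asdict(coupling)}
    manifest = DatasetManifest(entries=entries, seed=seed, parameters=params)
    (out_dir / "manifest.jsonl").write_text(manifest.to_jsonl())
    return manifest


def write_wav(path: str | Path, waveform: np.ndarray) -> None:
    x = np.clip(waveform, -1.0, 1.0)
    wavfile.write(str(path), SR, (x * 32767.0).astype(np.int16))


def read_wav(path: str | Path) -> np.ndarray:
    sr, data = wavfile.read(str(path))
    if sr != SR:
        raise ValueError(f"expected {SR} Hz audio, got {sr}")
    if data.dtype == np.int16:
        return data.astype(np.float64) / 32767.0
    return data.astype(np.float64)


def corpus_digest(utts: Sequence[Utterance]) -> str:
    """Stable digest of a corpus (waveforms + tiers), for determinism checks."""
    h = hashlib.sha256()
    for u in utts:
        h.update(np.asarray(u.waveform, dtype=np.float64).tobytes())
        h.update(json.dumps([u.phoneme_tier, u.word_tier, u.severity,
                             u.keyword_id, u.correctness,
                             sorted(u.truth_intervals.items())],
                            sort_keys=True).encode())
    return h.hexdigest()
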