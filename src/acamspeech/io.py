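"""Annotation and artifact I/O.

Annotations travel as a Praat TextGrid (interval tiers ``phones-produced``
and ``words``) plus a JSON sidecar carrying what a TextGrid cannot: the
canonical phoneme sequence, the severity score, the keyword class, the
correctness label and the planted ground-truth anomaly intervals.  The
sidecar schema is versioned.  Round trips are lossless: interval times are
written at full float precision and tiers are padded with empty-text
intervals so they tile the utterance span, as Praat expects.

Explanations are exported as one NPZ per branch (raw + display map, grid,
provenance hash), a PNG overlay on the mel spectrogram with anomaly-
interval shading, and a provenance JSON.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path

import numpy as np

SIDECAR_SCHEMA_VERSION = 1
PHONE_TIER = "phones-produced"
WORD_TIER = "words"


@dataclasses.dataclass
class Annotations:
    canonical_phonemes: tuple[str, ...]
    phoneme_tier: list[tuple[str, float, float]]
    word_tier: list[tuple[str, float, float]]
    severity: float
    keyword_id: int
    correctness: bool
    truth_intervals: dict[str, list[tuple[float, float]]]
    xmax: float


@dataclasses.dataclass
class AnnotatedUtterance:
    """An audio file joined with its annotations; duck-type compatible with
    the generator's utterance objects everywhere downstream."""
    waveform: np.ndarray
    sr: int
    canonical_phonemes: tuple[str, ...]
    phoneme_tier: list[tuple[str, float, float]]
    word_tier: list[tuple[str, float, float]]
    severity: float
    keyword_id: int
    correctness: bool
    truth_intervals: dict[str, list[tuple[float, float]]]


# ---------------------------------------------------------------------------
# TextGrid
# ---------------------------------------------------------------------------

def _pad_tier(intervals, xmax):
    """Insert empty-text intervals so the tier tiles [0, xmax]."""
    out, t = [], 0.0
    for sym, s, e in intervals:
        if s > t:
            out.append(("", t, s))
        out.append((sym, s, e))
        t = e
    if t < xmax:
        out.append(("", t, xmax))
    return out


def write_textgrid(path: str | Path, tiers: dict[str, list], xmax: float) -> None:
    lines = ['File type = "ooTextFile"', 'Object class = "TextGrid"', "",
             "xmin = 0", f"xmax = {xmax!r}", "tiers? <exists>",
             f"size = {len(tiers)}", "item []:"]
    for ti, (name, intervals) in enumerate(tiers.items(), 1):
        padded = _pad_tier(intervals, xmax)
        lines += [f"    item [{ti}]:", '        class = "IntervalTier"',
                  f'        name = "{name}"', "        xmin = 0",
                  f"        xmax = {xmax!r}",
                  f"        intervals: size = {len(padded)}"]
        for ii, (sym, s, e) in enumerate(padded, 1):
            lines += [f"        intervals [{ii}]:",
                      f"            xmin = {s!r}",
                      f"            xmax = {e!r}",
                      f'            text = "{sym}"']
    Path(path).write_text("\n".join(lines) + "\n")


def read_textgrid(path: str | Path) -> tuple[dict[str, list], float]:
    """Parse interval tiers from a (long-format) TextGrid.  Empty-text
    intervals are dropped; returns ({tier name: [(text, xmin, xmax)]}, xmax)."""
    text = Path(path).read_text()
    tiers: dict[str, list] = {}
    cur_name = None
    cur: dict = {}
    xmax_global = 0.0
    in_item = False
    for raw in text.splitlines():
        line = raw.strip()
        if line.startswith("item ["):
            in_item = "[]" not in line
            cur_name = None
            continue
        if "=" not in line:
            continue
        key, _, val = (p.strip() for p in line.partition("="))
        if key == "xmax" and not in_item:
            xmax_global = max(xmax_global, float(val))
        if key == "name":
            cur_name = val.strip('"')
            tiers[cur_name] = []
        elif key == "xmin" and cur_name is not None:
            cur = {"xmin": float(val)}
        elif key == "xmax" and cur_name is not None and "xmin" in cur:
            cur["xmax"] = float(val)
        elif key == "text" and cur_name is not None and "xmax" in cur:
            sym = val.strip('"')
            if sym:
                tiers[cur_name].append((sym, cur["xmin"], cur["xmax"]))
            cur = {}
    return tiers, xmax_global


def _validate_tier(name: str, intervals) -> None:
    prev_end = -np.inf
    for sym, s, e in intervals:
        if s < prev_end - 1e-12:
            raise ValueError(f"tier {name!r} has overlapping intervals "
                             f"(interval starting at {s})")
        if e < s:
            raise ValueError(f"tier {name!r} has an inverted interval "
                             f"({s}, {e})")
        prev_end = e


# ---------------------------------------------------------------------------
# sidecar + combined round trip
# ---------------------------------------------------------------------------

def write_annotations(path: str | Path, utt) -> None:
    """Write TextGrid + JSON sidecar for an utterance-like object."""
    path = Path(path)
    xmax = len(utt.waveform) / utt.sr
    write_textgrid(path, {PHONE_TIER: utt.phoneme_tier,
                          WORD_TIER: utt.word_tier}, xmax)
    sidecar = {
        "schema_version": SIDECAR_SCHEMA_VERSION,
        "canonical_phonemes": list(utt.canonical_phonemes),
        "severity": utt.severity,
        "keyword_id": utt.keyword_id,
        "correctness": bool(utt.correctness),
        "truth_intervals": {k: [list(iv) for iv in v]
                            for k, v in utt.truth_intervals.items()},
    }
    path.with_suffix(".json").write_text(
        json.dumps(sidecar, sort_keys=True, indent=1))


def read_annotations(path: str | Path) -> Annotations:
    """Read TextGrid + sidecar; validates tier and schema invariants."""
    path = Path(path)
    sidecar_path = path.with_suffix(".json")
    if not path.exists():
        raise FileNotFoundError(f"TextGrid not found: {path}")
    if not sidecar_path.exists():
        raise FileNotFoundError(f"JSON sidecar not found: {sidecar_path}")
    tiers, xmax = read_textgrid(path)
    for required in (PHONE_TIER, WORD_TIER):
        if required not in tiers:
            raise ValueError(f"missing tier {required!r} in {path}")
        _validate_tier(required, tiers[required])
    sidecar = json.loads(sidecar_path.read_text())
    version = sidecar.get("schema_version")
    if version != SIDECAR_SCHEMA_VERSION:
        raise ValueError(f"sidecar schema version mismatch: expected "
                         f"{SIDECAR_SCHEMA_VERSION}, got {version}")
    for field in ("canonical_phonemes", "severity", "keyword_id",
                  "correctness", "truth_intervals"):
        if field not in sidecar:
            raise ValueError(f"sidecar missing field {field!r}")
    return Annotations(
        canonical_phonemes=tuple(sidecar["canonical_phonemes"]),
        phoneme_tier=[(s, a, b) for s, a, b in tiers[PHONE_TIER]],
        word_tier=[(s, a, b) for s, a, b in tiers[WORD_TIER]],
        severity=float(sidecar["severity"]),
        keyword_id=int(sidecar["keyword_id"]),
        correctness=bool(sidecar["correctness"]),
        truth_intervals={k: [tuple(iv) for iv in v]
                         for k, v in sidecar["truth_intervals"].items()},
        xmax=xmax)


def load_annotated(audio_path: str | Path,
                   annotation_path: str | Path) -> AnnotatedUtterance:
    from .synthio import read_wav

    ann = read_annotations(annotation_path)
    wav = read_wav(audio_path)
    return AnnotatedUtterance(
        waveform=wav, sr=16_000,
        canonical_phonemes=ann.canonical_phonemes,
        phoneme_tier=ann.phoneme_tier, word_tier=ann.word_tier,
        severity=ann.severity, keyword_id=ann.keyword_id,
        correctness=ann.correctness, truth_intervals=ann.truth_intervals)


# ---------------------------------------------------------------------------
# explanation export
# ---------------------------------------------------------------------------

def config_digest(obj) -> str:
    blob = json.dumps(obj, sort_keys=True, default=str)
    return hashlib.sha256(blob.encode()).hexdigest()


def file_digest(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def export_explanation(explanation, out_dir: str | Path,
                       spectrogram: np.ndarray | None = None,
                       truth_intervals: dict | None = None,
                       provenance: dict | None = None) -> list[Path]:
    """Write NPZ + PNG per branch and a provenance JSON; returns the paths."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    out_dir = Path(out_dir)
    try:
        out_dir.mkdir(parents=True, exist_ok=True)
    except OSError as exc:
        raise OSError(f"cannot create output directory {out_dir}: {exc}") from exc
    written = []
    for branch in ("prediction", "impairment"):
        rmap = getattr(explanation, branch)
        if rmap is None:
            continue
        npz_path = out_dir / f"map_{branch}.npz"
        np.savez(npz_path, map_raw=rmap.raw, map_display=rmap.display,
                 fps=rmap.fps, t0=rmap.t0, target_class=rmap.target_class,
                 config_hash=np.array(rmap.config_hash))
        written.append(npz_path)
        fig, ax = plt.subplots(figsize=(8, 3))
        if spectrogram is not None:
            ax.imshow(spectrogram.T, origin="lower", aspect="auto",
                      cmap="gray_r",
                      extent=[rmap.t0, rmap.t0 + len(rmap.raw) / rmap.fps,
                              0, rmap.raw.shape[1]])
        ax.imshow(rmap.display.T, origin="lower", aspect="auto", cmap="magma",
                  alpha=0.55,
                  extent=[rmap.t0, rmap.t0 + len(rmap.raw) / rmap.fps,
                          0, rmap.raw.shape[1]])
        shade = {"pause": "orange", "mispronunciation": "red",
                 "boundary": "purple"}
        for kind, ivs in (truth_intervals or {}).items():
            for s, e in ivs:
                ax.axvspan(s, e, color=shade.get(kind, "gray"), alpha=0.2)
        ax.set_xlabel("time (s)")
        ax.set_ylabel("mel bin")
        ax.set_title(f"{branch} relevance (class {rmap.target_class})")
        png_path = out_dir / f"map_{branch}.png"
        fig.tight_layout()
        fig.savefig(png_path, dpi=110)
        plt.close(fig)
        written.append(png_path)
    prov = dict(provenance or {})
    prov.setdefault("tool", "acamspeech 0.1.0")
    prov_path = out_dir / "provenance.json"
    prov_path.write_text(json.dumps(prov, sort_keys=True, indent=1))
    written.append(prov_path)
    return written
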