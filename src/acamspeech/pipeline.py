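"""End-to-end study orchestration.

Thin glue that binds the generator, classifier, filter, attribution and
metrics modules into the reproducible studies the command-line interface
and the acceptance script run: corpus generation + training, detector
recovery against planted ground truth, filter validation statistics, and
the attribution direction/faithfulness study on a held-out split.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from . import acam, afilter, metrics, synthio
from .model import AqFilmClassifier, ModelConfig, TrainReport, train_toy


@dataclasses.dataclass
class Study:
    utterances: list
    splits: list[str]
    model: AqFilmClassifier
    train_report: TrainReport


def run_study(seed: int, n_per_class: int = 100,
              model_config: ModelConfig | None = None) -> Study:
    """Generate a severity-coupled corpus and train the FiLM classifier on
    its speaker-disjoint training split."""
    utts, splits = synthio.gen_corpus(n_per_class=n_per_class, seed=seed)
    cfg = model_config or ModelConfig(seed=seed)
    model = AqFilmClassifier(cfg)
    report = train_toy(model, utts, splits, cfg)
    return Study(utterances=utts, splits=splits, model=model,
                 train_report=report)


# ---------------------------------------------------------------------------
# detector recovery against planted truth
# ---------------------------------------------------------------------------

def plant_one_of_each(seed: int, n: int = 50,
                      vad: afilter.VadConfig = afilter.VadConfig(),
                      boundary: afilter.BoundaryConfig = afilter.BoundaryConfig(),
                      ) -> dict:
    """Generate ``n`` clean utterances, plant exactly one pause, one
    substitution and one boundary shift in each, and score each detector
    against its planted truth with frame-level IoU (frames pooled over all
    utterances).  Also cross-checks alignment op counts against a
    reference Levenshtein distance."""
    fps = 100.0
    per_type_frames = {k: [np.zeros(0, dtype=np.int8), np.zeros(0, dtype=np.int8)]
                       for k in ("pause", "mispronunciation", "boundary")}
    alignment_ok = 0
    for i in range(n):
        rng = np.random.default_rng([seed, 31_000 + i])
        kw = i % 15
        spec = synthio.make_keyword_spec(kw)
        clean = synthio.gen_keyword_waveform(spec, rng)
        utt = _plant_controlled(clean, rng)
        n_frames = int(np.ceil(utt.duration * fps))

        detected = {
            "pause": afilter.detect_pauses(utt.waveform, vad),
            "mispronunciation": afilter.mispronunciation_intervals(
                afilter.align_phonemes(utt.canonical_phonemes,
                                       utt.phoneme_tier)),
            "boundary": afilter.detect_boundary_errors(utt.word_tier,
                                                       boundary),
        }
        ops = afilter.align_phonemes(utt.canonical_phonemes, utt.phoneme_tier)
        n_edits = sum(1 for op in ops if op.kind != "match")
        if n_edits == _levenshtein(utt.canonical_phonemes,
                                   [s for s, _, _ in utt.phoneme_tier]):
            alignment_ok += 1
        for kind in per_type_frames:
            det = afilter.intervals_to_mask(detected[kind], fps, n_frames,
                                            kind).values
            tru = afilter.intervals_to_mask(utt.truth_intervals[kind], fps,
                                            n_frames, kind).values
            per_type_frames[kind][0] = np.concatenate(
                [per_type_frames[kind][0], det])
            per_type_frames[kind][1] = np.concatenate(
                [per_type_frames[kind][1], tru])
    iou = {}
    for kind, (det, tru) in per_type_frames.items():
        iou[kind], _ = metrics.frame_iou_dice(det, tru)
    return {"iou": iou, "alignment_match_fraction": alignment_ok / n, "n": n}


def _plant_controlled(utt, rng) -> "synthio.Utterance":
    """Exactly one pause, one substitution and one boundary shift."""
    spec = synthio.AnomalySpec(
        pause_rate=0.0, pause_duration=(0.3, 0.5),
        substitution_prob=0.0, deletion_prob=0.0, insertion_prob=0.0,
        boundary_shift_prob=1.0, boundary_shift=(0.35, 0.6),
        severity=utt.severity)
    # substitution: rebuild with exactly one substituted keyword phoneme
    segs = list(utt.segments)
    kw_idx = [i for i, s in enumerate(segs)
              if s.kind == "phoneme" and s.word_idx == 1]
    pick = kw_idx[int(rng.integers(len(kw_idx)))]
    choices = synthio.substitution_choices(segs[pick].symbol)
    sub = choices[int(rng.integers(len(choices)))]
    dur, bands = synthio.PHONEME_BANK[sub]
    segs[pick] = synthio.Segment("phoneme", sub, dur, bands,
                                 int(rng.integers(0, 2 ** 31 - 1)),
                                 word_idx=1, anomaly="substitution")
    # one pause before a random internal keyword junction
    if len(kw_idx) > 1:
        j = kw_idx[1 + int(rng.integers(len(kw_idx) - 1))]
        segs.insert(j, synthio.Segment(
            "pause", None, float(rng.uniform(0.3, 0.5)), (),
            int(rng.integers(0, 2 ** 31 - 1)), anomaly="pause"))
    # boundary shift after the inter-word gap
    for i, s in enumerate(segs):
        if s.kind == "gap" and any(ss.kind == "phoneme" for ss in segs[:i]):
            segs.insert(i + 1, synthio.Segment(
                "filler", None, float(rng.uniform(*spec.boundary_shift)),
                ((180.0, 80.0, 1.0),), int(rng.integers(0, 2 ** 31 - 1)),
                anomaly="boundary"))
            break
    out = synthio._assemble(segs, utt.canonical_phonemes, utt.severity,
                            utt.keyword_id, (), speaker_id=utt.speaker_id)
    out.correctness = False
    return out


def _levenshtein(a, b) -> int:
    a, b = list(a), list(b)
    prev = list(range(len(b) + 1))
    for i, ca in enumerate(a, 1):
        cur = [i] + [0] * len(b)
        for j, cb in enumerate(b, 1):
            cur[j] = min(prev[j - 1] + (ca != cb), prev[j] + 1, cur[j - 1] + 1)
        prev = cur
    return prev[-1]


# ---------------------------------------------------------------------------
# filter validation statistics
# ---------------------------------------------------------------------------

def af_validation(utterances,
                  vad: afilter.VadConfig = afilter.VadConfig(),
                  boundary: afilter.BoundaryConfig = afilter.BoundaryConfig(),
                  weights: afilter.FilterWeights = afilter.FilterWeights(),
                  ) -> dict:
    """Mean AF activation per utterance, grouped by correctness, plus the
    severity rank correlation — the activation-level agreement analysis."""
    mean_af, severities, correct = [], [], []
    for utt in utterances:
        comp = afilter.build_filter(utt.waveform, utt.canonical_phonemes,
                                    utt.phoneme_tier, utt.word_tier,
                                    vad=vad, boundary=boundary,
                                    weights=weights)
        mean_af.append(float(comp.values.mean()))
        severities.append(utt.severity)
        correct.append(utt.correctness)
    mean_af = np.array(mean_af)
    correct = np.array(correct)
    out = {"mean_af": mean_af, "severities": np.array(severities),
           "correct": correct, "n": len(utterances)}
    if correct.sum() >= 2 and (~correct).sum() >= 2:
        gs = metrics.group_stats(mean_af[~correct], mean_af[correct])
        out["group_stats"] = gs
    rho, p = metrics.spearman(mean_af, severities)
    out["spearman_rho"], out["spearman_p"] = rho, p
    return out


# ---------------------------------------------------------------------------
# attribution study on a held-out split
# ---------------------------------------------------------------------------

def truth_error_mask(utt, fps: float, n_frames: int, t0: float = 0.0
                     ) -> np.ndarray:
    ivs = [iv for k in ("pause", "mispronunciation", "boundary")
           for iv in utt.truth_intervals.get(k, [])]
    return afilter.intervals_to_mask(ivs, fps, n_frames, "all", t0).values


def attribution_study(model: AqFilmClassifier, utterances, seed: int,
                      n_faithfulness: int = 50,
                      perturbation: acam.PerturbationConfig | None = None,
                      segments: acam.SegmentConfig = acam.SegmentConfig(),
                      faithfulness: metrics.FaithfulnessConfig = metrics.FaithfulnessConfig(),
                      ) -> dict:
    """Per-utterance impairment-map IoU (A-CAM vs plain Grad-CAM) against
    planted error regions, and deletion/insertion AUPC of the prediction
    map against a temporally shuffled random baseline."""
    perturbation = perturbation or acam.PerturbationConfig(seed=seed)
    iou_acam, iou_base = [], []
    del_acam, ins_acam, del_rand, ins_rand = [], [], [], []
    rng = np.random.default_rng([seed, 77])
    for idx, utt in enumerate(utterances):
        x = model.input_features(utt.waveform)
        fps, t0 = model.input_grid()
        exp = acam.explain(model, utt, perturbation=perturbation,
                           segments=segments)
        tru = truth_error_mask(utt, fps, x.shape[0], t0)
        if tru.any():
            imp_t = exp.impairment.temporal()
            base = acam.gradcam_baseline(model, x, utt.severity,
                                         exp.impairment.target_class,
                                         branch="impairment")
            base_t = base.temporal()
            iou_acam.append(metrics.frame_iou_dice(
                metrics.binarize_map(imp_t), tru)[0])
            iou_base.append(metrics.frame_iou_dice(
                metrics.binarize_map(base_t), tru)[0])
        if idx < n_faithfulness:
            pred_map = exp.prediction.raw
            c = exp.prediction.target_class
            d_c, i_c = metrics.deletion_insertion(model, x, utt.severity,
                                                  pred_map, c, faithfulness)
            rand_map = metrics.baseline_map("random", reference_map=pred_map,
                                            rng=rng, n_trials=50)
            d_r, i_r = metrics.deletion_insertion(model, x, utt.severity,
                                                  rand_map, c, faithfulness)
            del_acam.append(d_c.aupc)
            ins_acam.append(i_c.aupc)
            del_rand.append(d_r.aupc)
            ins_rand.append(i_r.aupc)
    return {
        "iou_impairment_acam": float(np.mean(iou_acam)) if iou_acam else float("nan"),
        "iou_impairment_base": float(np.mean(iou_base)) if iou_base else float("nan"),
        "n_iou": len(iou_acam),
        "deletion_aupc_acam": float(np.mean(del_acam)),
        "insertion_aupc_acam": float(np.mean(ins_acam)),
        "deletion_aupc_random": float(np.mean(del_rand)),
        "insertion_aupc_random": float(np.mean(ins_rand)),
        "n_faithfulness": len(del_acam),
    }
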