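# Methods

This note documents the models, procedures, parameter choices and known
limitations of `acamspeech`, in the order the pipeline runs.

## Synthetic disordered speech

The generator emulates confrontation-naming responses: 15 keyword classes,
each a fixed sequence of 2–9 phonemes drawn from a 32-symbol inventory.
A phoneme is rendered as band-limited Gaussian noise shaped by one or two
formant-like bands (center frequency, bandwidth, relative amplitude);
vowels carry two bands, consonants one dominant band.  Segments are
RMS-normalized to −20 dBFS with 5 ms cosine ramps.  Each utterance is
`[lead gap 80 ms] [filler word "uh"] [gap 80 ms] [keyword] [trail gap]`.
The filler word exists so that every utterance has exactly one word
boundary — single-word responses would make the boundary detector vacuous.

**Severity coupling.**  A speaker-level severity score AQ ∈ [20.5, 94.8]
(lower = more severe) maps linearly in (94.8 − AQ) to per-utterance anomaly
rates between a floor (mildest) and a ceiling (most severe):

| rate                     | floor → ceiling |
|--------------------------|-----------------|
| pauses per utterance     | 0 → 2.0 (Poisson count) |
| substitution prob/phoneme| 0 → 0.20 |
| deletion prob/phoneme    | 0 → 0.08 |
| insertion prob/phoneme   | 0 → 0.08 |
| boundary-shift prob/word | 0 → 0.60 |

Linear coupling was chosen for monotonicity and easy inversion in tests.
The ceilings are calibrated so that the intended keyword remains
identifiable even at the severe end — the clinical regime being emulated is
one where keyword classification is still ~96 % accurate despite frequent
production errors.  Substitutions draw from the 6 nearest inventory
neighbors by primary center frequency: phonemic paraphasias are
predominantly single-feature errors, so the produced sound is acoustically
close to the target rather than an arbitrary inventory draw.

**Anomaly realization.**  Pauses are −60 dBFS Gaussian noise (never digital
zero, so energy VAD is non-trivially exercised) inserted at keyword-internal
phoneme junctions, 0.3–0.6 s.  Substitutions/insertions/deletions edit both
the audio and the produced phoneme tier.  Boundary shifts widen the
inter-word gap by 0.35–0.6 s filled with a low-frequency filler hum at
−28 dBFS — above the VAD silence floor, so pause and boundary detections
stay disjoint.  Every edit is logged in `truth_intervals`; a deleted
phoneme, which leaves no produced audio, is logged as a ±20 ms window at
the junction between its flanking produced phonemes.  `correctness` is
true iff the mispronunciation and boundary truth lists are empty.

**Speakers and splits.**  A speaker surrogate is a fixed ±5 % multiplicative
perturbation of all recipe center frequencies plus a single severity score;
each utterance belongs to one speaker and speakers never span splits
(70/10/20 by speaker).  One RNG stream per utterance, derived from
(seed, index), makes generation order-independent and bit-reproducible.

**What the generator does not emulate:** naturalistic spectro-temporal
detail, prosody, coarticulation, semantic paraphasia/neologisms, channel
noise.  Passing tests therefore demonstrate the *mechanics* of the pipeline
(detection, gating, attribution arithmetic, statistical direction), not
performance on real clinical audio.

## Classifier

Input: log-mel spectrogram, 16 kHz, 25 ms window / 10 ms hop, 128 mel bins,
natural log with a 1e−6 floor, then a fixed affine (x + 7)/4 so inputs are
O(1).  The model (pure numpy, hand-written backpropagation):

1. **Band-split convolution** — 128 mel bins split into 8 bands of 16; each
   band convolved over time (kernel 5, stride 4, 8 channels, ReLU).  The
   flattened (T′ × 64) activation is the *prediction tap*; the channel→band
   map is retained so prediction relevance can be painted back onto its own
   mel bins.
2. **Projection + sinusoidal positions**, then a **2-layer pre-LN
   transformer encoder** (single head, width 64, FFN ×2).  Its output is
   the *impairment tap*.
3. **FiLM** — a 1→16→2H MLP maps the raw AQ scalar to (γ, β); the final
   layer starts at zero weights with the γ bias at 1 and β bias at 0, so an
   untrained generator is exactly the identity and the unconditioned
   backbone is recoverable (`use_film=False` matches it bit-for-bit).  AQ
   is deliberately not normalized; the first layer absorbs its scale.
4. **Global average pooling** over time, 2-layer MLP head, 15 logits.

Gradients with respect to both taps are produced in the same backward sweep
used for training; their correctness is pinned by central finite
differences (relative error < 1e−3 demanded; observed ~1e−8).

**Training** (the "toy" study): Adam (lr 3e−3, cosine decay to 0),
mini-batches of 16, gradient-norm clipping at 5, 45 epochs over 100
utterances per class.  Augmentation, applied only to training samples:
mel-axis roll of up to ±4 bins (a pitch-shift proxy matched to the
generator's speaker-frequency perturbation), Gaussian feature noise
(σ = 0.05), and span corruption — a random span up to 25 % of frames is
replaced by the utterance mean or by frames spliced from another training
utterance, which teaches the classifier to discount locally misleading
(substituted-phoneme-like) evidence.  All randomness is seeded; two runs
with one seed produce byte-identical checkpoints.

## Aphasia filter

* **VAD**: short-time RMS in dBFS (25 ms / 10 ms frames), silence below
  −40 dBFS, maximal silent runs ≥ T_P = 0.25 s.  Energy thresholding was
  chosen because it is transparent and parameterized; the method is a
  config key, as are both thresholds.
* **Alignment**: unit-cost edit distance between the canonical sequence and
  the produced tier, deterministic backtrace (substitution preferred over
  insertion+deletion; among equal-cost paths the canonical index advances
  first).  Non-match ops carry the produced segment's span; deletions
  borrow the midpoint gap between flanking produced segments, widened to at
  least 10 ms so they cannot vanish when rasterized.
* **Boundaries**: inter-word tier gaps > T_B = 0.30 s.
* **Rasterization**: frame-center containment in half-open intervals,
  0-based frames — stated once here, used everywhere.
* **Composition**: AF_W = 1.0·M_P + 1.2·M_M + 1.5·M_WB exactly, per frame;
  0 ≤ AF_W ≤ 3.7.  Resampling onto a feature-tap grid is
  nearest-frame-center lookup, so mask values are never interpolated across
  anomaly borders by more than one frame.

## Attribution

Defaults: N = 8 perturbations, σ₀ = 0.01, P_max = 0.1, step 0.01, Gaussian
noise on the model input; one σ track per branch so branches stay
independent.  Normalization divides by (mean G² + 1e−5) — the mean *square*,
not the RMS; an unusual scaling kept deliberately, and since it is a
positive scalar it only rescales maps.  Dual filtering keeps coordinates
where both the activation and the normalized gradient are positive.
Segments: t_seg = 25 tap frames, overlap 0.5, per-segment Gaussian
smoothing with σ = width/2 where width = 5 frames.  Aggregation places each
smoothed segment CAM on a full-length canvas and divides by per-frame
coverage — a plain mean over segments is ill-posed when segments have
different temporal supports; coverage averaging reduces to the plain mean
whenever supports coincide.  The canvas is linearly interpolated onto the
spectrogram time axis; the impairment branch broadcasts over the 128-bin
frequency axis (its tap is temporal), the prediction branch expands each
retained band onto its own 16 mel bins.

A terminal ReLU guarantees non-negative raw maps: segment CAMs contract
α ≥ 0 against raw features, which can be negative for transformer taps, so
without the ReLU the non-negativity contract would not hold.  ReLU commutes
with multiplication by any non-negative scalar, so the gating identities
(AF ≡ 0 ⇒ zero map; AF ≡ c scales the raw map by c) survive exactly.  Raw
and min–max display copies are kept separate so linearity remains
assertable on the raw map; metrics consume raw maps except where a
definition requires [0, 1] (ADCC coherency/complexity use the display
copy).

The plain Grad-CAM baseline (GAP gradient weights × features, ReLU, no
perturbation/filtering/gating) reduces from the full pipeline when N = 0,
the dual filter is dropped, and one global unsmoothed segment is used — up
to the positive scalar of gradient normalization (verified piecewise in the
tests).

## Metrics

Deletion/insertion: bins of the raw map ranked descending, ties broken by
grid order; K = 20 steps of 1/K each; masking is the baseline blend
x_masked = B + (x − B)·M with B = per-mel-bin input mean by default (zeros
offered); curves include step 0 and AUPC is the trapezoidal area over the
fraction axis.  ADCC is the harmonic mean of coherency (Pearson correlation
of the display map with itself recomputed on the map-masked input, clipped
to [0, 1]), 1 − complexity (complexity = mean |display map|) and
1 − average drop (max(0, f_c(x) − f_c(x⊙map))/f_c(x)).  Binarization:
strict-mean threshold per utterance, or Otsu (256 bins; a constant map
yields all zeros with a warning).  IoU/Dice treat two empty masks as
perfect agreement.  Group statistics: two-sided Mann–Whitney U (scipy),
Cohen's d with pooled SD, group-mean ratio; Spearman ρ with average ranks.
No multiple-testing correction is applied.  All statistics are two-sided.

## Study design and problem sizes

The packaged study uses 1 500 utterances (100 per class, ~150 speaker
surrogates), speaker-disjoint 70/10/20 splits, 45 training epochs; filter
validation runs on the full held-out split, the attribution study on 60
held-out utterances (50 for the faithfulness curves), detector recovery on
50 single-anomaly utterances, and ablations/ADCC on 30.  These sizes give
stable statistics while keeping a full run to a few CPU-minutes.

## Known limitations

* Acoustics are schematic; none of the results here quantify behavior on
  real aphasic speech.
* The impairment branch inherits every aphasia-filter error: a missed
  anomaly is gated out of the map.  Detectors are tier/energy-based, not
  acoustic-model-based forced alignment.
* Semantic (word-finding) errors are out of scope by design; the filter
  only sees acoustic-phonological structure.
* Removing dual filtering or perturbation does not reliably worsen
  deletion AUPC on this synthetic set (the acceptance script reports the
  measured values); the component ablation direction is a property of the
  full-scale clinical setting that the desk-scale study does not pin down.
* The deletion/insertion step count, baseline recipe, VAD internals,
  T_P, T_B, t_seg, overlap and smoothing width are declared defaults, all
  exposed as config keys.
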