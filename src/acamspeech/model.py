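"""Severity-conditioned spectrogram keyword classifier.

A compact network implementing the FiLM-conditioning pattern used for
severity-aware keyword classification in aphasic speech:

    log-mel (T x 128)
      -> band-split strided 1-D convolution over time (prediction tap F_cnn)
      -> linear projection + sinusoidal positions
      -> one pre-LN transformer encoder layer (impairment tap F_tf)
      -> FiLM: gamma(AQ) * F_tf + beta(AQ), broadcast over time
      -> global average pool over time -> 2-layer MLP head -> 15 logits

The Aphasia Quotient (AQ) enters the FiLM generator as a raw, unnormalized
scalar; the generator's first layer absorbs its scale.  The generator's
final layer starts at zero weights with the gamma bias at 1 and the beta
bias at 0, so an untrained generator is exactly the identity modulation and
the unconditioned backbone is recovered by construction.

Everything is plain numpy with hand-written backpropagation.  The backward
pass returns, in one sweep, the parameter gradients used for training and
the gradients of any logit with respect to the two feature taps

    G_cnn = d y_c / d F_cnn,     G_tf = d y_c / d F_tf

which are the raw material for the attribution pipeline.  Gradient
correctness is pinned down by central-finite-difference tests rather than
by an autodiff framework.

The prediction tap keeps a reduced frequency axis: the 128 mel bins are
split into ``n_bands`` contiguous bands and each band is convolved
separately, so channel ``k`` of F_cnn maps back to band ``k // band_channels``
(the axis map used when relevance is painted back onto the spectrogram).
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np

LOG_FLOOR = 1e-6
INPUT_SHIFT = 7.0    # fixed affine on log-mel so inputs are O(1)
INPUT_SCALE = 4.0


# ---------------------------------------------------------------------------
# log-mel front end (16 kHz, 25 ms window / 10 ms hop, 128 bins, natural log)
# ---------------------------------------------------------------------------

def mel_filterbank(n_mels: int = 128, n_fft: int = 512, sr: int = 16_000) -> np.ndarray:
    """Triangular mel filterbank (HTK mel scale), shape (n_mels, n_fft//2+1)."""
    def hz_to_mel(f):
        return 2595.0 * np.log10(1.0 + np.asarray(f) / 700.0)

    def mel_to_hz(m):
        return 700.0 * (10.0 ** (np.asarray(m) / 2595.0) - 1.0)

    mel_pts = np.linspace(hz_to_mel(0.0), hz_to_mel(sr / 2), n_mels + 2)
    hz_pts = mel_to_hz(mel_pts)
    fft_freqs = np.linspace(0, sr / 2, n_fft // 2 + 1)
    fb = np.zeros((n_mels, len(fft_freqs)))
    for i in range(n_mels):
        lo, ctr, hi = hz_pts[i], hz_pts[i + 1], hz_pts[i + 2]
        up = (fft_freqs - lo) / max(ctr - lo, 1e-12)
        down = (hi - fft_freqs) / max(hi - ctr, 1e-12)
        fb[i] = np.maximum(0.0, np.minimum(up, down))
    return fb


_FB_CACHE: dict[tuple, np.ndarray] = {}


def logmel(waveform: np.ndarray, sr: int = 16_000, n_mels: int = 128,
           win: int = 400, hop: int = 160, n_fft: int = 512) -> np.ndarray:
    """Log-mel spectrogram, shape (frames, n_mels); natural log, 1e-6 floor."""
    x = np.asarray(waveform, dtype=np.float64)
    if len(x) < win:
        x = np.pad(x, (0, win - len(x)))
    n_frames = 1 + (len(x) - win) // hop
    idx = np.arange(win)[None, :] + hop * np.arange(n_frames)[:, None]
    frames = x[idx] * np.hanning(win)[None, :]
    spec = np.abs(np.fft.rfft(frames, n=n_fft, axis=1)) ** 2
    key = (n_mels, n_fft, sr)
    if key not in _FB_CACHE:
        _FB_CACHE[key] = mel_filterbank(n_mels, n_fft, sr)
    mel = spec @ _FB_CACHE[key].T
    return np.log(np.maximum(mel, LOG_FLOOR))


def mel_frame_grid(hop: int = 160, win: int = 400, sr: int = 16_000):
    """(frames-per-second, time of frame-0 center) of the log-mel grid."""
    return sr / hop, (win / 2) / sr


# ---------------------------------------------------------------------------
# configuration / containers
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class ModelConfig:
    n_mels: int = 128
    win: int = 400
    hop: int = 160
    n_fft: int = 512
    n_bands: int = 8
    band_channels: int = 8
    conv_kernel: int = 5
    conv_stride: int = 4
    n_layers: int = 2
    hidden: int = 64
    ffn_mult: int = 2
    film_hidden: int = 16
    n_classes: int = 15
    epochs: int = 45
    batch_size: int = 16
    lr: float = 3e-3
    aug_noise: float = 0.05     # train-time Gaussian noise on features
    aug_max_shift: int = 4      # train-time mel-axis roll (pitch-shift proxy)
    aug_time_mask: float = 0.25  # max fraction of frames time-masked
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_classes != 15:
            raise ValueError("this classifier is a 15-way keyword model")
        if self.n_mels % self.n_bands != 0:
            raise ValueError("n_mels must divide evenly into n_bands")


@dataclasses.dataclass
class FilmParams:
    gamma: np.ndarray
    beta: np.ndarray

    def __post_init__(self) -> None:
        self.gamma = np.asarray(self.gamma, dtype=np.float64)
        self.beta = np.asarray(self.beta, dtype=np.float64)
        if self.gamma.shape != self.beta.shape:
            raise ValueError("gamma and beta must have equal shapes")
        if not (np.isfinite(self.gamma).all() and np.isfinite(self.beta).all()):
            raise ValueError("FiLM parameters must be finite")


@dataclasses.dataclass
class FeatureTap:
    branch: str               # "prediction" | "impairment"
    values: np.ndarray        # (T, K)
    fps: float
    t0: float                 # time of frame-0 center, seconds
    band_map: np.ndarray | None = None  # channel -> mel-band index (prediction)


@dataclasses.dataclass
class ModelOutputs:
    logits: np.ndarray
    probabilities: np.ndarray
    taps: dict[str, FeatureTap]


@dataclasses.dataclass
class GradientMap:
    branch: str
    values: np.ndarray


def film_modulate(features: np.ndarray, params: FilmParams) -> np.ndarray:
    """out[t, h] = gamma[h] * features[t, h] + beta[h]."""
    features = np.asarray(features, dtype=np.float64)
    if features.ndim != 2 or features.shape[1] != params.gamma.shape[0]:
        raise ValueError(
            f"feature width {features.shape} does not match FiLM width "
            f"{params.gamma.shape[0]}")
    return params.gamma[None, :] * features + params.beta[None, :]


# ---------------------------------------------------------------------------
# the classifier
# ---------------------------------------------------------------------------

def _layernorm_forward(x, g, b, eps=1e-5):
    mu = x.mean(axis=1, keepdims=True)
    var = x.var(axis=1, keepdims=True)
    inv = 1.0 / np.sqrt(var + eps)
    xhat = (x - mu) * inv
    return xhat * g + b, (xhat, inv, g)


def _layernorm_backward(dy, cache):
    xhat, inv, g = cache
    dxhat = dy * g
    m1 = dxhat.mean(axis=1, keepdims=True)
    m2 = (dxhat * xhat).mean(axis=1, keepdims=True)
    dx = inv * (dxhat - m1 - xhat * m2)
    dg = (dy * xhat).sum(axis=0)
    db = dy.sum(axis=0)
    return dx, dg, db


class AqFilmClassifier:
    """15-way keyword classifier conditioned on a raw severity scalar."""

    def __init__(self, config: ModelConfig | None = None):
        self.config = config or ModelConfig()
        self.params: dict[str, np.ndarray] = {}
        self._init_params()

    # -- initialization ----------------------------------------------------
    def _init_params(self) -> None:
        c = self.config
        rng = np.random.default_rng(c.seed)
        H = c.hidden
        bw = c.n_mels // c.n_bands          # mel bins per band
        kin = c.conv_kernel * bw
        K = c.n_bands * c.band_channels     # prediction-tap channels

        def glorot(*shape):
            fan = shape[-2] + shape[-1] if len(shape) >= 2 else sum(shape)
            return rng.normal(0.0, np.sqrt(2.0 / fan), size=shape)

        p = {
            "conv_w": glorot(c.n_bands, kin, c.band_channels),
            "conv_b": np.zeros((c.n_bands, c.band_channels)),
            "proj_w": glorot(K, H),
            "proj_b": np.zeros(H),
            # FiLM generator: zero final weights, gamma bias 1, beta bias 0
            "film_w1": rng.normal(0.0, 0.01, size=(1, c.film_hidden)),
            "film_b1": np.zeros(c.film_hidden),
            "film_w2": np.zeros((c.film_hidden, 2 * H)),
            "film_b2": np.concatenate([np.ones(H), np.zeros(H)]),
            "head_w1": glorot(H, H), "head_b1": np.zeros(H),
            "head_w2": glorot(H, c.n_classes), "head_b2": np.zeros(c.n_classes),
        }
        for li in range(c.n_layers):
            p.update({
                f"L{li}_ln1_g": np.ones(H), f"L{li}_ln1_b": np.zeros(H),
                f"L{li}_wq": glorot(H, H), f"L{li}_wk": glorot(H, H),
                f"L{li}_wv": glorot(H, H), f"L{li}_wo": glorot(H, H),
                f"L{li}_ln2_g": np.ones(H), f"L{li}_ln2_b": np.zeros(H),
                f"L{li}_ffn_w1": glorot(H, c.ffn_mult * H),
                f"L{li}_ffn_b1": np.zeros(c.ffn_mult * H),
                f"L{li}_ffn_w2": glorot(c.ffn_mult * H, H),
                f"L{li}_ffn_b2": np.zeros(H),
            })
        self.params = p
        self._pe_cache: np.ndarray | None = None

    def _pe(self, T: int) -> np.ndarray:
        H = self.config.hidden
        if self._pe_cache is None or self._pe_cache.shape[0] < T:
            n = max(T, 512)
            pos = np.arange(n)[:, None]
            i = np.arange(H // 2)[None, :]
            ang = pos / (10000.0 ** (2 * i / H))
            pe = np.zeros((n, H))
            pe[:, 0::2] = np.sin(ang)
            pe[:, 1::2] = np.cos(ang)
            self._pe_cache = pe
        return self._pe_cache[:T]

    # -- feature extraction ------------------------------------------------
    def input_features(self, waveform: np.ndarray) -> np.ndarray:
        """Normalized log-mel, the tensor the model (and all perturbation /
        deletion / insertion machinery) operates on."""
        c = self.config
        lm = logmel(waveform, n_mels=c.n_mels, win=c.win, hop=c.hop,
                    n_fft=c.n_fft)
        return (lm + INPUT_SHIFT) / INPUT_SCALE

    def input_grid(self):
        return mel_frame_grid(self.config.hop, self.config.win)

    def tap_grid(self):
        """(fps, t0) of the subsampled tap grid shared by both taps."""
        fps, t0 = self.input_grid()
        c = self.config
        t0_tap = t0 + ((c.conv_kernel - 1) / 2) / fps
        return fps / c.conv_stride, t0_tap

    # -- FiLM generator ----------------------------------------------------
    def film_generate(self, severity: float) -> FilmParams:
        if not np.isfinite(severity):
            raise ValueError(f"severity must be finite, got {severity!r}")
        p = self.params
        H = self.config.hidden
        u = np.tanh(float(severity) * p["film_w1"][0] + p["film_b1"])
        out = u @ p["film_w2"] + p["film_b2"]
        return FilmParams(gamma=out[:H], beta=out[H:])

    # -- forward -----------------------------------------------------------
    def forward(self, x: np.ndarray, severity: float, *,
                use_film: bool = True,
                film_params: FilmParams | None = None,
                tap_override: dict[str, np.ndarray] | None = None,
                want_cache: bool = False):
        """Run the network on a normalized log-mel input (T x n_mels).

        Returns :class:`ModelOutputs` (and the backward cache when
        ``want_cache``).  ``tap_override`` substitutes a tensor for a tap and
        recomputes everything downstream, which gives an independent handle
        for finite-difference checks.
        """
        c = self.config
        p = self.params
        x = np.asarray(x, dtype=np.float64)
        if x.ndim != 2 or x.shape[1] != c.n_mels:
            raise ValueError(f"expected (T, {c.n_mels}) input, got {x.shape}")
        tap_override = tap_override or {}
        T = x.shape[0]
        bw = c.n_mels // c.n_bands
        ker, st = c.conv_kernel, c.conv_stride
        if T < ker:
            x = np.vstack([x, np.tile(x[-1:], (ker - T, 1))])
            T = ker
        T1 = (T - ker) // st + 1

        # band-split conv
        xb = x.reshape(T, c.n_bands, bw)
        idx = np.arange(T1)[:, None] * st + np.arange(ker)[None, :]
        cols = xb[idx]                                   # (T1, ker, B, bw)
        cols = cols.transpose(0, 2, 1, 3).reshape(T1, c.n_bands, ker * bw)
        conv = np.einsum("tbi,bic->tbc", cols, p["conv_w"]) + p["conv_b"]
        relu_mask = conv > 0
        f_cnn = np.where(relu_mask, conv, 0.0).reshape(T1, -1)   # (T1, K)
        if "prediction" in tap_override:
            f_cnn = np.asarray(tap_override["prediction"], dtype=np.float64)

        # projection + positions
        z0 = f_cnn @ p["proj_w"] + p["proj_b"] + self._pe(T1)

        # transformer encoder stack (pre-LN, single-head)
        scale = 1.0 / np.sqrt(c.hidden)
        z = z0
        layer_caches = []
        for li in range(c.n_layers):
            h1, ln1c = _layernorm_forward(z, p[f"L{li}_ln1_g"],
                                          p[f"L{li}_ln1_b"])
            q, k, v = h1 @ p[f"L{li}_wq"], h1 @ p[f"L{li}_wk"], h1 @ p[f"L{li}_wv"]
            s = (q @ k.T) * scale
            s = s - s.max(axis=1, keepdims=True)
            a = np.exp(s)
            a /= a.sum(axis=1, keepdims=True)
            o = a @ v
            z1 = z + o @ p[f"L{li}_wo"]
            h2, ln2c = _layernorm_forward(z1, p[f"L{li}_ln2_g"],
                                          p[f"L{li}_ln2_b"])
            ffn_pre = h2 @ p[f"L{li}_ffn_w1"] + p[f"L{li}_ffn_b1"]
            ffn_mask = ffn_pre > 0
            ffn_act = np.where(ffn_mask, ffn_pre, 0.0)
            z_next = z1 + ffn_act @ p[f"L{li}_ffn_w2"] + p[f"L{li}_ffn_b2"]
            layer_caches.append(dict(ln1c=ln1c, h1=h1, q=q, k=k, v=v, a=a,
                                     o=o, z1=z1, ln2c=ln2c, h2=h2,
                                     ffn_mask=ffn_mask, ffn_act=ffn_act))
            z = z_next
        f_tf = z                                                 # (T1, H)
        if "impairment" in tap_override:
            f_tf = np.asarray(tap_override["impairment"], dtype=np.float64)

        # FiLM
        film_cache = None
        if film_params is not None:
            fp = film_params
        elif use_film:
            u = np.tanh(float(severity) * p["film_w1"][0] + p["film_b1"])
            out = u @ p["film_w2"] + p["film_b2"]
            H = c.hidden
            fp = FilmParams(gamma=out[:H], beta=out[H:])
            film_cache = u
        else:
            fp = FilmParams(gamma=np.ones(c.hidden), beta=np.zeros(c.hidden))
        mod = fp.gamma[None, :] * f_tf + fp.beta[None, :]

        pooled = mod.mean(axis=0)
        head_pre = pooled @ p["head_w1"] + p["head_b1"]
        head_mask = head_pre > 0
        head_act = np.where(head_mask, head_pre, 0.0)
        logits = head_act @ p["head_w2"] + p["head_b2"]
        lmax = logits.max()
        e = np.exp(logits - lmax)
        probs = e / e.sum()

        fps_tap, t0_tap = self.tap_grid()
        taps = {
            "prediction": FeatureTap(
                "prediction", f_cnn, fps_tap, t0_tap,
                band_map=np.repeat(np.arange(c.n_bands), c.band_channels)),
            "impairment": FeatureTap("impairment", f_tf, fps_tap, t0_tap),
        }
        outputs = ModelOutputs(logits=logits, probabilities=probs, taps=taps)
        if not want_cache:
            return outputs
        cache = dict(x=x, cols=cols, relu_mask=relu_mask, f_cnn=f_cnn,
                     z0=z0, layers=layer_caches, f_tf=f_tf, fp=fp,
                     film_cache=film_cache, mod=mod, pooled=pooled,
                     head_mask=head_mask, head_act=head_act, probs=probs,
                     T1=T1, severity=float(severity),
                     override=set(tap_override))
        return outputs, cache

    def predict_proba(self, x: np.ndarray, severity: float) -> np.ndarray:
        return self.forward(x, severity).probabilities

    # -- backward ----------------------------------------------------------
    def backward(self, cache, dlogits: np.ndarray,
                 want_param_grads: bool = False):
        """Backpropagate an arbitrary cotangent on the logits.

        Returns ``(tap_grads, param_grads)`` where ``tap_grads`` maps branch
        name to the gradient with respect to that tap's values.
        """
        c, p = self.config, self.params
        H = c.hidden
        g: dict[str, np.ndarray] = {}

        d_head_act = dlogits @ p["head_w2"].T
        if want_param_grads:
            g["head_w2"] = np.outer(cache["head_act"], dlogits)
            g["head_b2"] = dlogits.copy()
        d_head_pre = d_head_act * cache["head_mask"]
        d_pooled = d_head_pre @ p["head_w1"].T
        if want_param_grads:
            g["head_w1"] = np.outer(cache["pooled"], d_head_pre)
            g["head_b1"] = d_head_pre.copy()

        T1 = cache["T1"]
        d_mod = np.tile(d_pooled / T1, (T1, 1))
        fp = cache["fp"]
        d_f_tf = d_mod * fp.gamma[None, :]
        if want_param_grads and cache["film_cache"] is not None:
            d_gamma = (d_mod * cache["f_tf"]).sum(axis=0)
            d_beta = d_mod.sum(axis=0)
            d_out = np.concatenate([d_gamma, d_beta])
            u = cache["film_cache"]
            g["film_w2"] = np.outer(u, d_out)
            g["film_b2"] = d_out
            d_u = p["film_w2"] @ d_out
            d_pre = d_u * (1.0 - u ** 2)
            g["film_w1"] = (cache["severity"] * d_pre)[None, :]
            g["film_b1"] = d_pre

        tap_grads = {"impairment": d_f_tf.copy()}
        if "impairment" in cache["override"]:
            # the tap was substituted: nothing upstream depends on it
            zeros_cnn = np.zeros_like(cache["f_cnn"])
            tap_grads["prediction"] = zeros_cnn
            return tap_grads, g

        scale = 1.0 / np.sqrt(H)
        d_z = d_f_tf
        for li in reversed(range(c.n_layers)):
            lc = cache["layers"][li]
            # FFN sublayer
            d_z1 = d_z.copy()
            d_ffn_act = d_z @ p[f"L{li}_ffn_w2"].T
            if want_param_grads:
                g[f"L{li}_ffn_w2"] = lc["ffn_act"].T @ d_z
                g[f"L{li}_ffn_b2"] = d_z.sum(axis=0)
            d_ffn_pre = d_ffn_act * lc["ffn_mask"]
            d_h2 = d_ffn_pre @ p[f"L{li}_ffn_w1"].T
            if want_param_grads:
                g[f"L{li}_ffn_w1"] = lc["h2"].T @ d_ffn_pre
                g[f"L{li}_ffn_b1"] = d_ffn_pre.sum(axis=0)
            dz, dg2, db2 = _layernorm_backward(d_h2, lc["ln2c"])
            if want_param_grads:
                g[f"L{li}_ln2_g"], g[f"L{li}_ln2_b"] = dg2, db2
            d_z1 += dz
            # attention sublayer
            d_o = d_z1 @ p[f"L{li}_wo"].T
            if want_param_grads:
                g[f"L{li}_wo"] = lc["o"].T @ d_z1
            a, q, k, v = lc["a"], lc["q"], lc["k"], lc["v"]
            d_a = d_o @ v.T
            d_v = a.T @ d_o
            d_s = a * (d_a - (d_a * a).sum(axis=1, keepdims=True))
            d_q = d_s @ k * scale
            d_k = d_s.T @ q * scale
            h1 = lc["h1"]
            if want_param_grads:
                g[f"L{li}_wq"] = h1.T @ d_q
                g[f"L{li}_wk"] = h1.T @ d_k
                g[f"L{li}_wv"] = h1.T @ d_v
            d_h1 = (d_q @ p[f"L{li}_wq"].T + d_k @ p[f"L{li}_wk"].T
                    + d_v @ p[f"L{li}_wv"].T)
            dz_in, dg1, db1 = _layernorm_backward(d_h1, lc["ln1c"])
            if want_param_grads:
                g[f"L{li}_ln1_g"], g[f"L{li}_ln1_b"] = dg1, db1
            d_z = d_z1 + dz_in
        d_z0 = d_z

        # projection
        d_f_cnn = d_z0 @ p["proj_w"].T
        if want_param_grads:
            g["proj_w"] = cache["f_cnn"].T @ d_z0
            g["proj_b"] = d_z0.sum(axis=0)
        tap_grads["prediction"] = d_f_cnn.copy()

        if want_param_grads and "prediction" not in cache["override"]:
            bw = c.n_mels // c.n_bands
            d_conv = (d_f_cnn.reshape(T1, c.n_bands, c.band_channels)
                      * cache["relu_mask"])
            g["conv_w"] = np.einsum("tbi,tbc->bic", cache["cols"], d_conv)
            g["conv_b"] = d_conv.sum(axis=0)
        return tap_grads, g

    # -- public gradient APIs ---------------------------------------------
    def class_gradient(self, x: np.ndarray, severity: float, target: int,
                       tap_override: dict[str, np.ndarray] | None = None,
                       ) -> dict[str, GradientMap]:
        """d y_c / d tap, for each branch, in a single backward sweep."""
        c = self.config
        if not 0 <= target < c.n_classes:
            raise ValueError(f"target class must be in [0, {c.n_classes - 1}]")
        _, cache = self.forward(x, severity, tap_override=tap_override,
                                want_cache=True)
        dlogits = np.zeros(c.n_classes)
        dlogits[target] = 1.0
        tap_grads, _ = self.backward(cache, dlogits)
        return {b: GradientMap(branch=b, values=v)
                for b, v in tap_grads.items()}

    def forward_with_taps(self, x: np.ndarray, severity: float) -> ModelOutputs:
        return self.forward(x, severity)

    # -- persistence -------------------------------------------------------
    def save(self, path: str | Path, extra: dict | None = None) -> None:
        meta = {"config": dataclasses.asdict(self.config),
                "spectrogram": {"sr": 16_000, "win": self.config.win,
                                "hop": self.config.hop,
                                "n_mels": self.config.n_mels,
                                "log": "natural, 1e-6 floor"},
                "extra": extra or {}}
        np.savez(str(path), __meta__=np.frombuffer(
            json.dumps(meta, sort_keys=True).encode(), dtype=np.uint8),
            **self.params)

    @classmethod
    def load(cls, path: str | Path) -> "AqFilmClassifier":
        with np.load(str(path)) as z:
            meta = json.loads(bytes(z["__meta__"].tobytes()).decode())
            model = cls(ModelConfig(**meta["config"]))
            for k in model.params:
                model.params[k] = z[k].copy()
        return model


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class TrainReport:
    accuracy: dict[str, float]
    losses: list[float]
    seed: int


def train_toy(model: AqFilmClassifier, utterances, splits,
              config: ModelConfig | None = None,
              checkpoint: str | Path | None = None) -> TrainReport:
    """Train on an in-memory corpus with speaker-disjoint split tags.

    Plain Adam over per-sample gradients accumulated into mini-batches;
    deterministic given ``config.seed``.
    """
    c = config or model.config
    by_split: dict[str, list[int]] = {"train": [], "val": [], "test": []}
    for i, s in enumerate(splits):
        by_split.setdefault(s, []).append(i)
    if not by_split["train"]:
        raise ValueError("empty training split")

    feats = [model.input_features(u.waveform) for u in utterances]
    sevs = [u.severity for u in utterances]
    labels = [u.keyword_id for u in utterances]

    rng = np.random.default_rng(c.seed + 1)
    m_state = {k: np.zeros_like(v) for k, v in model.params.items()}
    v_state = {k: np.zeros_like(v) for k, v in model.params.items()}
    beta1, beta2, eps = 0.9, 0.999, 1e-8
    step = 0
    losses = []
    train_idx = np.array(by_split["train"])
    for epoch in range(c.epochs):
        lr = c.lr * (0.5 * (1 + np.cos(np.pi * epoch / max(c.epochs - 1, 1))))
        order = rng.permutation(len(train_idx))
        epoch_loss = 0.0
        for start in range(0, len(order), c.batch_size):
            batch = train_idx[order[start:start + c.batch_size]]
            grads_sum: dict[str, np.ndarray] = {}
            for i in batch:
                f = feats[i]
                # augmentation: mel-axis roll (a pitch-shift proxy matching
                # the generator's speaker-frequency perturbation) + noise
                if c.aug_max_shift > 0:
                    shift = int(rng.integers(-c.aug_max_shift,
                                             c.aug_max_shift + 1))
                    if shift:
                        f = np.roll(f, shift, axis=1)
                if c.aug_time_mask > 0:
                    # corruption augmentation: overwrite a random span with
                    # either its mean (a blank mask) or frames spliced from
                    # another training utterance, so the classifier learns
                    # to aggregate distributed evidence and to discount
                    # locally misleading (substituted-phoneme-like) spans
                    span = int(rng.integers(
                        0, max(1, int(c.aug_time_mask * f.shape[0])) + 1))
                    if span:
                        s0 = int(rng.integers(0, f.shape[0] - span + 1))
                        f = f.copy()
                        if rng.random() < 0.5:
                            f[s0:s0 + span] = f.mean(axis=0, keepdims=True)
                        else:
                            j = int(train_idx[rng.integers(len(train_idx))])
                            donor = feats[j]
                            take = min(span, donor.shape[0])
                            d0 = int(rng.integers(0, donor.shape[0] - take + 1))
                            f[s0:s0 + take] = donor[d0:d0 + take]
                if c.aug_noise > 0:
                    f = f + rng.normal(0.0, c.aug_noise, size=f.shape)
                out, cache = model.forward(f, sevs[i], want_cache=True)
                probs = out.probabilities
                epoch_loss += -np.log(max(probs[labels[i]], 1e-12))
                dlogits = probs.copy()
                dlogits[labels[i]] -= 1.0
                _, g = model.backward(cache, dlogits, want_param_grads=True)
                for k2, v2 in g.items():
                    grads_sum[k2] = grads_sum.get(k2, 0.0) + v2
            step += 1
            for k2, gsum in grads_sum.items():
                gk = gsum / len(batch)
                nrm = np.linalg.norm(gk)
                if nrm > 5.0:
                    gk = gk * (5.0 / nrm)
                m_state[k2] = beta1 * m_state[k2] + (1 - beta1) * gk
                v_state[k2] = beta2 * v_state[k2] + (1 - beta2) * gk ** 2
                mhat = m_state[k2] / (1 - beta1 ** step)
                vhat = v_state[k2] / (1 - beta2 ** step)
                model.params[k2] = model.params[k2] - lr * mhat / (
                    np.sqrt(vhat) + eps)
        losses.append(epoch_loss / len(train_idx))

    def acc(idxs):
        if not idxs:
            return float("nan")
        hits = sum(int(np.argmax(model.predict_proba(feats[i], sevs[i]))
                       == labels[i]) for i in idxs)
        return hits / len(idxs)

    report = TrainReport(
        accuracy={s: acc(ix) for s, ix in by_split.items()},
        losses=losses, seed=c.seed)
    if checkpoint is not None:
        model.save(checkpoint, extra={"accuracy": report.accuracy,
                                      "seed": c.seed})
    return report
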