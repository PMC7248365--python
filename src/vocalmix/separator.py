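"""The MLP singing-voice separator: features, model, training, inference.

The separator regresses the magnitude spectra of the vocal and instrument
sources from the magnitude spectrogram of the mixture.  The network is a
single-hidden-layer perceptron operating on a causal context of three
consecutive frames:

* input: 3 x 513 = 1539 units (frames t-2, t-1, t of the scaled mixture
  magnitude),
* hidden: 1024 rectified-linear units (dropout during training),
* output: 2 x 513 = 1026 rectified-linear units, the first half being the
  vocal magnitude spectrum of frame t and the second half the instruments
  spectrum.

Training minimizes the mean squared error between predicted and true
magnitude spectra of both sources jointly, with Adam, mini-batches of 128
frame rows pooled across all training tracks, an initial learning rate of
0.005 multiplied by 0.9 after every epoch, and dropout probability 0.8 on
the hidden layer.  Magnitudes are divided by a single scalar (the 99th
percentile of the training mixture magnitudes) before entering the
network; the scalar is stored in the model and reapplied at inference.

The context is causal ([t-2, t-1, t] predicting frame t) so that
separation adds no lookahead beyond the one-hop block latency.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

import numpy as np

from .dsp import (
    AudioSignal,
    MagnitudeSpectrogram,
    STFTConfig,
    Spectrogram,
    resynthesize_with_mixture_phase,
    stft,
)

__all__ = [
    "SourcePair",
    "ContextFeatures",
    "SeparatorModel",
    "OracleModel",
    "TrainConfig",
    "DatasetSplit",
    "Corpus",
    "stack_context",
    "forward",
    "train",
    "separate",
    "chunk_and_split",
    "save_checkpoint",
    "load_checkpoint",
]

CHECKPOINT_VERSION = "vocalmix-checkpoint-1"


@dataclass
class SourcePair:
    """Time-aligned vocal and instruments signals with their mixture.

    For ground-truth data the mixture is the sample-wise sum of the two
    sources (checked to 1e-9 unless ``strict=False``, which is used for
    *estimated* pairs whose components do not sum to the input mixture).
    """

    vocal: AudioSignal
    instruments: AudioSignal
    mixture: AudioSignal
    identifier: str = ""
    strict: bool = True

    def __post_init__(self) -> None:
        if not (len(self.vocal) == len(self.instruments) == len(self.mixture)):
            raise ValueError("vocal, instruments and mixture must have equal length")
        if not (self.vocal.rate == self.instruments.rate == self.mixture.rate):
            raise ValueError("vocal, instruments and mixture must share a sample rate")
        if self.strict:
            err = np.max(
                np.abs(self.mixture.samples - self.vocal.samples - self.instruments.samples),
                initial=0.0,
            )
            if err > 1e-9:
                raise ValueError(
                    f"mixture differs from vocal + instruments by {err:.3g} (> 1e-9)"
                )

    @classmethod
    def from_sources(cls, vocal: AudioSignal, instruments: AudioSignal, identifier: str = "") -> "SourcePair":
        mixture = AudioSignal(vocal.samples + instruments.samples, vocal.rate)
        return cls(vocal, instruments, mixture, identifier)

    @property
    def rate(self) -> int:
        return self.mixture.rate

    def __len__(self) -> int:
        return len(self.mixture)


@dataclass
class ContextFeatures:
    """Stacked causal context rows: row t = [frame t-2, frame t-1, frame t]."""

    rows: np.ndarray  # (n_frames, 3 * n_bins)
    config: STFTConfig
    origin_length: int
    rate: int

    def __post_init__(self) -> None:
        self.rows = np.asarray(self.rows)
        if self.rows.ndim != 2 or self.rows.shape[1] != 3 * self.config.n_bins:
            raise ValueError(
                f"context rows must have dimension {3 * self.config.n_bins}, "
                f"got shape {self.rows.shape}"
            )

    @property
    def n_frames(self) -> int:
        return self.rows.shape[0]


def stack_context(mag: MagnitudeSpectrogram) -> ContextFeatures:
    """Stack three consecutive magnitude frames into causal input rows.

    Row ``t`` is the concatenation ``[frame(t-2), frame(t-1), frame(t)]``;
    frames at negative indices are all-zero.  Successive rows advance by
    one frame, so consecutive rows share two frames of context.
    """
    if mag.n_frames == 0:
        raise ValueError("cannot stack context of an empty spectrogram")
    f = mag.frames
    zero = np.zeros((1, f.shape[1]), dtype=f.dtype)
    prev1 = np.vstack([zero, f[:-1]])
    prev2 = np.vstack([zero, zero, f[:-2]]) if f.shape[0] >= 2 else zero.copy()
    rows = np.hstack([prev2[: f.shape[0]], prev1, f])
    return ContextFeatures(rows, mag.config, mag.origin_length, mag.rate)


@dataclass(frozen=True)
class TrainConfig:
    """Training recipe of the separator network."""

    batch_size: int = 128
    initial_lr: float = 0.005
    lr_decay_per_epoch: float = 0.9
    epochs: int = 100
    dropout_prob: float = 0.8  # probability of *dropping* a hidden unit
    hidden_units: int = 1024
    seed: int = 0
    adam_beta1: float = 0.9
    adam_beta2: float = 0.999
    adam_eps: float = 1e-8
    scale_percentile: float = 99.0

    def __post_init__(self) -> None:
        if not 0 <= self.dropout_prob < 1:
            raise ValueError("dropout_prob must be in [0, 1)")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")

    def learning_rate(self, epoch: int) -> float:
        """Learning rate entering ``epoch`` (0-based): lr0 * decay**epoch."""
        return self.initial_lr * self.lr_decay_per_epoch**epoch


@dataclass
class SeparatorModel:
    """Weights and metadata of the trained two-source magnitude regressor.

    ``w1``/``b1`` map the 3x513 context row to the hidden layer,
    ``w2``/``b2`` map the rectified hidden activation to the 2x513 output,
    which is rectified again so predicted magnitudes are non-negative.
    ``input_scale`` is the scalar magnitude normalizer learned from the
    training data; features entering :meth:`predict` must already be
    divided by it, and predictions come back on the same scaled axis.
    """

    w1: np.ndarray
    b1: np.ndarray
    w2: np.ndarray
    b2: np.ndarray
    input_scale: float
    stft_config: STFTConfig = field(default_factory=STFTConfig)
    train_config: TrainConfig | None = None
    mask_mode: bool = False  # if True, outputs are used as a ratio mask on |X|
    version: str = CHECKPOINT_VERSION

    def __post_init__(self) -> None:
        for name in ("w1", "b1", "w2", "b2"):
            arr = np.asarray(getattr(self, name), dtype=np.float64)
            setattr(self, name, arr)
            if not np.all(np.isfinite(arr)):
                raise ValueError(f"model parameter {name} contains non-finite values")
        if self.w1.shape[1] != self.w2.shape[0]:
            raise ValueError("hidden dimensions of w1 and w2 disagree")
        if self.w2.shape[1] % 2 != 0:
            raise ValueError("output dimension must be even (two source spectra)")
        if self.input_scale <= 0:
            raise ValueError("input_scale must be positive")

    @property
    def input_dim(self) -> int:
        return self.w1.shape[0]

    @property
    def output_dim(self) -> int:
        return self.w2.shape[1]

    @property
    def n_bins(self) -> int:
        return self.output_dim // 2

    def predict(self, rows: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Rectified affine map on scaled feature rows -> scaled magnitudes.

        Dropout is inactive at inference.  Returns ``(vocal, instruments)``
        row arrays, each of width ``output_dim / 2``, non-negative.
        """
        rows = np.asarray(rows, dtype=np.float64)
        if rows.ndim != 2 or rows.shape[1] != self.input_dim:
            raise ValueError(
                f"feature rows must have dimension {self.input_dim}, got {rows.shape}"
            )
        h = np.maximum(rows @ self.w1 + self.b1, 0.0)
        out = np.maximum(h @ self.w2 + self.b2, 0.0)
        return out[:, : self.n_bins], out[:, self.n_bins :]


class OracleModel:
    """Stub separator returning stored ground-truth magnitudes.

    Used to measure the upper bound of the mixture-phase pipeline (ideal
    magnitudes, mixture phase) and as a deterministic stand-in for a
    trained network in pipeline tests.  ``predict`` ignores its input rows
    apart from their count, which must match the stored spectra.
    """

    def __init__(self, vocal_mag: MagnitudeSpectrogram, instr_mag: MagnitudeSpectrogram,
                 stft_config: STFTConfig | None = None):
        self.vocal_frames = vocal_mag.frames
        self.instr_frames = instr_mag.frames
        self.input_scale = 1.0
        self.stft_config = stft_config or vocal_mag.config
        self.mask_mode = False
        self.n_bins = vocal_mag.frames.shape[1]
        self._cursor = 0

    def predict(self, rows: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        n = rows.shape[0]
        start = self._cursor if n < self.vocal_frames.shape[0] else 0
        if n == self.vocal_frames.shape[0]:
            return self.vocal_frames, self.instr_frames
        v = self.vocal_frames[start : start + n]
        i = self.instr_frames[start : start + n]
        self._cursor = start + n
        return v, i


def forward(
    model: SeparatorModel, feats: ContextFeatures
) -> tuple[MagnitudeSpectrogram, MagnitudeSpectrogram]:
    """Run the separator on context features, returning magnitude spectra.

    The feature rows are assumed to be on the model's scaled axis (i.e.
    already divided by ``input_scale``); the returned spectrograms are in
    physical magnitude units (multiplied back by ``input_scale``).
    """
    v, i = model.predict(feats.rows)
    scale = model.input_scale
    mk = lambda frames: MagnitudeSpectrogram(
        frames * scale, feats.config, feats.origin_length, feats.rate
    )
    return mk(v), mk(i)


def _magnitude_dataset(
    pairs: list[SourcePair], stft_cfg: STFTConfig
) -> tuple[list[np.ndarray], list[np.ndarray], list[np.ndarray]]:
    """Per-pair magnitude spectrogram frames of mixture, vocal, instruments."""
    mix, voc, ins = [], [], []
    for p in pairs:
        mix.append(np.abs(stft(p.mixture, stft_cfg).frames))
        voc.append(np.abs(stft(p.vocal, stft_cfg).frames))
        ins.append(np.abs(stft(p.instruments, stft_cfg).frames))
    return mix, voc, ins


def _context_rows(mag_frames: np.ndarray) -> np.ndarray:
    zero = np.zeros((1, mag_frames.shape[1]), dtype=mag_frames.dtype)
    prev1 = np.vstack([zero, mag_frames[:-1]])
    prev2 = np.vstack([zero, zero, mag_frames[:-2]]) if mag_frames.shape[0] >= 2 else zero.copy()
    return np.hstack([prev2[: mag_frames.shape[0]], prev1, mag_frames])


def train(
    pairs: list[SourcePair],
    cfg: TrainConfig | None = None,
    stft_cfg: STFTConfig | None = None,
) -> tuple[SeparatorModel, list[float]]:
    """Train the separator MLP on ground-truth source pairs.

    Builds frame-level context/target rows from every pair, pools and
    reshuffles them each epoch with the seeded generator, and minimizes the
    mean squared error of the scaled magnitude predictions for both
    sources jointly with Adam.  The learning rate is multiplied by
    ``lr_decay_per_epoch`` after every epoch; inverted dropout with drop
    probability ``dropout_prob`` regularizes the hidden layer.

    Returns the trained model and the per-epoch mean training loss.
    """
    cfg = cfg or TrainConfig()
    stft_cfg = stft_cfg or STFTConfig()
    if not pairs:
        raise ValueError("training requires at least one source pair")

    mix, voc, ins = _magnitude_dataset(pairs, stft_cfg)
    scale = float(np.percentile(np.concatenate([m.ravel() for m in mix]), cfg.scale_percentile))
    if scale <= 0:
        scale = 1.0

    x = np.vstack([_context_rows(m / scale) for m in mix]).astype(np.float32)
    y = np.vstack(
        [np.hstack([v, i]) / scale for v, i in zip(voc, ins)]
    ).astype(np.float32)
    n_rows, in_dim = x.shape
    out_dim = y.shape[1]

    rng = np.random.default_rng(cfg.seed)
    w1 = (rng.standard_normal((in_dim, cfg.hidden_units)) * np.sqrt(2.0 / in_dim)).astype(np.float32)
    b1 = np.zeros(cfg.hidden_units, dtype=np.float32)
    w2 = (rng.standard_normal((cfg.hidden_units, out_dim)) * np.sqrt(2.0 / cfg.hidden_units)).astype(np.float32)
    b2 = np.zeros(out_dim, dtype=np.float32)

    params = [w1, b1, w2, b2]
    m_t = [np.zeros_like(p) for p in params]
    v_t = [np.zeros_like(p) for p in params]
    step = 0
    keep = 1.0 - cfg.dropout_prob

    history: list[float] = []
    for epoch in range(cfg.epochs):
        lr = cfg.learning_rate(epoch)
        perm = rng.permutation(n_rows)
        sq_err_sum = 0.0
        for start in range(0, n_rows, cfg.batch_size):
            idx = perm[start : start + cfg.batch_size]
            xb, yb = x[idx], y[idx]
            bsz = xb.shape[0]

            z1 = xb @ w1 + b1
            h = np.maximum(z1, 0.0, dtype=np.float32)
            if cfg.dropout_prob > 0:
                mask = (rng.random(h.shape) >= cfg.dropout_prob).astype(np.float32) / keep
                h_d = h * mask
            else:
                mask = None
                h_d = h
            z2 = h_d @ w2 + b2
            pred = np.maximum(z2, 0.0, dtype=np.float32)

            err = pred - yb
            sq_err_sum += float(np.sum(err.astype(np.float64) ** 2))

            # MSE averaged over batch rows and output units
            g_pred = (2.0 / (bsz * out_dim)) * err
            g_z2 = g_pred * (z2 > 0)
            g_w2 = h_d.T @ g_z2
            g_b2 = g_z2.sum(axis=0)
            g_hd = g_z2 @ w2.T
            g_h = g_hd * mask if mask is not None else g_hd
            g_z1 = g_h * (z1 > 0)
            g_w1 = xb.T @ g_z1
            g_b1 = g_z1.sum(axis=0)

            step += 1
            bc1 = 1.0 - cfg.adam_beta1**step
            bc2 = 1.0 - cfg.adam_beta2**step
            for p, g, m_acc, v_acc in zip(params, [g_w1, g_b1, g_w2, g_b2], m_t, v_t):
                m_acc *= cfg.adam_beta1
                m_acc += (1 - cfg.adam_beta1) * g
                v_acc *= cfg.adam_beta2
                v_acc += (1 - cfg.adam_beta2) * g * g
                p -= (lr * (m_acc / bc1) / (np.sqrt(v_acc / bc2) + cfg.adam_eps)).astype(np.float32)

        epoch_loss = sq_err_sum / (n_rows * out_dim)
        if not np.isfinite(epoch_loss):
            raise FloatingPointError(
                f"training diverged: loss became non-finite in epoch {epoch + 1} "
                f"(lr {lr:.4g}); lower the learning rate or check the data scaling"
            )
        history.append(epoch_loss)

    model = SeparatorModel(
        w1=w1, b1=b1, w2=w2, b2=b2,
        input_scale=scale, stft_config=stft_cfg, train_config=cfg,
    )
    return model, history


def separate(
    model, mixture: AudioSignal, stft_cfg: STFTConfig | None = None
) -> SourcePair:
    """Separate a mixture into estimated vocal and instruments signals.

    Pipeline: STFT -> magnitude -> scalar feature scaling -> causal context
    stacking -> network forward pass -> per-source resynthesis with the
    mixture phase.  In mask mode the two network outputs are converted to a
    ratio mask applied to the mixture magnitude instead of being used as
    magnitudes directly.  The estimates have exactly the length of the
    input mixture.
    """
    stft_cfg = stft_cfg or model.stft_config
    spec = stft(mixture, stft_cfg)
    mag = spec.magnitude()
    rows = _context_rows(mag.frames / model.input_scale)
    v_scaled, i_scaled = model.predict(rows)
    # silence gate: frames with an exactly-zero mixture spectrum stay silent
    # (network biases would otherwise hallucinate output into silence)
    silent = ~np.any(mag.frames, axis=1)
    if silent.any():
        v_scaled = np.where(silent[:, None], 0.0, v_scaled)
        i_scaled = np.where(silent[:, None], 0.0, i_scaled)
    if getattr(model, "mask_mode", False):
        eps = 1e-12
        total = v_scaled + i_scaled + eps
        v_frames = (v_scaled / total) * mag.frames
        i_frames = (i_scaled / total) * mag.frames
    else:
        v_frames = v_scaled * model.input_scale
        i_frames = i_scaled * model.input_scale
    mk = lambda frames: MagnitudeSpectrogram(frames, stft_cfg, len(mixture), mixture.rate)
    vocal = resynthesize_with_mixture_phase(mk(v_frames), spec)
    instruments = resynthesize_with_mixture_phase(mk(i_frames), spec)
    return SourcePair(vocal, instruments, mixture, identifier="estimate", strict=False)


# -- dataset chunking and splitting ---------------------------------------

@dataclass
class DatasetSplit:
    """Disjoint, exhaustive partition of chunk identifiers into three sets."""

    train: list[str]
    validation: list[str]
    test: list[str]
    fractions: tuple[float, float, float] = (0.6, 0.2, 0.2)
    chunk_seconds: float = 30.0

    def __post_init__(self) -> None:
        if abs(sum(self.fractions) - 1.0) > 1e-9:
            raise ValueError(f"split fractions must sum to 1, got {self.fractions}")
        all_ids = self.train + self.validation + self.test
        if len(set(all_ids)) != len(all_ids):
            raise ValueError("split sets overlap")


@dataclass
class Corpus:
    """Materialized chunked dataset: chunk id -> SourcePair, plus the split."""

    chunks: dict[str, SourcePair]
    split: DatasetSplit

    def pairs(self, subset: str) -> list[SourcePair]:
        ids = getattr(self.split, subset)
        return [self.chunks[i] for i in ids]


def _split_counts(n: int, fractions: tuple[float, float, float]) -> list[int]:
    """Largest-remainder apportionment of n tracks into the three splits."""
    raw = [f * n for f in fractions]
    counts = [int(np.floor(r)) for r in raw]
    order = np.argsort([c - r for c, r in zip(counts, raw)])  # most-negative first
    for j in range(n - sum(counts)):
        counts[order[j]] += 1
    return counts


def chunk_and_split(
    tracks: list[SourcePair],
    fractions: tuple[float, float, float] = (0.6, 0.2, 0.2),
    chunk_seconds: float = 30.0,
    seed: int = 0,
) -> Corpus:
    """Chop tracks into fixed-length chunks and partition them by track.

    Tracks are cut into consecutive ``chunk_seconds`` chunks (a final
    shorter remainder is dropped; tracks shorter than one chunk are kept
    whole).  Whole tracks — never individual chunks — are assigned to the
    train/validation/test sets with the seeded generator, so no track
    spans two splits.
    """
    if not tracks:
        raise ValueError("no tracks to split")
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError(f"split fractions must sum to 1, got {fractions}")

    chunks: dict[str, SourcePair] = {}
    per_track_ids: list[list[str]] = []
    for t_idx, track in enumerate(tracks):
        base = track.identifier or f"track{t_idx:03d}"
        n_chunk = int(len(track) // (chunk_seconds * track.rate))
        ids = []
        if n_chunk == 0:
            cid = f"{base}/c00"
            chunks[cid] = replace(track, identifier=cid)
            ids.append(cid)
        else:
            step = int(round(chunk_seconds * track.rate))
            for j in range(n_chunk):
                sl = slice(j * step, (j + 1) * step)
                cid = f"{base}/c{j:02d}"
                chunks[cid] = SourcePair(
                    AudioSignal(track.vocal.samples[sl], track.rate),
                    AudioSignal(track.instruments.samples[sl], track.rate),
                    AudioSignal(track.mixture.samples[sl], track.rate),
                    identifier=cid,
                )
                ids.append(cid)
        per_track_ids.append(ids)

    rng = np.random.default_rng(seed)
    order = rng.permutation(len(tracks))
    n_train, n_val, n_test = _split_counts(len(tracks), fractions)
    sets: dict[str, list[str]] = {"train": [], "validation": [], "test": []}
    for pos, t_idx in enumerate(order):
        if pos < n_train:
            key = "train"
        elif pos < n_train + n_val:
            key = "validation"
        else:
            key = "test"
        sets[key].extend(per_track_ids[t_idx])

    split = DatasetSplit(
        sets["train"], sets["validation"], sets["test"],
        fractions=fractions, chunk_seconds=chunk_seconds,
    )
    return Corpus(chunks, split)


# -- checkpoint serialization ---------------------------------------------

def save_checkpoint(model: SeparatorModel, path) -> None:
    """Serialize a model to a portable .npz container with a version tag."""
    meta = {
        "version": model.version,
        "input_scale": model.input_scale,
        "mask_mode": model.mask_mode,
        "stft_config": {
            "window_len": model.stft_config.window_len,
            "hop": model.stft_config.hop,
            "window_kind": model.stft_config.window_kind,
        },
        "train_config": (
            {
                "batch_size": model.train_config.batch_size,
                "initial_lr": model.train_config.initial_lr,
                "lr_decay_per_epoch": model.train_config.lr_decay_per_epoch,
                "epochs": model.train_config.epochs,
                "dropout_prob": model.train_config.dropout_prob,
                "hidden_units": model.train_config.hidden_units,
                "seed": model.train_config.seed,
            }
            if model.train_config is not None
            else None
        ),
    }
    np.savez(
        path,
        w1=model.w1, b1=model.b1, w2=model.w2, b2=model.b2,
        meta=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
    )


def load_checkpoint(path) -> SeparatorModel:
    """Load a model saved by :func:`save_checkpoint`."""
    with np.load(path) as data:
        meta = json.loads(bytes(data["meta"]).decode())
        if meta["version"] != CHECKPOINT_VERSION:
            raise ValueError(f"unsupported checkpoint version {meta['version']!r}")
        tc = meta["train_config"]
        return SeparatorModel(
            w1=data["w1"], b1=data["b1"], w2=data["w2"], b2=data["b2"],
            input_scale=meta["input_scale"],
            stft_config=STFTConfig(**meta["stft_config"]),
            train_config=TrainConfig(**tc) if tc else None,
            mask_mode=meta["mask_mode"],
        )
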