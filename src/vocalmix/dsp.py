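"""Time-frequency analysis and synthesis.

Implements the analysis front end and synthesis back end shared by every
stage of the separation pipeline: a short-time Fourier transform (STFT)
with a 1024-sample periodic Hamming window and 75 % overlap, the inverse
STFT with overlap-add (OLA) resynthesis, mixture-phase resynthesis of
estimated magnitude spectra, and the algorithmic-latency accounting of the
frame scheme.

Conventions
-----------
* The analysis window is applied once, at analysis time.  Synthesis
  overlap-adds the inverse-transformed (already windowed) frames and
  divides by the sum of the shifted analysis windows, which yields exact
  reconstruction for any window that is nonzero everywhere.
* The signal is zero-padded by ``window_len - hop`` samples at the start
  and by up to one window at the end so that every sample of the original
  signal is covered by the full ``window_len / hop`` overlapping frames;
  synthesis trims the padding away.  With these conventions
  ``istft(stft(x))`` reproduces ``x`` to floating-point precision.
* Algorithmic latency is *defined* as the hop duration: the processing
  scheme consumes and emits audio in hop-sized blocks, so a block must be
  complete before it can be processed.  With the 256-sample hop at
  44.1 kHz this is 5.8 ms, i.e. 6 ms to the nearest millisecond.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.io import wavfile
from scipy.signal import get_window

__all__ = [
    "AudioSignal",
    "STFTConfig",
    "Spectrogram",
    "MagnitudeSpectrogram",
    "stft",
    "istft",
    "resynthesize_with_mixture_phase",
    "algorithmic_latency_ms",
    "read_wav",
    "write_wav",
]

DEFAULT_RATE = 44_100


@dataclass
class AudioSignal:
    """A finite, real-valued audio signal.

    Parameters
    ----------
    samples
        1-D (mono) or 2-D ``(n_samples, n_channels)`` float array with
        nominal amplitude range [-1, 1].  NaN or infinite samples are
        rejected.
    rate
        Sample rate in Hz (default 44 100).
    """

    samples: np.ndarray
    rate: int = DEFAULT_RATE

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.samples.ndim not in (1, 2):
            raise ValueError("samples must be 1-D (mono) or 2-D (multichannel)")
        if self.rate <= 0:
            raise ValueError(f"sample rate must be positive, got {self.rate}")
        if self.samples.size and not np.all(np.isfinite(self.samples)):
            raise ValueError("audio contains NaN or infinite samples")

    # -- basic properties --------------------------------------------------

    def __len__(self) -> int:
        return self.samples.shape[0]

    @property
    def n_channels(self) -> int:
        return 1 if self.samples.ndim == 1 else self.samples.shape[1]

    @property
    def duration(self) -> float:
        """Length in seconds."""
        return len(self) / self.rate

    def rms(self) -> float:
        """Root-mean-square amplitude over all samples."""
        if len(self) == 0:
            return 0.0
        return float(np.sqrt(np.mean(np.square(self.samples))))

    def to_mono(self) -> "AudioSignal":
        """Downmix to mono by averaging channels (no-op for mono input)."""
        if self.samples.ndim == 1:
            return self
        return AudioSignal(self.samples.mean(axis=1), self.rate)


@dataclass(frozen=True)
class STFTConfig:
    """Analysis parameters of the short-time Fourier transform.

    The defaults (1024-sample periodic Hamming window, hop 256, i.e. 75 %
    overlap) give 513 frequency bins per frame at any sample rate.
    """

    window_len: int = 1024
    hop: int = 256
    window_kind: str = "hamming"

    def __post_init__(self) -> None:
        if self.window_len <= 0 or self.window_len % 2 != 0:
            raise ValueError("window_len must be a positive even integer")
        if not 0 < self.hop <= self.window_len:
            raise ValueError("hop must satisfy 0 < hop <= window_len")

    @property
    def n_bins(self) -> int:
        """Number of non-negative-frequency bins (window_len/2 + 1)."""
        return self.window_len // 2 + 1

    @property
    def pre_pad(self) -> int:
        """Leading zero-padding so edge samples get full frame coverage."""
        return self.window_len - self.hop

    def window(self) -> np.ndarray:
        """The periodic analysis window as a float64 array."""
        return get_window(self.window_kind, self.window_len, fftbins=True).astype(np.float64)

    def n_frames(self, n_samples: int) -> int:
        """Frame count for a signal of ``n_samples`` under the padding rule."""
        if n_samples <= 0:
            raise ValueError("signal must contain at least one sample")
        return (self.pre_pad + n_samples - 1) // self.hop + 1


@dataclass
class Spectrogram:
    """Complex STFT frames plus the configuration that produced them."""

    frames: np.ndarray  # (n_frames, n_bins) complex
    config: STFTConfig
    origin_length: int
    rate: int = DEFAULT_RATE

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 2 or self.frames.shape[1] != self.config.n_bins:
            raise ValueError(
                f"frames must have shape (n_frames, {self.config.n_bins}), "
                f"got {self.frames.shape}"
            )

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    def magnitude(self) -> "MagnitudeSpectrogram":
        return MagnitudeSpectrogram(
            np.abs(self.frames), self.config, self.origin_length, self.rate
        )

    def phase(self) -> np.ndarray:
        return np.angle(self.frames)


@dataclass
class MagnitudeSpectrogram:
    """Non-negative magnitude spectra with the same framing as Spectrogram."""

    frames: np.ndarray  # (n_frames, n_bins) real, >= 0
    config: STFTConfig
    origin_length: int
    rate: int = DEFAULT_RATE

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=np.float64)
        if self.frames.ndim != 2 or self.frames.shape[1] != self.config.n_bins:
            raise ValueError(
                f"frames must have shape (n_frames, {self.config.n_bins}), "
                f"got {self.frames.shape}"
            )
        if self.frames.size and self.frames.min() < 0:
            raise ValueError("magnitude spectrogram entries must be non-negative")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]


def _padded(signal: np.ndarray, cfg: STFTConfig) -> np.ndarray:
    n = signal.shape[0]
    k = cfg.n_frames(n)
    padded_len = (k - 1) * cfg.hop + cfg.window_len
    out = np.zeros(padded_len, dtype=np.float64)
    out[cfg.pre_pad : cfg.pre_pad + n] = signal
    return out


def stft(signal: AudioSignal, cfg: STFTConfig | None = None) -> Spectrogram:
    """Short-time Fourier transform of a mono signal.

    The signal is zero-padded at both ends (see module docstring), cut into
    ``window_len``-sample frames advancing by ``hop`` samples, windowed
    once and transformed with a real FFT, keeping the ``window_len/2 + 1``
    non-negative-frequency bins.
    """
    cfg = cfg or STFTConfig()
    if signal.n_channels != 1:
        raise ValueError("stft expects a mono signal; downmix with to_mono() first")
    if len(signal) == 0:
        raise ValueError("cannot analyze an empty signal")
    x = _padded(signal.samples, cfg)
    k = cfg.n_frames(len(signal))
    idx = cfg.hop * np.arange(k)[:, None] + np.arange(cfg.window_len)[None, :]
    frames = x[idx] * cfg.window()[None, :]
    spec = np.fft.rfft(frames, axis=1)
    return Spectrogram(spec, cfg, origin_length=len(signal), rate=signal.rate)


def _overlap_add(segments: np.ndarray, cfg: STFTConfig, origin_length: int) -> np.ndarray:
    """OLA of per-frame time segments, normalized by the summed windows.

    Frames are accumulated in ascending order; the streaming engine mirrors
    this order exactly so that batch and streamed output agree bitwise.
    """
    k = segments.shape[0]
    padded_len = (k - 1) * cfg.hop + cfg.window_len
    out = np.zeros(padded_len)
    norm = np.zeros(padded_len)
    win = cfg.window()
    for i in range(k):
        start = i * cfg.hop
        out[start : start + cfg.window_len] += segments[i]
        norm[start : start + cfg.window_len] += win
    out /= norm
    return out[cfg.pre_pad : cfg.pre_pad + origin_length]


def istft(spec: Spectrogram) -> AudioSignal:
    """Inverse STFT with overlap-add resynthesis.

    Inverse-transforms each frame (still carrying the analysis window),
    overlap-adds the segments and divides by the sum of the shifted
    windows, then trims the analysis padding.  For unmodified spectra this
    reconstructs the input exactly (to floating-point precision).
    """
    segments = np.fft.irfft(spec.frames, n=spec.config.window_len, axis=1)
    samples = _overlap_add(segments, spec.config, spec.origin_length)
    return AudioSignal(samples, spec.rate)


def resynthesize_with_mixture_phase(
    mag: MagnitudeSpectrogram, mixture_spec: Spectrogram
) -> AudioSignal:
    """Resynthesize a magnitude estimate using the phase of the mixture.

    Combines the estimated magnitude spectra with ``angle(X)`` of the
    observed mixture spectrogram and inverts with overlap-add.  This is the
    standard phase-recovery shortcut for magnitude-domain separators.
    """
    if mag.frames.shape != mixture_spec.frames.shape:
        raise ValueError(
            f"shape mismatch: magnitude {mag.frames.shape} vs "
            f"mixture {mixture_spec.frames.shape}"
        )
    if mag.config != mixture_spec.config:
        raise ValueError("magnitude and mixture spectrograms use different STFT configs")
    spec = Spectrogram(
        mag.frames * np.exp(1j * np.angle(mixture_spec.frames)),
        mixture_spec.config,
        mixture_spec.origin_length,
        mixture_spec.rate,
    )
    return istft(spec)


def algorithmic_latency_ms(cfg: STFTConfig | None = None, rate: int = DEFAULT_RATE) -> tuple[float, int]:
    """Declared algorithmic latency of the frame scheme, in milliseconds.

    Defined as the hop duration (the block size in which audio is consumed
    and emitted): ``hop / rate * 1000``.  Returns the exact value and its
    nearest-integer rounding.  With the defaults (hop 256 at 44.1 kHz) this
    is 5.805 ms, i.e. 6 ms.
    """
    cfg = cfg or STFTConfig()
    if rate <= 0:
        raise ValueError("rate must be positive")
    ms = cfg.hop / rate * 1000.0
    return ms, int(round(ms))


# -- WAV I/O ---------------------------------------------------------------

def read_wav(path, expected_rate: int | None = DEFAULT_RATE, downmix: bool = True) -> AudioSignal:
    """Read a PCM or float WAV file into an AudioSignal in [-1, 1].

    Integer PCM (16/24/32-bit) is scaled to full-scale floats.  Stereo
    files are downmixed to mono by default.  A file whose rate differs from
    ``expected_rate`` is rejected (resampling is out of scope); pass
    ``expected_rate=None`` to accept any rate.
    """
    rate, data = wavfile.read(path)
    if expected_rate is not None and rate != expected_rate:
        raise ValueError(f"expected {expected_rate} Hz, file is {rate} Hz")
    if data.dtype.kind == "i":
        data = data.astype(np.float64) / float(np.iinfo(data.dtype).max)
    elif data.dtype.kind == "u":  # 8-bit unsigned PCM
        data = (data.astype(np.float64) - 128.0) / 127.0
    else:
        data = data.astype(np.float64)
    sig = AudioSignal(data, rate)
    return sig.to_mono() if downmix else sig


def write_wav(path, signal: AudioSignal) -> None:
    """Write an AudioSignal as a 32-bit float WAV file."""
    wavfile.write(path, signal.rate, signal.samples.astype(np.float32))
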