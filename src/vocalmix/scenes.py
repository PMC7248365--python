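"""Synthetic music scenes: vocal/instrument sources, rooms, corpora.

This module generates the study material the separator is trained and
evaluated on, emulating the salient features of commercial
vocal/accompaniment corpora and of reverberant concert rooms:

* a *vocal-like* source: a harmonic tone with a piecewise note contour,
  ~5 Hz vibrato, a formant-flavored spectral envelope, syllabic on/off
  gating with occasional silent (non-vocal) passages, and a faint gated
  breath-noise component;
* an *instruments-like* source: percussive noise bursts, a bass line, a
  sustained chord bed and a low broadband noise floor;
* a statistical room impulse response (direct impulse plus exponentially
  decaying noise tail) parameterized by the reverberation time T60, with
  a Schroeder backward-integration estimator to validate it;
* corpus assembly: fixed-length tracks, optional reverberant rendering,
  and a 60/20/20 train/validation/test split by track.

Every generator is a pure function of its seed; fixtures regenerate
bit-identically.  The room model controls T60 and the direct-to-reverb
ratio only: with a single exponential decay slope, estimates extrapolated
from any decay range coincide, so T20 cannot be set independently of T60.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.signal import fftconvolve

from .dsp import AudioSignal, write_wav
from .separator import Corpus, SourcePair, chunk_and_split

__all__ = [
    "VocalParams",
    "InstrumentParams",
    "SceneConfig",
    "gen_vocal",
    "gen_vocal_with_contour",
    "gen_instruments",
    "make_rir",
    "estimate_reverb_time",
    "render_scene",
    "build_corpus",
    "disjoint_band_pair",
    "write_corpus",
]

# 60 dB of amplitude decay: exp(-6.9078 t / T60) in amplitude, i.e.
# 20*log10(e) * 6.9078 = 60 dB at t = T60.
DECAY_CONST = 6.9077552789821375  # ln(10^3)


@dataclass(frozen=True)
class VocalParams:
    """Shape of the synthetic singing voice."""

    f0_min: float = 110.0          # Hz, lowest note
    f0_max: float = 440.0          # Hz, highest note
    vibrato_rate: float = 5.0      # Hz
    vibrato_cents: float = 50.0    # peak deviation
    n_harmonics: int = 12
    max_harmonic_hz: float | None = None   # cap on partial frequency
    spectral_tilt: float = 0.8     # amplitude ~ 1/h**tilt
    formant_hz: float = 600.0      # gentle resonance bump
    formant_octaves: float = 0.8   # bump width (octaves)
    note_seconds: tuple[float, float] = (0.25, 0.7)
    gap_prob: float = 0.25         # probability a note is silent
    ramp_seconds: float = 0.02
    breath_noise_db: float = -35.0 # relative to the harmonic part; gated
    level_rms: float = 0.1         # RMS over voiced regions

    def __post_init__(self) -> None:
        if not 0 < self.f0_min <= self.f0_max:
            raise ValueError("need 0 < f0_min <= f0_max")
        if not 0.0 <= self.gap_prob <= 1.0:
            raise ValueError("gap_prob must lie in [0, 1]")


@dataclass(frozen=True)
class InstrumentParams:
    """Shape of the synthetic accompaniment (percussion + bass + chords)."""

    burst_rate: float = 2.0                     # percussive events per second
    burst_decay: float = 0.06                   # seconds (exponential)
    burst_band: tuple[float, float] = (150.0, 9000.0)
    bass_f0: float = 82.41                      # Hz (E2)
    bass_note_seconds: float = 0.5
    bass_harmonics: int = 3
    chord_freqs: tuple[float, ...] = (220.0, 277.18, 329.63)
    chord_harmonics: int = 3
    percussive_gain: float = 1.0
    bass_gain: float = 0.7
    chord_gain: float = 0.45
    noise_gain: float = 0.008                   # broadband floor
    noise_band: tuple[float, float] = (100.0, 12000.0)
    level_rms: float = 0.1


@dataclass(frozen=True)
class SceneConfig:
    """Statistical room model: reverberation time and direct/reverb balance."""

    t60: float = 0.65
    direct_to_reverb_db: float = 0.0
    rir_seconds: float | None = None    # default 1.5 * t60
    seed: int = 0

    def __post_init__(self) -> None:
        if self.t60 <= 0:
            raise ValueError("t60 must be positive")
        if self.rir_seconds is not None and self.rir_seconds < self.t60:
            raise ValueError("rir_seconds must be at least t60")

    @property
    def rir_length_seconds(self) -> float:
        return self.rir_seconds if self.rir_seconds is not None else 1.5 * self.t60


def _ramped_gate(n: int, on: bool, ramp: int) -> np.ndarray:
    """Unit gate with raised-cosine edges, or zeros when the note is off."""
    if not on:
        return np.zeros(n)
    g = np.ones(n)
    r = min(ramp, n // 2)
    if r > 0:
        fade = 0.5 * (1 - np.cos(np.pi * np.arange(r) / r))
        g[:r] = fade
        g[-r:] = fade[::-1]
    return g


def _bandpass_noise(n: int, band: tuple[float, float], rate: int, rng) -> np.ndarray:
    """White noise brick-wall limited to ``band`` via the real FFT."""
    noise = rng.standard_normal(n)
    spec = np.fft.rfft(noise)
    freqs = np.fft.rfftfreq(n, 1.0 / rate)
    spec[(freqs < band[0]) | (freqs > band[1])] = 0.0
    out = np.fft.irfft(spec, n=n)
    peak = np.max(np.abs(out))
    return out / peak if peak > 0 else out


def gen_vocal_with_contour(
    duration: float,
    params: VocalParams | None = None,
    seed: int = 0,
    rate: int = 44_100,
) -> tuple[AudioSignal, np.ndarray, np.ndarray]:
    """Generate a vocal-like source and return its pitch contour.

    Returns ``(signal, f0, voiced)`` where ``f0`` is the instantaneous
    fundamental in Hz per sample (vibrato included) and ``voiced`` is a
    boolean per-sample mask of the sung (non-gap) regions.  The signal is
    a sum of harmonics of the contour shaped by a 1/h**tilt roll-off with
    a formant-like bump, plus gated band-limited breath noise.
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    p = params or VocalParams()
    rng = np.random.default_rng(seed)
    n = int(round(duration * rate))

    # piecewise note contour: a bounded random walk in semitones
    lo, hi = np.log2(p.f0_min), np.log2(p.f0_max)
    note_log2 = rng.uniform(lo, hi)
    base = np.empty(n)
    voiced = np.zeros(n, dtype=bool)
    env = np.zeros(n)
    ramp = int(round(p.ramp_seconds * rate))
    pos = 0
    while pos < n:
        length = int(rng.uniform(*p.note_seconds) * rate)
        length = max(1, min(length, n - pos))
        on = rng.random() >= p.gap_prob
        base[pos : pos + length] = 2.0 ** note_log2
        voiced[pos : pos + length] = on
        env[pos : pos + length] = _ramped_gate(length, on, ramp)
        step = rng.integers(-4, 5) / 12.0
        note_log2 = float(np.clip(note_log2 + step, lo, hi))
        pos += length

    t = np.arange(n) / rate
    vib_phase = rng.uniform(0, 2 * np.pi)
    f0 = base * 2.0 ** (
        (p.vibrato_cents / 1200.0) * np.sin(2 * np.pi * p.vibrato_rate * t + vib_phase)
    )
    phase = 2 * np.pi * np.cumsum(f0) / rate

    f_max = p.max_harmonic_hz if p.max_harmonic_hz is not None else 0.45 * rate
    sig = np.zeros(n)
    nominal_f0 = float(np.exp2(0.5 * (lo + hi)))
    vib_factor = 2.0 ** (p.vibrato_cents / 1200.0)
    for h in range(1, p.n_harmonics + 1):
        # gate partials per note (base is note-constant) so the band cap
        # cannot chatter with vibrato and click mid-note
        active = h * base * vib_factor <= f_max
        if not active.any():
            break
        fh_nominal = h * nominal_f0
        amp = h ** (-p.spectral_tilt) * (
            1.0 + 1.5 * np.exp(-0.5 * (np.log2(fh_nominal / p.formant_hz) / p.formant_octaves) ** 2)
        )
        sig += amp * np.sin(h * phase) * active

    sig *= env
    if p.breath_noise_db is not None and np.any(voiced):
        harm_rms = np.sqrt(np.mean(sig[voiced] ** 2))
        noise = _bandpass_noise(n, (80.0, f_max), rate, rng) * env
        noise_rms = np.sqrt(np.mean(noise[voiced] ** 2))
        if noise_rms > 0:
            sig += noise * (harm_rms * 10.0 ** (p.breath_noise_db / 20.0) / noise_rms)

    if np.any(voiced):
        sig *= p.level_rms / np.sqrt(np.mean(sig[voiced] ** 2))
    return AudioSignal(sig, rate), f0, voiced


def gen_vocal(
    duration: float, params: VocalParams | None = None, seed: int = 0, rate: int = 44_100
) -> AudioSignal:
    """Generate a vocal-like source (see :func:`gen_vocal_with_contour`)."""
    return gen_vocal_with_contour(duration, params, seed, rate)[0]


def gen_instruments(
    duration: float, params: InstrumentParams | None = None, seed: int = 0, rate: int = 44_100
) -> AudioSignal:
    """Generate an instruments-like source.

    Mixes four deterministic-from-seed components: percussive noise bursts
    on a jittered grid, a bass line with a few harmonics, a sustained
    chord bed with slow amplitude modulation, and a low broadband noise
    floor.  Setting every component gain (and the burst rate) to zero
    yields silence.
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    p = params or InstrumentParams()
    rng = np.random.default_rng(seed)
    n = int(round(duration * rate))
    t = np.arange(n) / rate
    sig = np.zeros(n)

    # percussion: decaying band-limited noise bursts
    if p.percussive_gain > 0 and p.burst_rate > 0:
        n_bursts = max(1, int(round(duration * p.burst_rate)))
        grid = np.arange(n_bursts) / p.burst_rate
        onsets = grid + rng.uniform(0, 0.4 / p.burst_rate, n_bursts)
        burst_len = int(5 * p.burst_decay * rate)
        decay = np.exp(-np.arange(burst_len) / (p.burst_decay * rate))
        perc = np.zeros(n)
        for onset in onsets:
            i0 = int(onset * rate)
            if i0 >= n:
                continue
            seg = min(burst_len, n - i0)
            perc[i0 : i0 + seg] += (
                _bandpass_noise(seg, p.burst_band, rate, rng) * decay[:seg]
            )
        sig += p.percussive_gain * perc

    # bass: note pattern on a fixed grid, few harmonics, square-ish
    if p.bass_gain > 0 and p.bass_f0 > 0:
        note_len = int(p.bass_note_seconds * rate)
        pattern = np.zeros(n)
        pos = 0
        while pos < n:
            length = min(note_len, n - pos)
            mult = rng.choice([0.5, 1.0, 1.0, 1.5, 2.0])
            f = p.bass_f0 * mult
            tt = np.arange(length) / rate
            note = sum(
                (1.0 / (2 * k - 1)) * np.sin(2 * np.pi * (2 * k - 1) * f * tt)
                for k in range(1, p.bass_harmonics + 1)
            )
            pattern[pos : pos + length] = note * _ramped_gate(length, True, int(0.01 * rate))
            pos += length
        sig += p.bass_gain * pattern

    # sustained chord bed with slow random amplitude modulation
    if p.chord_gain > 0 and p.chord_freqs:
        chord = np.zeros(n)
        for f in p.chord_freqs:
            for h in range(1, p.chord_harmonics + 1):
                if h * f < 0.45 * rate:
                    ph = rng.uniform(0, 2 * np.pi)
                    chord += (1.0 / h) * np.sin(2 * np.pi * h * f * t + ph)
        mod_rate = rng.uniform(0.1, 0.3)
        mod = 0.75 + 0.25 * np.sin(2 * np.pi * mod_rate * t + rng.uniform(0, 2 * np.pi))
        sig += p.chord_gain * chord * mod / max(len(p.chord_freqs), 1)

    if p.noise_gain > 0:
        sig += p.noise_gain * _bandpass_noise(n, p.noise_band, rate, rng)

    rms = np.sqrt(np.mean(sig**2))
    if rms > 0:
        sig *= p.level_rms / rms
    return AudioSignal(sig, rate)


def make_rir(scene: SceneConfig, rate: int = 44_100) -> AudioSignal:
    """Synthesize a statistical room impulse response.

    A unit-sample direct path followed by a Gaussian-noise tail with
    amplitude envelope ``exp(-6.9078 t / t60)`` (60 dB of decay over one
    T60).  The direct amplitude is set so that the direct-to-reverberant
    energy ratio matches ``scene.direct_to_reverb_db``; the whole response
    is normalized to unit peak.
    """
    rng = np.random.default_rng(scene.seed)
    n = int(round(scene.rir_length_seconds * rate))
    t = np.arange(1, n) / rate
    tail = rng.standard_normal(n - 1) * np.exp(-DECAY_CONST * t / scene.t60)
    tail_energy = float(tail @ tail)
    direct = np.sqrt(tail_energy * 10.0 ** (scene.direct_to_reverb_db / 10.0))
    h = np.concatenate([[direct], tail])
    return AudioSignal(h / np.max(np.abs(h)), rate)


def estimate_reverb_time(rir: AudioSignal) -> float:
    """Estimate T60 by Schroeder backward integration.

    Integrates the squared response backward in time, fits a line to the
    energy-decay curve between -5 and -35 dB, and extrapolates the slope
    to 60 dB of decay.  Raises if the response never reaches the -35 dB
    point with enough samples to fit (e.g. a bare impulse with no tail).
    """
    h = rir.samples
    if h.size == 0 or not np.any(h):
        raise ValueError("impulse response is silent")
    edc = np.cumsum(h[::-1] ** 2)[::-1]
    with np.errstate(divide="ignore"):
        db = 10.0 * np.log10(edc / edc[0])
    in_range = (db <= -5.0) & (db >= -35.0) & np.isfinite(db)
    if np.count_nonzero(in_range) < 10:
        raise ValueError("decay range -5..-35 dB not reached; cannot estimate T60")
    t = np.arange(h.size)[in_range] / rir.rate
    slope, _ = np.polyfit(t, db[in_range], 1)
    if slope >= 0:
        raise ValueError("energy-decay curve does not decay")
    return float(-60.0 / slope)


def render_scene(pair: SourcePair, rir: AudioSignal) -> SourcePair:
    """Convolve both sources with a room response.

    The ground truth becomes the *reverberant image* of each source (what
    a microphone in the room would pick up), and the mixture is the sum of
    the two images; lengths are trimmed to the dry duration.
    """
    if pair.rate != rir.rate:
        raise ValueError("source pair and RIR must share a sample rate")
    n = len(pair)
    v = fftconvolve(pair.vocal.samples, rir.samples)[:n]
    i = fftconvolve(pair.instruments.samples, rir.samples)[:n]
    return SourcePair(
        AudioSignal(v, pair.rate),
        AudioSignal(i, pair.rate),
        AudioSignal(v + i, pair.rate),
        identifier=pair.identifier,
    )


def build_corpus(
    n_tracks: int,
    duration: float = 30.0,
    scene: SceneConfig | None = None,
    fractions: tuple[float, float, float] = (0.6, 0.2, 0.2),
    seed: int = 0,
    rate: int = 44_100,
    chunk_seconds: float = 30.0,
    vocal_params: VocalParams | None = None,
    instrument_params: InstrumentParams | None = None,
) -> Corpus:
    """Generate a chunked, split corpus of synthetic source pairs.

    Each track gets independent per-track seeds derived from ``seed``;
    with a :class:`SceneConfig` every track is rendered through the same
    room response before chunking (one room per corpus, mirroring a fixed
    recording setup).  Fully reproducible from ``seed``.
    """
    if n_tracks < 5:
        raise ValueError("a corpus needs at least 5 tracks to fill a 60/20/20 split")
    rng = np.random.default_rng(seed)
    rir = make_rir(scene, rate) if scene is not None else None
    tracks = []
    for k in range(n_tracks):
        vseed = int(rng.integers(2**31))
        iseed = int(rng.integers(2**31))
        vocal = gen_vocal(duration, vocal_params, seed=vseed, rate=rate)
        instr = gen_instruments(duration, instrument_params, seed=iseed, rate=rate)
        pair = SourcePair.from_sources(vocal, instr, identifier=f"track{k:03d}")
        if rir is not None:
            pair = render_scene(pair, rir)
        tracks.append(pair)
    return chunk_and_split(tracks, fractions, chunk_seconds, seed=seed)


def disjoint_band_pair(
    duration: float = 4.0, seed: int = 0, rate: int = 44_100
) -> SourcePair:
    """A spectrally separable fixture: vocal < 1 kHz, instruments > 2 kHz.

    The vocal's harmonics are capped below 950 Hz and the accompaniment
    (bursts, chord partials, noise floor) lives entirely above 2.2 kHz, so
    an ideal band-splitter separates the two almost perfectly.  Used as
    the convergence/upper-bound fixture in training and pipeline tests.
    """
    vp = VocalParams(
        f0_min=180.0, f0_max=260.0, n_harmonics=4, max_harmonic_hz=950.0,
        vibrato_cents=30.0, gap_prob=0.15, breath_noise_db=-40.0,
    )
    ip = InstrumentParams(
        burst_band=(2200.0, 8000.0), bass_gain=0.0,
        chord_freqs=(2500.0, 3150.0, 3970.0), chord_harmonics=2,
        noise_band=(2200.0, 9000.0), noise_gain=0.02,
    )
    vocal = gen_vocal(duration, vp, seed=seed, rate=rate)
    instr = gen_instruments(duration, ip, seed=seed + 1, rate=rate)
    return SourcePair.from_sources(vocal, instr, identifier=f"disjoint{seed}")


def write_corpus(corpus: Corpus, out_dir, manifest_extra: dict | None = None) -> Path:
    """Write corpus chunks as WAV files plus a JSON manifest; returns the manifest path."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    entries = []
    for cid, pair in corpus.chunks.items():
        stem = cid.replace("/", "_")
        for role, sig in (("vocal", pair.vocal), ("instruments", pair.instruments), ("mixture", pair.mixture)):
            write_wav(out / f"{stem}.{role}.wav", sig)
        subset = next(
            s for s in ("train", "validation", "test") if cid in getattr(corpus.split, s)
        )
        entries.append({"id": cid, "stem": stem, "subset": subset, "rate": pair.rate,
                        "n_samples": len(pair)})
    manifest = {
        "chunks": entries,
        "fractions": list(corpus.split.fractions),
        "chunk_seconds": corpus.split.chunk_seconds,
    }
    if manifest_extra:
        manifest.update(manifest_extra)
    path = out / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return path
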