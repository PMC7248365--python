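"""Vocals-to-instruments ratio (VIR) remixing and level calibration.

The VIR is the power ratio, in dB, between the vocal and the instruments
signal in a remix.  The control is an integer-dB slider from -12 to +12 dB
(25 positions, 24 one-dB steps) with two adjustment methods:

``vocals_gain``
    The instruments level stays fixed and the vocals are scaled by
    ``10**(vir_db/20)``; the overall level varies with the setting.

``balanced``
    Vocals and instruments are scaled in opposite directions by
    ``10**(±vir_db/40)`` (half the VIR in amplitude-dB on each source) and
    the sum is then renormalized so its RMS equals the calibrated
    reference exactly, keeping the presentation level constant across the
    whole slider range.

The calibrated presentation level (65 dB SPL in a playback room) is
represented digitally by a configurable reference RMS, 0.05 full-scale by
default; absolute SPL is a property of the playback chain and outside the
digital signal path.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .dsp import AudioSignal

__all__ = [
    "VIRSetting",
    "apply_vir",
    "quantize_vir",
    "calibrate_level",
    "vir_gains",
    "DEFAULT_REFERENCE_RMS",
]

DEFAULT_REFERENCE_RMS = 0.05
VIR_MIN_DB = -12
VIR_MAX_DB = 12
MODES = ("vocals_gain", "balanced")


@dataclass(frozen=True)
class VIRSetting:
    """Remix control: integer VIR in [-12, +12] dB, mode, reference level."""

    vir_db: int = 0
    mode: str = "vocals_gain"
    reference_rms: float = DEFAULT_REFERENCE_RMS

    def __post_init__(self) -> None:
        if not isinstance(self.vir_db, (int, np.integer)):
            raise ValueError(f"vir_db must be an integer dB value, got {self.vir_db!r}")
        if not VIR_MIN_DB <= self.vir_db <= VIR_MAX_DB:
            raise ValueError(f"vir_db must lie in [{VIR_MIN_DB}, {VIR_MAX_DB}]")
        if self.mode not in MODES:
            raise ValueError(f"mode must be one of {MODES}, got {self.mode!r}")
        if self.reference_rms <= 0:
            raise ValueError("reference_rms must be positive")


def vir_gains(setting: VIRSetting) -> tuple[float, float]:
    """Amplitude gains (vocal, instruments) before any renormalization.

    ``vocals_gain`` mode leaves the instruments untouched; ``balanced``
    mode splits the VIR symmetrically (±vir_db/2 in power on each source).
    """
    d = setting.vir_db
    if setting.mode == "vocals_gain":
        return 10.0 ** (d / 20.0), 1.0
    return 10.0 ** (d / 40.0), 10.0 ** (-d / 40.0)


def apply_vir(vocal: AudioSignal, instruments: AudioSignal, setting: VIRSetting) -> AudioSignal:
    """Remix vocal and instruments at the requested VIR.

    In ``balanced`` mode the remix is renormalized so its RMS equals
    ``setting.reference_rms`` exactly; a silent pre-normalization remix is
    an error because there is no level to calibrate.
    """
    if len(vocal) != len(instruments):
        raise ValueError("vocal and instruments must have equal length")
    if vocal.rate != instruments.rate:
        raise ValueError("vocal and instruments must share a sample rate")
    gv, gi = vir_gains(setting)
    mix = gv * vocal.samples + gi * instruments.samples
    if setting.mode == "balanced":
        rms = float(np.sqrt(np.mean(np.square(mix)))) if mix.size else 0.0
        if rms == 0.0:
            raise ValueError("cannot calibrate the level of a silent remix")
        mix = mix * (setting.reference_rms / rms)
    return AudioSignal(mix, vocal.rate)


def quantize_vir(raw_db: float) -> int:
    """Snap a continuous dB value to the integer slider grid.

    Nearest 1-dB position, clipped to [-12, +12]; half-way values round
    away from zero (e.g. +11.5 -> +12).
    """
    if math.isnan(raw_db):
        raise ValueError("VIR value is NaN")
    snapped = math.floor(abs(raw_db) + 0.5) * (1 if raw_db >= 0 else -1)
    return int(min(max(snapped, VIR_MIN_DB), VIR_MAX_DB))


def calibrate_level(signal: AudioSignal, reference_rms: float = DEFAULT_REFERENCE_RMS) -> AudioSignal:
    """Scale a signal so its RMS equals ``reference_rms`` exactly."""
    if reference_rms <= 0:
        raise ValueError("reference_rms must be positive")
    rms = signal.rms()
    if rms == 0.0:
        raise ValueError("cannot calibrate a silent signal")
    return AudioSignal(signal.samples * (reference_rms / rms), signal.rate)
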