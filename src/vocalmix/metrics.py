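"""BSS-Eval objective separation metrics (time-invariant variant).

An estimate ``e`` of a target source is decomposed against the set of true
sources ``{s_1, ..., s_k}`` into three orthogonal parts:

* ``s_target`` — the orthogonal projection of ``e`` onto the target source
  (a single scalar coefficient; the time-invariant, filter-length-1
  variant of the BSS-Eval framework),
* ``e_interf`` — the projection of ``e`` onto the span of *all* true
  sources, minus ``s_target`` (energy leaked from the other sources),
* ``e_artif`` — the residual outside the source subspace (artifacts
  introduced by the algorithm).

From the energies of these parts:

    SDR = 10 log10( ||s_target||^2 / ||e_interf + e_artif||^2 )
    SIR = 10 log10( ||s_target||^2 / ||e_interf||^2 )
    SAR = 10 log10( ||s_target + e_interf||^2 / ||e_artif||^2 )

Ratios whose denominator vanishes (perfect separation) are capped at
+200 dB so that averages over tracks stay finite; the cap is symmetric at
-200 dB for degenerate numerators.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .dsp import AudioSignal
from .separator import SourcePair

__all__ = ["BSSEvalResult", "PairEvaluation", "bss_decompose", "evaluate_pair", "DB_CAP"]

DB_CAP = 200.0


@dataclass(frozen=True)
class BSSEvalResult:
    """SDR/SIR/SAR in dB plus the energies of the decomposition parts."""

    sdr_db: float
    sir_db: float
    sar_db: float
    target_energy: float
    interference_energy: float
    artifact_energy: float


def _ratio_db(num: float, den: float) -> float:
    if num <= 0.0:
        return -DB_CAP
    if den <= 0.0:
        return DB_CAP
    return float(np.clip(10.0 * np.log10(num / den), -DB_CAP, DB_CAP))


def bss_decompose(
    estimate: AudioSignal, true_sources: list[AudioSignal], target_index: int
) -> BSSEvalResult:
    """Decompose an estimate against the true sources and compute ratios.

    ``true_sources[target_index]`` is the source the estimate is supposed
    to reproduce.  Sources must be linearly independent and the target
    must carry energy; otherwise the projections are singular.
    """
    e = estimate.samples.astype(np.float64)
    S = np.stack([s.samples.astype(np.float64) for s in true_sources])
    if S.shape[1] != e.shape[0]:
        raise ValueError("estimate and true sources must have equal length")
    if not 0 <= target_index < S.shape[0]:
        raise IndexError(f"target_index {target_index} out of range")

    target = S[target_index]
    t_energy = float(target @ target)
    if t_energy == 0.0:
        raise ValueError("target source has zero energy")

    gram = S @ S.T
    cond = np.linalg.cond(gram)
    if not np.isfinite(cond) or cond > 1e12:
        raise ValueError("true sources are (near-)collinear; projection is singular")

    s_target = (float(e @ target) / t_energy) * target
    coeffs = np.linalg.solve(gram, S @ e)
    proj_all = coeffs @ S
    e_interf = proj_all - s_target
    e_artif = e - proj_all

    en_t = float(s_target @ s_target)
    en_i = float(e_interf @ e_interf)
    en_a = float(e_artif @ e_artif)

    return BSSEvalResult(
        sdr_db=_ratio_db(en_t, en_i + en_a),
        sir_db=_ratio_db(en_t, en_i),
        sar_db=_ratio_db(en_t + en_i, en_a),
        target_energy=en_t,
        interference_energy=en_i,
        artifact_energy=en_a,
    )


@dataclass(frozen=True)
class PairEvaluation:
    """Per-source BSS-Eval results for a (vocal, instruments) estimate pair."""

    vocal: BSSEvalResult
    instruments: BSSEvalResult

    @property
    def mean_sdr_db(self) -> float:
        return 0.5 * (self.vocal.sdr_db + self.instruments.sdr_db)

    @property
    def mean_sir_db(self) -> float:
        return 0.5 * (self.vocal.sir_db + self.instruments.sir_db)

    @property
    def mean_sar_db(self) -> float:
        return 0.5 * (self.vocal.sar_db + self.instruments.sar_db)


def evaluate_pair(estimates: SourcePair, truths: SourcePair) -> PairEvaluation:
    """Evaluate vocal and instruments estimates against the true pair."""
    if len(estimates) != len(truths):
        raise ValueError("estimate and truth pairs must have equal length")
    sources = [truths.vocal, truths.instruments]
    return PairEvaluation(
        vocal=bss_decompose(estimates.vocal, sources, 0),
        instruments=bss_decompose(estimates.instruments, sources, 1),
    )
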