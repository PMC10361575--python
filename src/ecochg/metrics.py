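"""Validation and summary metrics: residual similarity, Total Response,
threshold estimation, and cohort descriptive statistics.

``residual_similarity`` is the model-free cross-check of the analytic
decomposition: each low-frequency average cycle is regressed (over circular
lag and scale) against a library of high-frequency, CM-only average cycles.
The smaller the best-match residual, the closer the cycle is to a pure
hair-cell shape and the less neurophonic it should contain — so the residual
RMS should track the fitted ANN proportion.

The **Total Response (TR)** sums the significant spectral magnitudes at the
stimulus frequency and its 2nd and 3rd harmonics across the standard test
frequencies, giving a single overall measure of cochlear output in
microvolts (also expressed in dB re 1 uV).

Threshold estimators implement the two clinical rules: extrapolation from a
single high-level response assuming 1 dB of response drop per dB of level,
down to the 0.02 uV significance floor; and interpolation within a level
series between the last significant and first non-significant response.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ResidualSimilarity",
    "TRResult",
    "ThresholdEstimate",
    "SIGNIFICANCE_FLOOR_UV",
    "residual_similarity",
    "harmonic_magnitudes",
    "total_response",
    "db_re_1uV",
    "threshold_from_single_level",
    "threshold_from_level_series",
    "cohort_summary",
]

#: Minimum response magnitude considered significant under good recording
#: conditions: 0.02 uV, i.e. -34 dB re 1 uV.
SIGNIFICANCE_FLOOR_UV = 0.02


@dataclass(frozen=True)
class ResidualSimilarity:
    """Best match of a cycle against a CM-only library."""

    best_library_match: int
    best_lag: int
    best_scale: float
    residual_rms: float  # RMS of the residual, normalized by the query RMS


def residual_similarity(
    query: np.ndarray, library: Sequence[np.ndarray]
) -> ResidualSimilarity:
    """Regress ``query`` on each library cycle over circular lag and scale.

    For every library member the optimal integer circular lag is found by
    FFT cross-correlation and the optimal scale by least squares; the member
    minimizing the residual RMS is returned.  The reported residual is
    normalized by the query RMS, making the metric invariant to query scale
    and circular shift.
    """
    if len(library) == 0:
        raise ValueError("library must be non-empty")
    q = np.asarray(query, dtype=float)
    q_spec = np.fft.rfft(q)
    q_ss = float(np.sum(q**2))
    if q_ss == 0:
        raise ValueError("query has zero energy")
    best = None
    for j, member in enumerate(library):
        m = np.asarray(member, dtype=float)
        if len(m) != len(q):
            raise ValueError("library cycle length mismatch with query")
        m_ss = float(np.sum(m**2))
        if m_ss == 0:
            continue
        # corr[lag] = sum_n q[n] * m[(n - lag) % N]
        corr = np.fft.irfft(q_spec * np.conj(np.fft.rfft(m)), n=len(q))
        lag = int(np.argmax(corr**2))
        scale = corr[lag] / m_ss
        # explicit time-domain residual: the spectral shortcut
        # q_ss - corr^2/m_ss cancels catastrophically for near-exact matches
        sse = float(np.sum((q - scale * np.roll(m, lag)) ** 2))
        if best is None or sse < best[0]:
            best = (sse, j, lag, scale)
    if best is None:
        raise ValueError("library contains only zero-energy cycles")
    sse, j, lag, scale = best
    rms = float(np.sqrt(sse / q_ss))
    return ResidualSimilarity(
        best_library_match=j, best_lag=lag, best_scale=float(scale),
        residual_rms=rms,
    )


def harmonic_magnitudes(
    cycle: np.ndarray, n_harmonics: int = 3
) -> tuple[np.ndarray, np.ndarray]:
    """Magnitudes (uV) and significance flags of the first harmonics.

    Magnitude of harmonic k is the amplitude of that sinusoidal component of
    the average cycle (2|X_k|/N).  A harmonic is significant if it reaches
    the 0.02 uV floor and stands at least 3x above the median magnitude of
    the non-harmonic bins (the noise floor of the cycle spectrum).
    """
    cycle = np.asarray(cycle, dtype=float)
    n = len(cycle)
    spec = np.abs(np.fft.rfft(cycle)) * 2.0 / n
    mags = spec[1 : n_harmonics + 1]
    noise_bins = spec[n_harmonics + 1 :]
    noise = np.median(noise_bins) if len(noise_bins) else 0.0
    flags = (mags >= SIGNIFICANCE_FLOOR_UV) & (mags >= 3.0 * noise)
    return mags, flags


@dataclass(frozen=True)
class TRResult:
    """Total Response: summed significant harmonic magnitudes."""

    per_frequency: pd.DataFrame  # frequency_hz, harmonic, magnitude_uv, significant
    total_uv: float
    total_db: float | None  # dB re 1 uV; None when the total is zero


def total_response(
    harmonics: Mapping[float, Sequence[float]],
    significance: Mapping[float, Sequence[bool]] | None = None,
) -> TRResult:
    """Sum significant harmonic magnitudes across test frequencies.

    ``harmonics`` maps frequency (Hz) to (f0, 2f0, 3f0) magnitudes in uV.
    ``significance`` optionally provides matching boolean flags; if omitted,
    a magnitude is significant when it reaches the 0.02 uV floor.
    """
    rows = []
    total = 0.0
    for freq, mags in harmonics.items():
        mags = np.asarray(mags, dtype=float)
        if np.any(mags < 0):
            raise ValueError(f"negative harmonic magnitude at {freq} Hz")
        if significance is not None:
            flags = np.asarray(significance[freq], dtype=bool)
        else:
            flags = mags >= SIGNIFICANCE_FLOOR_UV
        for k, (m, s) in enumerate(zip(mags, flags), start=1):
            rows.append(
                {
                    "frequency_hz": freq,
                    "harmonic": k,
                    "magnitude_uv": float(m),
                    "significant": bool(s),
                }
            )
            if s:
                total += float(m)
    return TRResult(
        per_frequency=pd.DataFrame(rows),
        total_uv=total,
        total_db=db_re_1uV(total) if total > 0 else None,
    )


def db_re_1uV(amplitude_uv: float) -> float:
    """Response amplitude in dB re 1 uV: 20 log10(amplitude)."""
    if amplitude_uv <= 0:
        raise ValueError("amplitude must be positive for dB conversion")
    return 20.0 * np.log10(amplitude_uv)


@dataclass(frozen=True)
class ThresholdEstimate:
    method: Literal["calculated_from_single_level", "level_series"]
    threshold_db: float
    floor_uv: float = SIGNIFICANCE_FLOOR_UV
    bound: Literal["exact", "le", "gt"] = "exact"


def threshold_from_single_level(
    response_uv: float,
    level_db: float,
    floor_uv: float = SIGNIFICANCE_FLOOR_UV,
) -> ThresholdEstimate:
    """Extrapolate threshold from one high-level response at 1 dB/dB.

    Threshold is the level at which the response, decaying 1 dB per dB of
    level reduction, reaches the significance floor.
    """
    if floor_uv <= 0:
        raise ValueError("floor must be positive")
    if not np.isfinite(level_db):
        raise ValueError("level must be finite")
    if response_uv < floor_uv:
        raise ValueError("already below significance floor")
    threshold = level_db - (db_re_1uV(response_uv) - db_re_1uV(floor_uv))
    return ThresholdEstimate("calculated_from_single_level", float(threshold),
                             floor_uv)


def threshold_from_level_series(
    levels_db: Sequence[float],
    responses_uv: Sequence[float],
    floor_uv: float = SIGNIFICANCE_FLOOR_UV,
) -> ThresholdEstimate:
    """Interpolate threshold within a descending level series.

    Levels must be strictly descending in 10 dB steps.  The threshold is the
    level at which the response magnitude (in dB re 1 uV) crosses the floor,
    interpolated between the last significant and the first non-significant
    response.  If every response is significant the threshold is reported as
    a bound at the lowest tested level; if none is, as a bound above the
    highest level.
    """
    levels = np.asarray(levels_db, dtype=float)
    responses = np.asarray(responses_uv, dtype=float)
    if len(levels) < 2 or len(levels) != len(responses):
        raise ValueError("need >= 2 matched levels and responses")
    steps = np.diff(levels)
    if np.any(steps >= 0) or np.any(np.abs(steps + 10.0) > 1e-9):
        raise ValueError("levels must descend in 10 dB steps")
    significant = responses >= floor_uv
    if significant.all():
        return ThresholdEstimate("level_series", float(levels[-1]), floor_uv,
                                 bound="le")
    if not significant.any():
        return ThresholdEstimate("level_series", float(levels[0]), floor_uv,
                                 bound="gt")
    # first transition significant -> non-significant walking down the series
    idx = int(np.argmax(~significant))
    if idx == 0:
        return ThresholdEstimate("level_series", float(levels[0]), floor_uv,
                                 bound="gt")
    l_s, l_ns = levels[idx - 1], levels[idx]
    db_s = db_re_1uV(responses[idx - 1])
    db_floor = db_re_1uV(floor_uv)
    # a zero response has no dB value; a 20 dB drop below floor is a stand-in
    db_ns = db_re_1uV(responses[idx]) if responses[idx] > 0 else db_floor - 20.0
    threshold = l_s + (l_ns - l_s) * (db_s - db_floor) / (db_s - db_ns)
    return ThresholdEstimate("level_series", float(threshold), floor_uv)


def cohort_summary(proportions_by_group: Mapping[str, Sequence[float]]) -> pd.DataFrame:
    """Descriptive statistics of ANN proportion per cohort group.

    Returns mean, sample SD, SE, and the fraction of records gated to an
    exactly zero proportion (classifier judged ANN-absent).
    """
    if len(proportions_by_group) == 0:
        raise ValueError("need at least one group")
    rows = []
    for group, values in proportions_by_group.items():
        v = np.asarray(values, dtype=float)
        if len(v) == 0:
            raise ValueError(f"group {group!r} is empty")
        sd = float(np.std(v, ddof=1)) if len(v) > 1 else 0.0
        rows.append(
            {
                "group": group,
                "n": len(v),
                "mean": float(np.mean(v)),
                "sd": sd,
                "se": sd / np.sqrt(len(v)),
                "fraction_absent": float(np.mean(v == 0.0)),
            }
        )
    return pd.DataFrame(rows)
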