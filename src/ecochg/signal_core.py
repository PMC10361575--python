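"""Average-cycle construction from phase-alternating tone-burst recordings.

Round-window electrocochleography (ECochG) to a tone burst contains a
steady-state segment in which every stimulus cycle evokes nominally the same
response.  The *average cycle* — the pointwise mean of all steady-state cycles
— is the unit of analysis throughout this package: it is equivalent to a
period histogram and carries the waveform-shape information that separates
the hair-cell (cochlear microphonic, CM) and neural (auditory nerve
neurophonic, ANN) components.

This module builds average cycles from raw sweep waveforms, combines the
responses to condensation and rarefaction stimulus phases into difference and
alternating waveforms, and puts cycles into the canonical normalized form
(fixed length, unit half peak-to-peak amplitude, zero starting phase of the
fundamental) used by the classifier and the analytic decomposition.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal

import numpy as np
from scipy.interpolate import CubicSpline

from .errors import DegenerateCycleError, InsufficientSteadyStateError

#: Tone-burst frequencies used in the standard stimulus protocol (Hz).
STANDARD_FREQUENCIES = (250, 500, 750, 1000, 2000, 4000)

#: Fraction of total power the fundamental must carry for phase alignment.
_FUNDAMENTAL_POWER_FLOOR = 1e-12


@dataclass(frozen=True)
class StimulusSpec:
    """Stimulus metadata for one tone-burst sweep.

    Parameters
    ----------
    frequency : float
        Tone frequency in Hz.
    level : float
        Stimulus level in dB on the scale named by ``level_scale``.
    phase : {"condensation", "rarefaction"}
        Starting polarity of the tone burst.
    repetitions : int
        Number of sweeps averaged into the recording.
    burst_duration_ms : float
        Duration of the tone burst in milliseconds.
    sampling_rate : float
        Sampling rate of the recording in Hz; must give at least 20 samples
        per stimulus cycle.
    level_scale : {"SPL", "nHL"}
        dB reference scale of ``level``.
    """

    frequency: float
    level: float
    phase: Literal["condensation", "rarefaction"] = "condensation"
    repetitions: int = 100
    burst_duration_ms: float = 40.0
    sampling_rate: float = 48000.0
    level_scale: Literal["SPL", "nHL"] = "SPL"

    def __post_init__(self) -> None:
        if self.frequency <= 0:
            raise ValueError(f"frequency must be positive, got {self.frequency}")
        if self.sampling_rate < 20 * self.frequency:
            raise ValueError(
                "sampling_rate must give >= 20 samples per cycle: "
                f"{self.sampling_rate} Hz at {self.frequency} Hz"
            )
        if self.repetitions <= 0:
            raise ValueError("repetitions must be positive")
        if self.phase not in ("condensation", "rarefaction"):
            raise ValueError(f"unknown phase {self.phase!r}")

    @property
    def samples_per_cycle(self) -> float:
        return self.sampling_rate / self.frequency

    @property
    def n_cycles(self) -> int:
        """Number of complete stimulus cycles in the burst."""
        return int(np.floor(self.burst_duration_ms / 1000.0 * self.frequency))


@dataclass(frozen=True)
class SweepRecording:
    """A sweep-averaged tone-burst waveform with its metadata.

    ``waveform`` holds the potential in microvolts over the burst window
    (plus optional pre/post silence), sampled at ``stimulus.sampling_rate``.
    """

    waveform: np.ndarray
    stimulus: StimulusSpec
    subject_id: str = ""
    cohort_tag: str = ""
    species: Literal["gerbil", "human"] = "gerbil"
    pre_ms: float = 0.0
    post_ms: float = 0.0

    def __post_init__(self) -> None:
        wf = np.asarray(self.waveform, dtype=float)
        object.__setattr__(self, "waveform", wf)
        if wf.ndim != 1:
            raise ValueError("waveform must be one-dimensional")
        if not np.all(np.isfinite(wf)):
            raise ValueError("waveform contains non-finite samples")
        expected = (
            (self.stimulus.burst_duration_ms + self.pre_ms + self.post_ms)
            / 1000.0
            * self.stimulus.sampling_rate
        )
        if abs(len(wf) - expected) > 1.5:
            raise ValueError(
                f"waveform length {len(wf)} inconsistent with metadata "
                f"(expected ~{expected:.0f} samples)"
            )


@dataclass(frozen=True)
class SteadyStateWindow:
    """Rule selecting the steady-state cycles of a burst.

    Onset cycles carry the compound action potential and the response build-up
    and the final cycle carries offset effects, so they are excluded from the
    average by default.
    """

    skip_onset: int = 2
    skip_offset: int = 1

    def __post_init__(self) -> None:
        if self.skip_onset < 0 or self.skip_offset < 0:
            raise ValueError("cycle exclusions must be nonnegative")


def extract_cycles(
    recording: SweepRecording,
    window: SteadyStateWindow = SteadyStateWindow(),
) -> list[np.ndarray]:
    """Cut the steady-state portion of a burst into single-cycle waveforms.

    Cycle boundaries generally fall between samples, so each cycle is read
    off a cubic-spline interpolant of the sweep at exact fractional-sample
    positions; all returned cycles therefore share the same length
    ``round(sampling_rate / frequency)`` with no cumulative truncation drift.

    Raises
    ------
    InsufficientSteadyStateError
        If the burst has no complete cycle left after the window exclusions.
    """
    stim = recording.stimulus
    spc = stim.samples_per_cycle
    if spc < 20:
        raise InsufficientSteadyStateError(
            f"only {spc:.1f} samples per cycle at {stim.frequency} Hz"
        )
    usable = stim.n_cycles - window.skip_onset - window.skip_offset
    if usable < 1:
        raise InsufficientSteadyStateError(
            f"insufficient steady state: {stim.n_cycles} cycles in burst, "
            f"window excludes {window.skip_onset + window.skip_offset}"
        )
    n_out = int(round(spc))
    pre_samples = recording.pre_ms / 1000.0 * stim.sampling_rate
    interp = CubicSpline(np.arange(len(recording.waveform)), recording.waveform)
    cycles = []
    for i in range(window.skip_onset, stim.n_cycles - window.skip_offset):
        positions = pre_samples + (i + np.arange(n_out) / n_out) * spc
        cycles.append(interp(positions))
    return cycles


def average_cycle(cycles: list[np.ndarray]) -> np.ndarray:
    """Pointwise mean of equally long single-cycle waveforms."""
    if len(cycles) == 0:
        raise ValueError("cannot average an empty list of cycles")
    lengths = {len(c) for c in cycles}
    if len(lengths) != 1:
        raise ValueError(f"ragged cycle lengths {sorted(lengths)}")
    return np.mean(np.asarray(cycles, dtype=float), axis=0)


def combine_phases(cond: np.ndarray, rare: np.ndarray) -> dict[str, np.ndarray]:
    """Difference and alternating waveforms from the two stimulus phases.

    The CM inverts with stimulus polarity while the rectified ANN does not,
    so the difference waveform ``(cond - rare) / 2`` retains CM-dominated
    energy and the alternating waveform ``(cond + rare) / 2`` retains
    ANN-dominated energy.
    """
    cond = np.asarray(cond, dtype=float)
    rare = np.asarray(rare, dtype=float)
    if cond.shape != rare.shape:
        raise ValueError(
            f"phase waveform length mismatch: {cond.shape} vs {rare.shape}"
        )
    return {
        "difference": (cond - rare) / 2.0,
        "alternating": (cond + rare) / 2.0,
    }


def _periodic_spline(cycle: np.ndarray) -> CubicSpline:
    """Periodic cubic spline of one cycle on the unit interval."""
    m = len(cycle)
    t = np.arange(m + 1) / m
    y = np.concatenate([cycle, cycle[:1]])
    return CubicSpline(t, y, bc_type="periodic")


def _fundamental_phase(cycle: np.ndarray) -> float:
    """Phase of the first Fourier harmonic, with a degeneracy guard."""
    spec = np.fft.rfft(cycle - np.mean(cycle))
    total = np.sum(np.abs(spec[1:]) ** 2)
    if total <= 0 or np.abs(spec[1]) ** 2 < _FUNDAMENTAL_POWER_FLOOR * total:
        raise DegenerateCycleError(
            "degenerate cycle: no usable fundamental for phase alignment"
        )
    return float(np.angle(spec[1]))


def alignment_shift(cycle: np.ndarray) -> float:
    """Circular shift (as a fraction of the period) that zeroes the phase.

    After shifting the cycle by this fraction, its fundamental is a pure
    ``sin`` starting at the positive-going zero crossing.
    """
    # For y(t) ~ sin(2 pi t + psi), arg(rfft[1]) = psi - pi/2; sampling at
    # t0 + k/N with t0 = -psi / (2 pi) cancels psi.
    psi = _fundamental_phase(cycle) + np.pi / 2.0
    return float((-psi / (2.0 * np.pi)) % 1.0)


def resample_cycle(
    cycle: np.ndarray, n_points: int, shift_fraction: float = 0.0
) -> np.ndarray:
    """Resample one period on ``n_points`` with an optional circular shift."""
    spline = _periodic_spline(np.asarray(cycle, dtype=float))
    positions = (np.arange(n_points) / n_points + shift_fraction) % 1.0
    return spline(positions)


def normalize_and_align(cycle: np.ndarray, n_points: int = 100) -> np.ndarray:
    """Put a cycle into canonical shape-only form.

    The cycle is resampled to ``n_points`` with a periodic cubic spline,
    circularly shifted so that sample 0 falls at the positive-going zero
    crossing of the fundamental (first-harmonic phase zero), and scaled to a
    half peak-to-peak amplitude of 1.  Classification then operates purely on
    waveform shape, independent of recorded amplitude and phase.
    """
    cycle = np.asarray(cycle, dtype=float)
    if n_points < 32:
        raise ValueError("n_points must be >= 32")
    if len(cycle) < 4 or np.ptp(cycle) == 0:
        raise DegenerateCycleError("degenerate cycle: constant waveform")
    out = resample_cycle(cycle, n_points, alignment_shift(cycle))
    half_pp = np.ptp(out) / 2.0
    if half_pp <= 0:
        raise DegenerateCycleError("degenerate cycle: zero amplitude")
    return out / half_pp


#: Channel order of the classifier input tensor.
CHANNELS = ("condensation", "rarefaction", "difference", "alternating")


@dataclass(frozen=True)
class AverageCycle:
    """The four average-cycle waveforms of one frequency/level condition.

    Raw waveforms are in microvolts.  Normalized copies share one circular
    shift, derived from the condensation fundamental, so that the relative
    timing between channels is preserved; each channel is amplitude-scaled
    to half peak-to-peak 1 (a numerically zero channel is stored as zeros).
    """

    condensation: np.ndarray
    rarefaction: np.ndarray
    difference: np.ndarray
    alternating: np.ndarray
    normalized: dict[str, np.ndarray]
    n_points: int
    n_cycles_averaged: int
    stimulus: StimulusSpec
    subject_id: str = ""
    cohort_tag: str = ""
    species: str = "gerbil"
    truth: dict = field(default_factory=dict)

    @classmethod
    def from_phase_pair(
        cls,
        cond: np.ndarray,
        rare: np.ndarray,
        stimulus: StimulusSpec,
        n_points: int = 100,
        n_cycles_averaged: int = 0,
        **meta,
    ) -> "AverageCycle":
        """Build the full quadruple from per-phase average cycles."""
        combined = combine_phases(cond, rare)
        raw = {
            "condensation": np.asarray(cond, dtype=float),
            "rarefaction": np.asarray(rare, dtype=float),
            **combined,
        }
        shift = alignment_shift(raw["condensation"])
        normalized = {}
        for name in CHANNELS:
            resampled = resample_cycle(raw[name], n_points, shift)
            half_pp = np.ptp(resampled) / 2.0
            # amplitude floor relative to the condensation channel keeps a
            # numerically silent channel (e.g. noiseless CM-only alternating)
            # from being blown up to full scale
            floor = 1e-9 * max(np.ptp(raw["condensation"]), 1e-30)
            if half_pp <= floor:
                normalized[name] = np.zeros(n_points)
            else:
                normalized[name] = resampled / half_pp
        raw_resampled = {
            name: resample_cycle(raw[name], n_points) for name in CHANNELS
        }
        return cls(
            condensation=raw_resampled["condensation"],
            rarefaction=raw_resampled["rarefaction"],
            difference=raw_resampled["difference"],
            alternating=raw_resampled["alternating"],
            normalized=normalized,
            n_points=n_points,
            n_cycles_averaged=n_cycles_averaged,
            stimulus=stimulus,
            **meta,
        )

    def tensor(self) -> np.ndarray:
        """Normalized cycles stacked as an (n_points, 4) array."""
        return np.stack([self.normalized[name] for name in CHANNELS], axis=1)

    def with_truth(self, **truth) -> "AverageCycle":
        return replace(self, truth={**self.truth, **truth})


def average_cycle_from_recordings(
    cond_rec: SweepRecording,
    rare_rec: SweepRecording,
    window: SteadyStateWindow = SteadyStateWindow(),
    n_points: int = 100,
) -> AverageCycle:
    """End-to-end construction: sweeps -> steady-state cycles -> AverageCycle."""
    cond_cycles = extract_cycles(cond_rec, window)
    rare_cycles = extract_cycles(rare_rec, window)
    cond = average_cycle(cond_cycles)
    rare = average_cycle(rare_cycles)
    stim = cond_rec.stimulus
    return AverageCycle.from_phase_pair(
        cond,
        rare,
        stimulus=stim,
        n_points=n_points,
        n_cycles_averaged=len(cond_cycles),
        subject_id=cond_rec.subject_id,
        cohort_tag=cond_rec.cohort_tag,
        species=cond_rec.species,
    )
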