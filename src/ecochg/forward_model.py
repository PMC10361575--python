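"""Biophysical forward model of ECochG average cycles and cohort simulator.

Two sources shape the steady-state round-window response to a tone:

* the **cochlear microphonic (CM)** — hair-cell transduction current that
  follows the stimulus sinusoid but saturates asymmetrically as the
  stereocilia reach the ends of their operating range; modeled here as a
  sinusoid passed through a two-sided saturating nonlinearity with
  independent peak and trough limits;
* the **auditory nerve neurophonic (ANN)** — the summed phase-locked firing
  of auditory-nerve fibers, modeled as a half-wave-rectified cycle histogram
  (optionally broadened by a "spread of excitation" blur) circularly
  convolved with a biphasic unit potential, the far-field shape of a single
  fiber's action potential at the round window.

The CM inverts when stimulus polarity flips while the rectified ANN does
not, which is what lets phase-alternating stimulation separate the two.

The cohort simulator composes these primitives into labeled synthetic
populations: normal hearing (NH), kainic-acid synaptopathy (KA), basal
hair-cell loss from high-frequency noise exposure (HF-NIHL), and a
human-like mixture, each record carrying its generating parameters.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
import pandas as pd

from .signal_core import STANDARD_FREQUENCIES, AverageCycle, StimulusSpec

__all__ = [
    "CMParams",
    "ANNParams",
    "UnitPotentialShape",
    "LesionSpec",
    "CohortSpec",
    "CohortDataset",
    "saturator",
    "cm_waveform",
    "ann_waveform",
    "synthesize_average_cycle",
    "simulate_cohort",
    "COHORT_PRESETS",
]


@dataclass(frozen=True)
class CMParams:
    """Generative parameters of the cochlear microphonic.

    ``amplitude`` is the emitted half peak-to-peak in microvolts; ``phase``
    is the stimulus phase offset in radians; ``peak_saturation`` and
    ``trough_saturation`` are the dimensionless asymptotes of the saturating
    nonlinearity (large values recover a pure sinusoid, values below ~1
    flatten the corresponding half of the cycle).
    """

    amplitude: float
    phase: float = 0.0
    peak_saturation: float = 1e6
    trough_saturation: float = 1e6

    def __post_init__(self) -> None:
        if self.amplitude < 0:
            raise ValueError("CM amplitude must be nonnegative")
        if self.peak_saturation <= 0 or self.trough_saturation <= 0:
            raise ValueError("saturation parameters must be positive")


@dataclass(frozen=True)
class UnitPotentialShape:
    """Biphasic action-potential shape as seen at the round window.

    A leading negative lobe followed by a positive lobe (N1-P1 -like),
    each Gaussian with the given full width at half maximum in
    milliseconds.  Widths are fixed in *time*, so the phase-domain footprint
    of the unit potential grows with stimulus frequency — the mechanism that
    washes out ANN waveform structure near 1 kHz.
    """

    neg_width_ms: float = 0.25
    pos_width_ms: float = 0.5
    separation_ms: float = 0.5
    amplitudes: tuple[float, float] = (-1.0, 0.5)

    def __post_init__(self) -> None:
        if self.neg_width_ms <= 0 or self.pos_width_ms <= 0:
            raise ValueError("lobe widths must be positive")
        if self.separation_ms < 0:
            raise ValueError("lobe separation must be nonnegative")
        if not (self.amplitudes[0] < 0 < self.amplitudes[1]):
            raise ValueError("unit potential must be biphasic (neg, pos)")

    @property
    def support_ms(self) -> float:
        """Effective duration: separation plus two FWHMs of each lobe."""
        return self.separation_ms + 2.0 * (self.neg_width_ms + self.pos_width_ms)

    def sample_on_cycle(self, frequency: float, n_points: int) -> np.ndarray:
        """Wrap the unit potential onto one stimulus period, mean removed."""
        period_ms = 1000.0 / frequency
        if self.support_ms > 3.0 * period_ms:
            raise ValueError(
                "unit potential exceeds cycle support "
                f"({self.support_ms:.2f} ms vs 3 x {period_ms:.2f} ms period)"
            )
        t = np.arange(n_points) / n_points * period_ms
        sd1 = self.neg_width_ms / 2.3548200450309493  # FWHM -> SD
        sd2 = self.pos_width_ms / 2.3548200450309493
        u = np.zeros(n_points)
        for m in range(-4, 5):  # wrapped copies for circular support
            tm = t + m * period_ms
            u += self.amplitudes[0] * np.exp(-0.5 * (tm / sd1) ** 2)
            u += self.amplitudes[1] * np.exp(-0.5 * ((tm - self.separation_ms) / sd2) ** 2)
        return u - np.mean(u)


@dataclass(frozen=True)
class ANNParams:
    """Generative parameters of the auditory nerve neurophonic.

    ``amplitude`` is the emitted half peak-to-peak in microvolts and
    ``spread`` (radians) is the SD of the wrapped-Gaussian blur applied to
    the cycle histogram to represent phase dispersion across fibers.
    """

    amplitude: float
    spread: float = 0.5
    unit_potential: UnitPotentialShape = field(default_factory=UnitPotentialShape)

    def __post_init__(self) -> None:
        if self.amplitude < 0:
            raise ValueError("ANN amplitude must be nonnegative")
        if self.spread < 0:
            raise ValueError("spread must be nonnegative")


def saturator(x: np.ndarray, s_p: float, s_t: float) -> np.ndarray:
    """Two-sided saturating nonlinearity with independent asymptotes.

    Exponential-approach form: unit slope at the origin, monotone
    nondecreasing, bounded in ``(-s_t, s_p)``.  Large asymptotes make it
    linear; small ones clip the corresponding polarity.
    """
    if s_p <= 0 or s_t <= 0:
        raise ValueError("saturation parameters must be positive")
    x = np.asarray(x, dtype=float)
    pos = s_p * (1.0 - np.exp(-np.clip(x, 0, None) / s_p))
    neg = -s_t * (1.0 - np.exp(np.clip(x, None, 0) / s_t))
    return np.where(x >= 0, pos, neg)


def _rescale_half_pp(y: np.ndarray, amplitude: float) -> np.ndarray:
    half_pp = np.ptp(y) / 2.0
    if half_pp == 0:
        return np.zeros_like(y)
    return amplitude * y / half_pp


def cm_waveform(
    stimulus: StimulusSpec, params: CMParams, n_points: int = 100
) -> np.ndarray:
    """One cycle of the saturated cochlear microphonic, half pp = amplitude."""
    theta = 2.0 * np.pi * np.arange(n_points) / n_points
    g = saturator(
        np.sin(theta + params.phase),
        params.peak_saturation,
        params.trough_saturation,
    )
    return _rescale_half_pp(g, params.amplitude)


def cycle_histogram(n_points: int) -> np.ndarray:
    """Half-wave-rectified sinusoidal drive: spike probability per phase bin."""
    theta = 2.0 * np.pi * np.arange(n_points) / n_points
    return np.maximum(np.sin(theta), 0.0)


def _blur_spectrum(n_points: int, spread: float) -> np.ndarray:
    """rFFT multiplier of a wrapped Gaussian of SD ``spread`` radians."""
    k = np.arange(n_points // 2 + 1)
    return np.exp(-0.5 * (k * spread) ** 2)


@lru_cache(maxsize=256)
def _histogram_spectrum(n_points: int) -> np.ndarray:
    out = np.fft.rfft(cycle_histogram(n_points))
    out.flags.writeable = False
    return out


@lru_cache(maxsize=1024)
def _unit_spectrum(
    shape: UnitPotentialShape, frequency: float, n_points: int
) -> np.ndarray:
    out = np.fft.rfft(shape.sample_on_cycle(frequency, n_points))
    out.flags.writeable = False
    return out


def ann_waveform(
    stimulus: StimulusSpec,
    params: ANNParams,
    n_points: int = 100,
    phase: float = 0.0,
) -> np.ndarray:
    """One cycle of the neurophonic: blurred histogram (*) unit potential.

    ``phase`` rotates the rectified drive, ``max(sin(theta + phase), 0)``:
    the neurophonic is phase-locked to the same basilar-membrane motion that
    drives the CM, so synthesis and fitting pass the CM phase here.  The
    result has zero mean (the unit potential is mean-removed, so the
    circular convolution kills the DC term) and half peak-to-peak equal to
    ``params.amplitude``.
    """
    if params.amplitude == 0:
        return np.zeros(n_points)
    spec = (
        _histogram_spectrum(n_points)
        * _blur_spectrum(n_points, params.spread)
        * _unit_spectrum(params.unit_potential, stimulus.frequency, n_points)
    )
    if phase != 0.0:
        k = np.arange(n_points // 2 + 1)
        spec = spec * np.exp(1j * k * phase)
    raw = np.fft.irfft(spec, n=n_points) / n_points
    return _rescale_half_pp(raw, params.amplitude)


def synthesize_average_cycle(
    cm: CMParams,
    ann: ANNParams,
    stimulus: StimulusSpec,
    snr_db: float | None = None,
    seed: int | np.random.Generator | None = None,
    n_points: int = 100,
    **meta,
) -> AverageCycle:
    """Compose CM + ANN + noise into a phase-alternating AverageCycle.

    The condensation cycle is ``cm + ann + noise``.  Flipping stimulus
    polarity inverts the CM (phase + pi) and shifts the rectified drive of
    the neurophonic by half a cycle, so the rarefaction ANN is the
    half-cycle-rotated condensation ANN; summing the two phases then
    interleaves the rectified responses, leaving only even harmonics
    (2 f0 dominant) in the alternating waveform.  ``snr_db`` sets Gaussian
    noise RMS relative to the noiseless condensation RMS; ``None`` means
    noiseless.  Deterministic under a fixed integer seed.
    """
    cm_cond = cm_waveform(stimulus, cm, n_points)
    cm_rare = cm_waveform(
        stimulus,
        CMParams(
            cm.amplitude,
            cm.phase + np.pi,
            cm.peak_saturation,
            cm.trough_saturation,
        ),
        n_points,
    )
    cond = cm_cond + ann_waveform(stimulus, ann, n_points, phase=cm.phase)
    rare = cm_rare + ann_waveform(stimulus, ann, n_points, phase=cm.phase + np.pi)
    if snr_db is not None:
        if not np.isfinite(snr_db):
            raise ValueError("snr_db must be finite (or None for noiseless)")
        rng = (
            seed
            if isinstance(seed, np.random.Generator)
            else np.random.default_rng(seed)
        )
        signal_rms = np.sqrt(np.mean(cond**2))
        noise_rms = signal_rms / 10.0 ** (snr_db / 20.0)
        cond = cond + rng.normal(0.0, noise_rms, n_points)
        rare = rare + rng.normal(0.0, noise_rms, n_points)
    cycle = AverageCycle.from_phase_pair(
        cond, rare, stimulus=stimulus, n_points=n_points, **meta
    )
    a_total = cm.amplitude + ann.amplitude
    return cycle.with_truth(
        a_cm=cm.amplitude,
        a_ann=ann.amplitude,
        ann_proportion=ann.amplitude / a_total if a_total > 0 else 0.0,
        ann_present=ann.amplitude > 0,
        cm_phase=cm.phase,
        peak_saturation=cm.peak_saturation,
        trough_saturation=cm.trough_saturation,
        spread=ann.spread,
    )


@dataclass(frozen=True)
class LesionSpec:
    """Frequency-banded lesion profile applied on top of the NH generator.

    ``ann_survival`` multiplies the ANN amplitude per frequency (apex-to-base
    gradient: kainic acid spares more apical fibers); ``cm_scale`` multiplies
    the CM amplitude; above ``cm_saturation_onset_db`` the CM level-growth
    plateaus (basal hair-cell loss blocks spread of excitation).
    """

    ann_survival: dict[float, float] = field(default_factory=dict)
    cm_scale: dict[float, float] = field(default_factory=dict)
    cm_saturation_onset_db: float | None = None

    def __post_init__(self) -> None:
        for table in (self.ann_survival, self.cm_scale):
            for f, v in table.items():
                if not 0.0 <= v <= 1.0:
                    raise ValueError(f"lesion fraction out of [0,1] at {f} Hz: {v}")

    def survival(self, frequency: float) -> float:
        return self.ann_survival.get(frequency, 1.0)

    def scale(self, frequency: float) -> float:
        return self.cm_scale.get(frequency, 1.0)


#: Apex-to-base ANN survival after round-window kainic acid: diffusion spares
#: apical (low-frequency) fibers more than basal ones.
_KA_SURVIVAL = {250.0: 0.45, 500.0: 0.30, 750.0: 0.20, 1000.0: 0.10}

#: Basal hair-cell loss reduces the CM everywhere (spread of excitation into
#: the base dominates high-level responses even for low-frequency tones).
_HFNIHL_CM_SCALE = {f: v for f, v in zip(
    (250.0, 500.0, 750.0, 1000.0, 2000.0, 4000.0),
    (0.55, 0.5, 0.45, 0.4, 0.25, 0.15),
)}

COHORT_PRESETS = ("NH", "NH_KA", "HFNIHL", "HFNIHL_KA", "HUMAN_LIKE")


@dataclass(frozen=True)
class CohortSpec:
    """Configuration of one simulated cohort."""

    preset: str = "NH"
    n_subjects: int = 10
    frequencies: tuple[float, ...] = tuple(float(f) for f in STANDARD_FREQUENCIES)
    levels: tuple[float, ...] = (30.0, 40.0, 50.0, 60.0, 70.0, 80.0, 90.0)
    snr_db: float = 25.0
    seed: int = 0
    n_points: int = 100

    def __post_init__(self) -> None:
        if self.preset not in COHORT_PRESETS:
            raise ValueError(
                f"unknown preset {self.preset!r}; choose from {COHORT_PRESETS}"
            )
        if self.n_subjects <= 0:
            raise ValueError("n_subjects must be positive")
        if not np.isfinite(self.snr_db):
            raise ValueError("snr_db must be finite")


@dataclass
class CohortDataset:
    """Simulated cohort: labeled AverageCycle records plus provenance."""

    records: list[AverageCycle]
    spec: CohortSpec

    def __len__(self) -> int:
        return len(self.records)

    def to_frame(self) -> pd.DataFrame:
        """Per-record metadata and generating truth as a DataFrame."""
        rows = []
        for i, rec in enumerate(self.records):
            rows.append(
                {
                    "record_id": i,
                    "subject_id": rec.subject_id,
                    "cohort_tag": rec.cohort_tag,
                    "frequency_hz": rec.stimulus.frequency,
                    "level_db": rec.stimulus.level,
                    **rec.truth,
                }
            )
        return pd.DataFrame(rows)

    def digest(self) -> str:
        """SHA-256 over raw waveforms and truth labels (determinism check)."""
        h = hashlib.sha256()
        for rec in self.records:
            h.update(np.ascontiguousarray(rec.condensation).tobytes())
            h.update(np.ascontiguousarray(rec.rarefaction).tobytes())
            h.update(repr(sorted(rec.truth.items())).encode())
        return h.hexdigest()


# -- NH generative defaults ---------------------------------------------------
# CM grows ~linearly in microvolts over 30-90 dB (gerbil round-window scale,
# hundreds of uV at 90 dB); saturation deepens with level; the ANN proportion
# declines with level because basal spread of excitation grows the CM faster
# than phase-locked firing can grow the ANN.
_CM_UV_PER_DB = 3.5
_CM_LEVEL_FLOOR_DB = 10.0
_CM_FREQ_SCALE = {250.0: 0.6, 500.0: 1.0, 750.0: 0.9, 1000.0: 0.8,
                  2000.0: 0.9, 4000.0: 1.0}
_PROPORTION_AT_30DB = 0.50
_PROPORTION_SLOPE_PER_DB = 0.006
#: True ANN proportions span 0.1-0.6: below ~0.1 the neurophonic is not
#: separable from the noise floor even in principle, and proportions much
#: above 0.6 do not occur physiologically (the CM always contributes).
_PROPORTION_RANGE = (0.10, 0.60)
_ANN_1KHZ_FACTOR = 0.4
_PHASE_LOCKING_MAX_HZ = 1000.0


def _nh_cm_amplitude(level: float, frequency: float, gain: float) -> float:
    freq_scale = _CM_FREQ_SCALE.get(frequency, 1.0)
    return gain * freq_scale * max(level - _CM_LEVEL_FLOOR_DB, 1.0)


def _saturation_at_level(level: float, rng: np.random.Generator) -> tuple[float, float]:
    # near-linear at 30 dB, strongly saturated by 90 dB; trough saturates
    # less than the peak (operating-point asymmetry)
    log_sp = 1.5 - 0.035 * (level - 30.0) + rng.normal(0.0, 0.15)
    s_p = float(np.clip(10.0**log_sp, 0.08, 1e6))
    s_t = float(np.clip(s_p * rng.uniform(2.0, 4.0), 0.08, 1e6))
    return s_p, s_t


def simulate_cohort(spec: CohortSpec) -> CohortDataset:
    """Generate a labeled synthetic cohort under the given preset.

    Every record carries its generating CM/ANN amplitudes, true ANN
    proportion, and presence label in ``record.truth``.  Identical specs
    (including seed) produce bit-identical datasets.
    """
    lesion = _preset_lesion(spec.preset)
    ka = spec.preset in ("NH_KA", "HFNIHL_KA")
    hf = spec.preset in ("HFNIHL", "HFNIHL_KA")
    human = spec.preset == "HUMAN_LIKE"
    root = np.random.SeedSequence(spec.seed)
    subject_seeds = root.spawn(spec.n_subjects)

    records: list[AverageCycle] = []
    for s_idx, s_seed in enumerate(subject_seeds):
        rng = np.random.default_rng(s_seed)
        gain = _CM_UV_PER_DB * rng.lognormal(0.0, 0.3)
        if human:
            gain *= 0.1  # human RW responses ~an order of magnitude smaller
        p0 = float(np.clip(rng.normal(_PROPORTION_AT_30DB, 0.08), 0.2, 0.7))
        p_slope = _PROPORTION_SLOPE_PER_DB * rng.uniform(0.7, 1.3)
        phase0 = rng.uniform(0.0, 2.0 * np.pi)
        # human-like mixture: some subjects have complete synaptopathy
        subject_survival = 1.0
        if human:
            subject_survival = 0.0 if rng.uniform() < 0.3 else rng.uniform(0.2, 1.0)
        for frequency in spec.frequencies:
            survival_jitter = rng.lognormal(0.0, 0.3) if ka else 1.0
            for level in spec.levels:
                stimulus = StimulusSpec(
                    frequency=frequency,
                    level=level,
                    sampling_rate=max(48000.0, 20.0 * frequency),
                )
                a_cm_nh = _nh_cm_amplitude(level, frequency, gain)
                a_cm = a_cm_nh * lesion.scale(frequency)
                if hf and lesion.cm_saturation_onset_db is not None:
                    onset = lesion.cm_saturation_onset_db
                    if level > onset:
                        # plateau: only 10% of the NH growth rate above onset
                        a_plateau = _nh_cm_amplitude(onset, frequency, gain)
                        a_cm = lesion.scale(frequency) * (
                            a_plateau + 0.1 * (a_cm_nh - a_plateau)
                        )
                s_p, s_t = _saturation_at_level(level, rng)
                if hf:
                    s_p, s_t = s_p * 0.5, s_t * 0.5  # earlier saturation

                if frequency <= _PHASE_LOCKING_MAX_HZ:
                    p_target = float(
                        np.clip(p0 - p_slope * (level - 30.0), *_PROPORTION_RANGE)
                    )
                    # ANN driven by the un-lesioned CM drive: under HF-NIHL the
                    # CM plateaus while the ANN keeps growing, raising the
                    # realized proportion at high levels
                    a_ann = p_target / (1.0 - p_target) * a_cm_nh
                    if frequency == 1000.0:
                        a_ann *= _ANN_1KHZ_FACTOR
                    survival = lesion.survival(frequency) if ka else 1.0
                    a_ann *= float(np.clip(survival * survival_jitter, 0.0, 1.0)) if ka else 1.0
                    a_ann *= subject_survival
                    spread = float(
                        np.clip(0.3 + 0.005 * (level - 30.0) + rng.normal(0, 0.1),
                                0.05, 1.2)
                    )
                else:
                    a_ann, spread = 0.0, 0.5
                rec = synthesize_average_cycle(
                    CMParams(a_cm, phase0, s_p, s_t),
                    ANNParams(a_ann, spread),
                    stimulus,
                    snr_db=spec.snr_db,
                    seed=rng,
                    n_points=spec.n_points,
                    subject_id=f"{spec.preset}_{s_idx:03d}",
                    cohort_tag=spec.preset,
                    species="human" if human else "gerbil",
                )
                records.append(rec)
    return CohortDataset(records=records, spec=spec)


def _preset_lesion(preset: str) -> LesionSpec:
    if preset == "NH":
        return LesionSpec()
    if preset == "NH_KA":
        return LesionSpec(ann_survival=dict(_KA_SURVIVAL))
    if preset == "HFNIHL":
        return LesionSpec(cm_scale=dict(_HFNIHL_CM_SCALE),
                          cm_saturation_onset_db=60.0)
    if preset == "HFNIHL_KA":
        return LesionSpec(
            ann_survival=dict(_KA_SURVIVAL),
            cm_scale=dict(_HFNIHL_CM_SCALE),
            cm_saturation_onset_db=60.0,
        )
    if preset == "HUMAN_LIKE":
        return LesionSpec()
    raise ValueError(f"unknown preset {preset!r}")
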