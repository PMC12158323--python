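"""Software emulation of the single-frequency sine-fit impedance phase meter.

The portable prototype measures impedance at one frequency (1 to about
100 Hz): it drives the tooth with a small sinusoidal voltage, converts the
resulting current to a voltage with a trans-impedance amplifier, digitizes
both channels with a 16-bit unipolar ADC, and estimates amplitude, phase and
frequency of each channel by non-linear sine fitting.  Fitting the full sine
model rejects residual high-frequency harmonics from the PWM-based stimulus
generation and wideband noise far better than a zero-crossing or FFT-bin
estimate.  Ten phase measurements are taken in sequence and averaged before
classification.

This module reproduces that chain numerically: ideal stimulus synthesis
(optionally with odd harmonics standing in for PWM residue), exact circuit
current, front-end gains, additive noise, unipolar offset and quantization,
four-parameter sine fits on both channels, phasor division, repetition and
averaging.  The analog PWM/low-pass hardware itself is not modeled.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple, Union

import numpy as np
from scipy.optimize import least_squares

from .circuit_model import CircuitParams, circuit_impedance
from .neuron_classifier import ClassificationResult, NeuronConfig, demineralization_index
from .synthetic_data import Waveform

__all__ = [
    "AcquisitionConfig",
    "PhaseMeasurement",
    "SineFitError",
    "sine_fit",
    "measure_impedance",
    "meter_classify",
]

#: circuit under test: full CircuitParams, (R, C) parallel pair, or a pure resistor
CircuitLike = Union[CircuitParams, Tuple[float, float], float]


@dataclass(frozen=True)
class AcquisitionConfig:
    """Front-end and acquisition settings of the emulated meter.

    ``tia_gain`` (V/A) and ``stim_gain`` (V/V) scale the current and stimulus
    channels onto the unipolar ADC range; defaults keep a 10 mV stimulus
    across the 77-500 kOhm tooth/validation impedance range on scale without
    clipping.  ``noise_sd`` is additive Gaussian noise in volts at each ADC
    input.
    """

    f0: float = 15.0
    v_amp: float = 0.01
    fs: float = 10_000.0
    duration: float = 1.0
    adc_bits: int = 16
    adc_range: float = 4.096
    tia_gain: float = 1.4e7
    stim_gain: float = 100.0
    noise_sd: float = 0.002
    n_repeats: int = 10
    seed: int = 0
    harmonic_level: float = 0.0  # odd-harmonic amplitude relative to fundamental

    def __post_init__(self) -> None:
        if not (1.0 <= self.f0 <= 100.0):
            raise ValueError("f0 must lie in the meter's 1-100 Hz range")
        if self.adc_bits < 8:
            raise ValueError("adc_bits must be >= 8")
        if self.n_repeats < 1:
            raise ValueError("n_repeats must be >= 1")
        if self.fs <= 2.0 * self.f0:
            raise ValueError("fs must exceed twice f0")


@dataclass(frozen=True)
class PhaseMeasurement:
    """Averaged single-frequency impedance estimate (positive-phase convention)."""

    z_mod: float
    z_phase: float
    f_est: float
    per_repeat_phases: Tuple[float, ...]
    phase_sd: float

    def __post_init__(self) -> None:
        if self.z_mod <= 0:
            raise ValueError("z_mod must be positive")
        if self.phase_sd < 0:
            raise ValueError("phase_sd must be non-negative")


class SineFitError(RuntimeError):
    """Four-parameter sine fit failed; carries the fixed-frequency fallback."""

    def __init__(self, message: str, fallback: Tuple[float, float, float, float]):
        super().__init__(message)
        self.fallback = fallback  # (amplitude, phase_deg, frequency, offset)


def _three_param_fit(x: np.ndarray, t: np.ndarray, f: float) -> Tuple[float, float, float]:
    """Linear LSQ of A*sin(2*pi*f*t + phi) + C at fixed frequency."""
    wt = 2.0 * np.pi * f * t
    M = np.column_stack([np.sin(wt), np.cos(wt), np.ones_like(t)])
    (a, b, c), *_ = np.linalg.lstsq(M, x, rcond=None)
    amp = math.hypot(a, b)
    phase = math.degrees(math.atan2(b, a))
    return amp, phase, c


def _norm_phase(deg: float) -> float:
    """Wrap to (-180, 180]."""
    out = (deg + 180.0) % 360.0 - 180.0
    return 180.0 if out == -180.0 else out


def sine_fit(w: Waveform, f_hint: float) -> Tuple[float, float, float, float]:
    """Four-parameter sine fit A*sin(2*pi*f*t + phi) + C with f free.

    Initialized from the fixed-frequency linear fit at ``f_hint``.  Returns
    (amplitude >= 0, phase in degrees in (-180, 180], frequency in Hz,
    offset).  The record must contain at least 3 cycles of ``f_hint`` and be
    sampled above Nyquist.  On divergence raises :class:`SineFitError`
    carrying the three-parameter fallback.
    """
    t = w.times
    x = w.samples
    n_cycles = (t[-1] - t[0]) * f_hint
    if n_cycles < 3.0:
        raise ValueError(f"record holds only {n_cycles:.2f} cycles of {f_hint} Hz; need >= 3")
    if w.fs <= 2.0 * f_hint:
        raise ValueError("sampling rate violates the Nyquist condition")

    amp0, ph0, c0 = _three_param_fit(x, t, f_hint)
    theta0 = np.array([max(amp0, 1e-15), math.radians(ph0), f_hint, c0])

    def resid(theta):
        A, phi, f, C = theta
        return A * np.sin(2.0 * np.pi * f * t + phi) + C - x

    res = least_squares(resid, theta0, method="lm", xtol=1e-14, ftol=1e-14, gtol=1e-14)
    if not res.success or not np.all(np.isfinite(res.x)):
        raise SineFitError("four-parameter sine fit did not converge",
                           fallback=(amp0, _norm_phase(ph0), f_hint, c0))
    A, phi, f, C = res.x
    if A < 0:  # fold the sign into the phase
        A, phi = -A, phi + math.pi
    return float(A), _norm_phase(math.degrees(phi)), float(abs(f)), float(C)


def _impedance_at(circuit: CircuitLike, f0: float) -> complex:
    if isinstance(circuit, CircuitParams):
        return circuit_impedance(circuit, f0)
    if isinstance(circuit, tuple):
        r, c = circuit
        if r <= 0 or c < 0:
            raise ValueError("R must be > 0 and C >= 0")
        w = 2.0 * np.pi * f0
        return r / (1.0 + 1j * w * r * c)
    r = float(circuit)
    if r <= 0:
        raise ValueError("resistance must be > 0")
    return complex(r)


def _acquire(ideal: np.ndarray, cfg: AcquisitionConfig,
             rng: np.random.Generator, channel: str) -> np.ndarray:
    """Offset to midscale, add noise, check clipping, quantize."""
    v = ideal + cfg.adc_range / 2.0
    if cfg.noise_sd > 0:
        v = v + rng.normal(0.0, cfg.noise_sd, size=v.size)
    if np.any(v < 0.0) or np.any(v > cfg.adc_range):
        raise ValueError(f"ADC clipping on the {channel} channel "
                         f"(signal exceeds the 0-{cfg.adc_range} V unipolar range)")
    step = cfg.adc_range / 2 ** cfg.adc_bits
    return np.round(v / step) * step


def measure_impedance(circuit: CircuitLike,
                      cfg: Optional[AcquisitionConfig] = None) -> PhaseMeasurement:
    """Emulated single-frequency impedance measurement.

    Synthesizes stimulus and exact circuit current, passes both through the
    front-end model (gain, noise, unipolar offset, quantization), sine-fits
    both channels, and forms Z = V_phasor / I_phasor.  The whole sequence is
    repeated ``cfg.n_repeats`` times; the reported phase is the repeat
    average, in the positive-degrees convention.  Deterministic given
    ``cfg.seed``.
    """
    cfg = cfg or AcquisitionConfig()
    z0 = _impedance_at(circuit, cfg.f0)
    rng = np.random.default_rng(cfg.seed)
    t = np.arange(int(round(cfg.fs * cfg.duration))) / cfg.fs
    wt = 2.0 * np.pi * cfg.f0 * t

    v_ideal = cfg.v_amp * np.sin(wt)
    if cfg.harmonic_level > 0:  # residual PWM harmonics on the stimulus
        for k in (3, 5):
            v_ideal = v_ideal + cfg.harmonic_level * cfg.v_amp * np.sin(k * wt)
    i_amp = cfg.v_amp / abs(z0)
    i_ideal = i_amp * np.sin(wt - np.angle(z0))
    if cfg.harmonic_level > 0:
        # worst case for the fit: harmonics reach the current channel at the
        # same relative level as on the stimulus
        for k in (3, 5):
            i_ideal = i_ideal + cfg.harmonic_level * i_amp * np.sin(k * wt - np.angle(z0))

    phases: List[float] = []
    mods: List[float] = []
    f_ests: List[float] = []
    for _ in range(cfg.n_repeats):
        v_adc = _acquire(cfg.stim_gain * v_ideal, cfg, rng, "stimulus")
        i_adc = _acquire(cfg.tia_gain * i_ideal, cfg, rng, "current")
        av, pv, fv, _ = sine_fit(Waveform(v_adc, cfg.fs), cfg.f0)
        ai, pi_, fi, _ = sine_fit(Waveform(i_adc, cfg.fs), cfg.f0)
        z_mod = (av / cfg.stim_gain) / (ai / cfg.tia_gain)
        z_phase = _norm_phase(pv - pi_)
        phases.append(abs(z_phase))
        mods.append(z_mod)
        f_ests.append(0.5 * (fv + fi))

    phases_arr = np.array(phases)
    sd = float(np.std(phases_arr, ddof=1)) if len(phases) > 1 else 0.0
    return PhaseMeasurement(z_mod=float(np.mean(mods)),
                            z_phase=float(np.mean(phases_arr)),
                            f_est=float(np.mean(f_ests)),
                            per_repeat_phases=tuple(phases),
                            phase_sd=sd)


def meter_classify(m: PhaseMeasurement,
                   cfg: Optional[NeuronConfig] = None) -> ClassificationResult:
    """Feed the averaged meter phase to the single-neuron classifier."""
    cfg = cfg or NeuronConfig()
    index = demineralization_index(m.z_phase, cfg)
    label = "DM" if index >= cfg.threshold else "ND"
    return ClassificationResult(index=index, label=label, input_phase=m.z_phase)
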