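"""Synthetic labeled datasets of tooth impedance spectra and waveforms.

No measured tooth spectra are publicly deposited, so validation of the
pipeline runs on synthetic data with the statistical structure the
classifiers assume: class-conditional circuit parameters centered on the
fitted element values for sound (ND) and demineralized (DM) enamel,
log-normal spread on R1/R2/Q (element values vary geometrically between
teeth), Gaussian spread on N, triplicate acquisitions per tooth with small
multiplicative magnitude noise and additive phase noise, and time-domain
stimulus/current waveform pairs for the single-frequency phase meter.

The generator targets statistical realism (class centers, spreads, replicate
structure), not mechanistic realism: no demineralization kinetics, pH or
enamel microstructure is modeled.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np

from .circuit_model import (
    DM_PARAMS,
    ND_PARAMS,
    CircuitParams,
    FrequencyGrid,
    ImpedanceSpectrum,
    circuit_impedance,
    simulate_spectrum,
    standard_grid,
)

__all__ = [
    "PopulationModel",
    "NoiseModel",
    "LabeledDataset",
    "Waveform",
    "sample_parameters",
    "generate_labeled_dataset",
    "generate_waveforms",
]


@dataclass(frozen=True)
class PopulationModel:
    """Class-conditional distribution of circuit parameters.

    r1, r2, q are log-normal around the class center with geometric standard
    deviation ``log_sd`` (a dimensionless factor; 1.6 means roughly +/-60%
    one-sigma spread); n is Gaussian with SD ``n_sd``, clipped to (0, 1].
    Defaults put the class centers at the fitted sound/demineralized element
    values, with spread wide enough that the classes overlap slightly in
    parameter space.
    """

    nd_center: CircuitParams = ND_PARAMS
    dm_center: CircuitParams = DM_PARAMS
    log_sd: Dict[str, float] = field(
        default_factory=lambda: {"r1": 1.6, "r2": 1.6, "q": 1.6})
    n_sd: float = 0.04
    seed: int = 0

    def __post_init__(self) -> None:
        if any(v < 1.0 for v in self.log_sd.values()):
            raise ValueError("geometric spreads must be >= 1 (1 = no spread)")
        if self.n_sd < 0:
            raise ValueError("n_sd must be >= 0")

    def center(self, label: str) -> CircuitParams:
        if label == "ND":
            return self.nd_center
        if label == "DM":
            return self.dm_center
        raise ValueError(f"label must be 'ND' or 'DM'; got {label!r}")


@dataclass(frozen=True)
class NoiseModel:
    """Per-point acquisition noise and replicate structure.

    Defaults (2% relative magnitude noise, 1 degree phase noise, triplicate
    acquisitions) match visibly tight repeated measurements on the same tooth.
    """

    mag_rel_sd: float = 0.02
    phase_sd: float = 1.0  # degrees
    n_replicates: int = 3

    def __post_init__(self) -> None:
        if self.mag_rel_sd < 0 or self.phase_sd < 0:
            raise ValueError("noise levels must be >= 0")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")


@dataclass
class LabeledDataset:
    """Labeled spectra with generating-parameter provenance.

    ``spectra`` holds every replicate; ``provenance`` maps tooth_id to the
    CircuitParams that generated it; ``features`` optionally caches per-tooth
    (r1, r2, q) triples for the parameter-space classifier.
    """

    spectra: List[ImpedanceSpectrum]
    provenance: Dict[int, CircuitParams]
    features: Optional[Dict[int, Tuple[float, float, float]]] = None

    @property
    def tooth_ids(self) -> List[int]:
        return sorted(self.provenance)

    def label_of(self, tooth_id: int) -> str:
        for s in self.spectra:
            if s.tooth_id == tooth_id:
                return s.label
        raise KeyError(tooth_id)

    def replicates(self, tooth_id: int) -> List[ImpedanceSpectrum]:
        return [s for s in self.spectra if s.tooth_id == tooth_id]

    def labels(self) -> Dict[int, str]:
        return {t: self.label_of(t) for t in self.tooth_ids}


def sample_parameters(m: PopulationModel, label: str, k: int,
                      rng: Optional[np.random.Generator] = None) -> List[CircuitParams]:
    """Draw ``k`` circuit-parameter sets for one class.

    Deterministic given ``m.seed`` (per-label independent streams) unless an
    explicit ``rng`` is supplied.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    center = m.center(label)
    if rng is None:
        # independent, reproducible stream per label
        rng = np.random.default_rng([m.seed, {"ND": 1, "DM": 2}[label]])
    out = []
    for _ in range(k):
        vals = {}
        for name, c in (("r1", center.r1), ("r2", center.r2), ("q", center.q)):
            gsd = m.log_sd[name]
            vals[name] = float(c * np.exp(rng.normal(0.0, np.log(gsd))))
        n = float(np.clip(rng.normal(center.n, m.n_sd), 1e-6, 1.0))
        out.append(CircuitParams(n=n, **vals))
    return out


def _add_noise(s: ImpedanceSpectrum, noise: NoiseModel,
               rng: np.random.Generator, replicate_id: int) -> ImpedanceSpectrum:
    """Apply |Z|*(1+eps) magnitude noise and additive phase noise per point."""
    mag = s.magnitude * (1.0 + rng.normal(0.0, noise.mag_rel_sd, size=len(s.grid)))
    mag = np.maximum(mag, 1e-12)
    ph = np.angle(s.z) + np.radians(rng.normal(0.0, noise.phase_sd, size=len(s.grid)))
    return ImpedanceSpectrum(grid=s.grid, z=mag * np.exp(1j * ph),
                             replicate_id=replicate_id, label=s.label,
                             tooth_id=s.tooth_id)


def generate_labeled_dataset(m: Optional[PopulationModel] = None,
                             noise: Optional[NoiseModel] = None,
                             n_per_class: int = 12,
                             grid: Optional[FrequencyGrid] = None) -> LabeledDataset:
    """Balanced dataset of ``n_per_class`` teeth per class, with replicates.

    Each tooth gets one parameter draw and ``noise.n_replicates`` noisy
    spectrum replicates; provenance records the generating parameters so any
    spectrum can be recomputed.  Fully reproducible from ``m.seed``.
    """
    m = m or PopulationModel()
    noise = noise or NoiseModel()
    grid = grid or standard_grid()
    rng = np.random.default_rng([m.seed, 0xD47A])

    spectra: List[ImpedanceSpectrum] = []
    provenance: Dict[int, CircuitParams] = {}
    features: Dict[int, Tuple[float, float, float]] = {}
    tooth_id = 0
    for label in ("ND", "DM"):
        draws = sample_parameters(m, label, n_per_class, rng=rng)
        for p in draws:
            clean = simulate_spectrum(p, grid, label=label, tooth_id=tooth_id)
            for rep in range(noise.n_replicates):
                spectra.append(_add_noise(clean, noise, rng, replicate_id=rep))
            provenance[tooth_id] = p
            features[tooth_id] = (p.r1, p.r2, p.q)
            tooth_id += 1
    return LabeledDataset(spectra=spectra, provenance=provenance, features=features)


@dataclass(frozen=True)
class Waveform:
    """Uniformly sampled voltage record."""

    samples: np.ndarray
    fs: float
    t0: float = 0.0

    def __post_init__(self) -> None:
        if self.fs <= 0:
            raise ValueError("fs must be > 0")
        x = np.asarray(self.samples, dtype=float)
        if not np.all(np.isfinite(x)):
            raise ValueError("samples must be finite")
        object.__setattr__(self, "samples", x)

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.samples.size) / self.fs


def generate_waveforms(p: CircuitParams, f0: float, v_amp: float = 0.01,
                       fs: float = 10_000.0, duration: float = 0.5,
                       noise_sd: float = 0.0,
                       seed: int = 0) -> Tuple[Waveform, Waveform]:
    """Stimulus voltage and resulting current for a single-frequency measurement.

    The stimulus is v(t) = v_amp*sin(2*pi*f0*t); the current follows the exact
    complex relationship i = v/Z(f0) (amplitude v_amp/|Z|, phase lead equal to
    the capacitive phase magnitude), plus optional white Gaussian noise on the
    current in amperes.
    """
    if fs <= 2.0 * f0:
        raise ValueError(f"fs={fs} violates the Nyquist condition for f0={f0}")
    if duration * f0 < 5.0:
        raise ValueError("duration must cover at least 5 stimulus cycles")
    t = np.arange(int(round(fs * duration))) / fs
    z0 = circuit_impedance(p, f0)
    v = v_amp * np.sin(2.0 * np.pi * f0 * t)
    # i = v/Z: current phase is -angle(Z), a lead for capacitive circuits
    i = (v_amp / abs(z0)) * np.sin(2.0 * np.pi * f0 * t - np.angle(z0))
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        i = i + rng.normal(0.0, noise_sd, size=t.size)
    return Waveform(v, fs), Waveform(i, fs)
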