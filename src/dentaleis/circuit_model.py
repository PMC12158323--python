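"""Equivalent-circuit forward model for tooth impedance spectra.

Enamel/electrolyte interfaces measured by two-electrode electrochemical
impedance spectroscopy behave, to good approximation, like a first-order
system: a series resistance ``R1`` (solution plus contact) feeding a parallel
combination of a charge-transfer resistance ``R2`` and a constant-phase
element (CPE) that stands in for the non-ideal double-layer capacitance::

    Z(f) = R1 + R2 * Z_CPE / (R2 + Z_CPE),   Z_CPE = 1 / ((j*2*pi*f)**N * Q)

``N`` in (0, 1] interpolates between a resistor (N=0, degenerate) and an
ideal capacitor (N=1).  Demineralization increases enamel porosity and ionic
conduction, which shifts all four element values and, most visibly, the
impedance phase in the low tens of Hz.

Sign convention: impedance is held internally as a true complex number, so a
capacitive circuit has negative imaginary part and negative phase.  Every
user-facing phase (classifier input, CSV output, meter output) is reported as
a positive magnitude in degrees, matching how dental impedance phases are
quoted in practice.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

__all__ = [
    "CircuitParams",
    "FrequencyGrid",
    "ImpedanceSpectrum",
    "ND_PARAMS",
    "DM_PARAMS",
    "cpe_impedance",
    "circuit_impedance",
    "simulate_spectrum",
    "phase_at_frequency",
    "standard_grid",
]

LABELS = ("ND", "DM")  # Non-Demineralized / Demineralized


@dataclass(frozen=True)
class CircuitParams:
    """The four fitted element values of the R1-(R2 || CPE) circuit.

    Parameters
    ----------
    r1 : float
        Series resistance in ohms (> 0).
    r2 : float
        Charge-transfer resistance in ohms (> 0).
    q : float
        CPE coefficient in s^n/ohm (> 0).
    n : float
        CPE exponent, dimensionless, in (0, 1].
    """

    r1: float
    r2: float
    q: float
    n: float

    def __post_init__(self) -> None:
        if not (self.r1 > 0 and self.r2 > 0 and self.q > 0):
            raise ValueError(
                f"r1, r2, q must be positive; got r1={self.r1}, r2={self.r2}, q={self.q}"
            )
        if not (0.0 < self.n <= 1.0):
            raise ValueError(f"n must lie in (0, 1]; got n={self.n}")

    def to_dict(self) -> dict:
        return {"r1_ohm": self.r1, "r2_ohm": self.r2, "q_s^n_per_ohm": self.q, "n": self.n}

    @classmethod
    def from_dict(cls, d: dict) -> "CircuitParams":
        return cls(r1=d["r1_ohm"], r2=d["r2_ohm"], q=d["q_s^n_per_ohm"], n=d["n"])

    def as_array(self) -> np.ndarray:
        return np.array([self.r1, self.r2, self.q, self.n])


#: Class-center element values for non-demineralized and demineralized enamel,
#: as estimated by equivalent-circuit fitting of measured tooth spectra.
ND_PARAMS = CircuitParams(r1=3.9e3, r2=2.6e7, q=3.3e-7, n=0.81)
DM_PARAMS = CircuitParams(r1=7.5e4, r2=3.4e7, q=2.1e-7, n=0.86)


@dataclass(frozen=True)
class FrequencyGrid:
    """Strictly increasing grid of positive frequencies in Hz."""

    frequencies: np.ndarray

    def __post_init__(self) -> None:
        f = np.asarray(self.frequencies, dtype=float)
        if f.ndim != 1 or f.size == 0:
            raise ValueError("frequency grid must be a non-empty 1-D array")
        if np.any(f <= 0) or not np.all(np.isfinite(f)):
            raise ValueError("all frequencies must be finite and > 0")
        if np.any(np.diff(f) <= 0):
            raise ValueError("frequencies must be strictly increasing")
        object.__setattr__(self, "frequencies", f)

    def __len__(self) -> int:
        return int(self.frequencies.size)

    @property
    def fmin(self) -> float:
        return float(self.frequencies[0])

    @property
    def fmax(self) -> float:
        return float(self.frequencies[-1])


def standard_grid(points_per_decade: int = 5,
                  fmin: float = 0.1,
                  fmax: float = 1.0e4) -> FrequencyGrid:
    """Log-uniform acquisition grid, endpoints inclusive.

    Defaults reproduce the acquisition protocol: 0.1 Hz to 10 kHz at five
    points per decade, i.e. 10**(k/5) for k = -5..20, 26 points.
    """
    k0 = round(np.log10(fmin) * points_per_decade)
    k1 = round(np.log10(fmax) * points_per_decade)
    if k1 <= k0:
        raise ValueError("fmax must exceed fmin by at least one grid step")
    exps = np.arange(k0, k1 + 1) / points_per_decade
    return FrequencyGrid(10.0 ** exps)


@dataclass(frozen=True)
class ImpedanceSpectrum:
    """Complex impedance sampled on a frequency grid.

    ``z`` keeps the physical sign (capacitive => Im(z) < 0).  ``label`` is
    "ND"/"DM" when known, ``tooth_id``/``replicate_id`` identify repeated
    acquisitions of the same sample.
    """

    grid: FrequencyGrid
    z: np.ndarray
    replicate_id: int = 0
    label: Optional[str] = None
    tooth_id: Optional[int] = None

    def __post_init__(self) -> None:
        z = np.asarray(self.z, dtype=complex)
        if z.shape != (len(self.grid),):
            raise ValueError(
                f"z has shape {z.shape}, expected ({len(self.grid)},) to match the grid"
            )
        if not np.all(np.isfinite(z)):
            raise ValueError("impedance values must be finite")
        if np.any(np.abs(z) <= 0):
            raise ValueError("impedance magnitude must be positive everywhere")
        if self.label is not None and self.label not in LABELS:
            raise ValueError(f"label must be one of {LABELS}; got {self.label!r}")
        object.__setattr__(self, "z", z)

    @property
    def frequencies(self) -> np.ndarray:
        return self.grid.frequencies

    @property
    def magnitude(self) -> np.ndarray:
        return np.abs(self.z)

    @property
    def phase_deg(self) -> np.ndarray:
        """Phase in positive-degrees convention (capacitive phase magnitude)."""
        return np.abs(np.degrees(np.angle(self.z)))


def cpe_impedance(q: float, n: float, f) -> complex:
    """Impedance of a constant-phase element, 1 / ((j*2*pi*f)**n * q).

    The phase is exactly -n*90 degrees and the magnitude 1/(q*(2*pi*f)**n).
    ``n`` = 1 is an ideal capacitor of capacitance ``q``; ``n`` = 0 degenerates
    to a resistor of 1/``q``.  Accepts scalar or array ``f``.
    """
    f = np.asarray(f, dtype=float)
    if q <= 0:
        raise ValueError(f"CPE coefficient q must be > 0; got {q}")
    if not (0.0 <= n <= 1.0):
        raise ValueError(f"CPE exponent n must lie in [0, 1]; got {n}")
    if np.any(f <= 0):
        raise ValueError("frequency must be > 0")
    z = 1.0 / ((1j * 2.0 * np.pi * f) ** n * q)
    return complex(z) if z.ndim == 0 else z


def circuit_impedance(p: CircuitParams, f) -> complex:
    """Impedance of R1 in series with (R2 parallel CPE) at frequency ``f`` (Hz)."""
    zc = cpe_impedance(p.q, p.n, f)
    z = p.r1 + (p.r2 * zc) / (p.r2 + zc)
    return complex(z) if np.ndim(z) == 0 else z


def simulate_spectrum(p: CircuitParams,
                      grid: FrequencyGrid,
                      replicate_id: int = 0,
                      label: Optional[str] = None,
                      tooth_id: Optional[int] = None) -> ImpedanceSpectrum:
    """Noise-free forward simulation of the circuit on ``grid``."""
    z = circuit_impedance(p, grid.frequencies)
    return ImpedanceSpectrum(grid=grid, z=np.atleast_1d(z),
                             replicate_id=replicate_id, label=label,
                             tooth_id=tooth_id)


def phase_at_frequency(s: ImpedanceSpectrum, f: float) -> float:
    """Impedance phase at ``f`` in positive degrees.

    Exact at grid points; between them the phase is interpolated linearly in
    log10(f), which is accurate because the circuit's phase is smooth on a log
    frequency axis.  ``f`` must lie within the grid range.
    """
    if not (s.grid.fmin <= f <= s.grid.fmax):
        raise ValueError(
            f"frequency {f} Hz outside spectrum range "
            f"[{s.grid.fmin}, {s.grid.fmax}] Hz"
        )
    return float(np.interp(np.log10(f), np.log10(s.frequencies), s.phase_deg))
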