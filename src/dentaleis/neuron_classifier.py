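"""Single-neuron (inverted-sigmoid perceptron) classifier on the 15 Hz phase.

Sound enamel shows a large capacitive phase at 15 Hz (about 70 degrees in
positive convention); demineralized enamel a much smaller one (about 44
degrees).  A single perceptron with an inverted (decreasing) sigmoid maps the
phase to a demineralization index from 0% (sound) to 100% (fully
demineralized):

    index = 100 / (1 + exp(G * (W*phase - IB)))

With W = 1 the input bias IB is the 50% midpoint of the decision function on
the phase axis; the gain G sets its steepness.  The calibration rule places
IB at the mean phase of demineralized training teeth plus 1.5 standard
deviations, i.e. just above where nearly all demineralized teeth fall, and
picks G from a small grid by training error.  The default configuration is
IB = 65, W = 1, G = 2, decision threshold 50%, classification frequency 15 Hz.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Optional

import numpy as np

from .circuit_model import ImpedanceSpectrum, phase_at_frequency
from .synthetic_data import LabeledDataset

__all__ = [
    "NeuronConfig",
    "ClassificationResult",
    "demineralization_index",
    "classify",
    "calibrate",
    "dataset_tooth_phases",
]


@dataclass(frozen=True)
class NeuronConfig:
    """Tunable parameters of the single-neuron classifier."""

    ib: float = 65.0       # input bias, degrees
    w: float = 1.0         # weighting factor applied to the input phase
    g: float = 2.0         # sigmoid gain, per degree
    threshold: float = 50.0  # decision cut on the index, percent
    f0: float = 15.0       # classification frequency, Hz

    def __post_init__(self) -> None:
        if self.g <= 0:
            raise ValueError("gain g must be > 0")
        if not (0.0 < self.threshold < 100.0):
            raise ValueError("threshold must lie strictly between 0 and 100")
        if self.f0 <= 0:
            raise ValueError("classification frequency must be > 0")

    def to_dict(self) -> dict:
        return {"ib": self.ib, "w": self.w, "g": self.g,
                "threshold": self.threshold, "f0": self.f0}

    @classmethod
    def from_dict(cls, d: dict) -> "NeuronConfig":
        return cls(**d)


@dataclass(frozen=True)
class ClassificationResult:
    index: float        # demineralization index, percent in [0, 100]
    label: str          # "ND" or "DM"
    input_phase: float  # degrees, positive convention


def demineralization_index(phase: float, cfg: Optional[NeuronConfig] = None) -> float:
    """Inverted-sigmoid demineralization index in percent.

    Strictly decreasing in ``phase``; equals 50 exactly when w*phase = ib.
    Saturates smoothly to 0 (clearly sound) and 100 (clearly demineralized).
    """
    cfg = cfg or NeuronConfig()
    if not math.isfinite(phase):
        raise ValueError("phase must be finite")
    x = cfg.g * (cfg.w * phase - cfg.ib)
    # exp underflows harmlessly to 0 for very negative x; cap the positive tail
    return 100.0 / (1.0 + math.exp(min(x, 700.0)))


def classify(s: ImpedanceSpectrum, cfg: Optional[NeuronConfig] = None) -> ClassificationResult:
    """Classify a spectrum from its phase at the classification frequency.

    Ties at the threshold classify as DM: in a screening context a borderline
    tooth should be flagged, not cleared.
    """
    cfg = cfg or NeuronConfig()
    phase = phase_at_frequency(s, cfg.f0)
    index = demineralization_index(phase, cfg)
    label = "DM" if index >= cfg.threshold else "ND"
    return ClassificationResult(index=index, label=label, input_phase=phase)


def dataset_tooth_phases(d: LabeledDataset, f0: float = 15.0) -> dict:
    """Per-tooth replicate-averaged phase at ``f0``, with labels.

    Returns {tooth_id: (mean_phase_deg, label)}.
    """
    out = {}
    for t in d.tooth_ids:
        reps = d.replicates(t)
        phases = [phase_at_frequency(s, f0) for s in reps]
        out[t] = (float(np.mean(phases)), reps[0].label)
    return out


def calibrate(training: LabeledDataset,
              g_grid: Iterable[float] = (0.5, 1.0, 2.0, 4.0),
              f0: float = 15.0) -> NeuronConfig:
    """Derive a NeuronConfig from a labeled training set.

    IB = mean(DM phases) + 1.5 * sample SD(DM phases), computed over
    per-tooth replicate-averaged phases; W = 1; G chosen from ``g_grid`` by
    minimum training error rate (ties broken toward the smaller, smoother
    gain); threshold fixed at 50%.
    """
    phases = dataset_tooth_phases(training, f0)
    dm = np.array([ph for ph, lab in phases.values() if lab == "DM"])
    nd = np.array([ph for ph, lab in phases.values() if lab == "ND"])
    if dm.size == 0 or nd.size == 0:
        raise ValueError("training set must contain both ND and DM teeth")
    ib = float(np.mean(dm) + 1.5 * np.std(dm, ddof=1))

    best_g, best_err = None, None
    for g in g_grid:
        cfg = NeuronConfig(ib=ib, w=1.0, g=float(g), threshold=50.0, f0=f0)
        errors = 0
        for ph, lab in phases.values():
            pred = "DM" if demineralization_index(ph, cfg) >= cfg.threshold else "ND"
            errors += pred != lab
        err = errors / len(phases)
        if best_err is None or err < best_err or (err == best_err and g < best_g):
            best_g, best_err = float(g), err
    return NeuronConfig(ib=ib, w=1.0, g=best_g, threshold=50.0, f0=f0)
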