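"""MLP classifier on fitted circuit parameters (R1, R2, Q1).

A small multi-layer perceptron — two hidden layers of three and two tanh
neurons, a single logistic output unit — classifies teeth from their fitted
equivalent-circuit element values.  Because the three features span very
different magnitudes (kiloohms to hundreds of nanofarad-equivalents), each is
min-max normalized to [0, 1] using training-set extremes only.  The network
is trained with the L-BFGS quasi-Newton solver, which behaves well on small
tabular datasets; evaluation uses a stratified, tooth-grouped 70/30 split and
stratified 5-fold cross-validation.

The CPE exponent N is excluded from the default feature set: its variation is
small and weakly related to demineralization, and including it does not help.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from sklearn.neural_network import MLPClassifier

from .synthetic_data import LabeledDataset
from .metrics import confusion, roc_auc, scores

__all__ = [
    "MLPConfig",
    "Normalizer",
    "TrainedMLP",
    "CVReport",
    "split_dataset",
    "fit_normalizer",
    "apply_normalizer",
    "train_mlp",
    "predict",
    "cross_validate",
    "dataset_features",
]

FEATURE_NAMES = ("r1", "r2", "q", "n")


@dataclass(frozen=True)
class MLPConfig:
    """Network architecture and training settings."""

    hidden_layers: Tuple[int, int] = (3, 2)
    activation: str = "tanh"
    solver: str = "lbfgs"
    l2_penalty: float = 1e-4
    max_iter: int = 2000
    seed: int = 0
    features: Tuple[str, ...] = ("r1", "r2", "q")

    def __post_init__(self) -> None:
        if not self.features:
            raise ValueError("feature set must be non-empty")
        bad = set(self.features) - set(FEATURE_NAMES)
        if bad:
            raise ValueError(f"unknown features: {sorted(bad)}")

    def to_dict(self) -> dict:
        return {
            "hidden_layers": list(self.hidden_layers),
            "activation": self.activation,
            "solver": self.solver,
            "l2_penalty": self.l2_penalty,
            "max_iter": self.max_iter,
            "seed": self.seed,
            "features": list(self.features),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "MLPConfig":
        d = dict(d)
        if "hidden_layers" in d:
            d["hidden_layers"] = tuple(d["hidden_layers"])
        if "features" in d:
            d["features"] = tuple(d["features"])
        return cls(**d)


@dataclass(frozen=True)
class Normalizer:
    """Per-feature min-max scaling learned from training data.

    Transforms training data into [0, 1]; test values outside the training
    range map outside [0, 1] without clipping, so no test-set information
    leaks into the transform.
    """

    mins: np.ndarray
    maxs: np.ndarray

    def __post_init__(self) -> None:
        if np.any(self.maxs <= self.mins):
            raise ValueError("each feature needs max > min (constant feature?)")


@dataclass
class TrainedMLP:
    model: MLPClassifier
    normalizer: Normalizer
    config: MLPConfig
    converged: bool = True


@dataclass(frozen=True)
class CVReport:
    """Per-split accuracy, recall and AUC with their mean and SD."""

    accuracy: Tuple[float, ...]
    recall: Tuple[float, ...]
    auc: Tuple[float, ...]

    @property
    def mean(self) -> Dict[str, float]:
        return {k: float(np.mean(getattr(self, k))) for k in ("accuracy", "recall", "auc")}

    @property
    def sd(self) -> Dict[str, float]:
        return {k: float(np.std(getattr(self, k), ddof=1)) for k in ("accuracy", "recall", "auc")}

    def to_dict(self) -> dict:
        return {"per_split": {"accuracy": list(self.accuracy),
                              "recall": list(self.recall),
                              "auc": list(self.auc)},
                "mean": self.mean, "sd": self.sd}


def dataset_features(d: LabeledDataset,
                     feature_names: Sequence[str] = ("r1", "r2", "q"),
                     ) -> Tuple[np.ndarray, List[str], List[int]]:
    """Per-tooth feature matrix, labels and tooth ids from a labeled dataset.

    Uses the dataset's cached (r1, r2, q) features where available, falling
    back to provenance parameters; ``n`` is taken from provenance.
    """
    X, y, ids = [], [], []
    for t in d.tooth_ids:
        p = d.provenance[t]
        vals = {"r1": p.r1, "r2": p.r2, "q": p.q, "n": p.n}
        if d.features is not None and t in d.features and len(d.features[t]) == 3:
            vals["r1"], vals["r2"], vals["q"] = d.features[t]
        X.append([vals[f] for f in feature_names])
        y.append(d.label_of(t))
        ids.append(t)
    return np.asarray(X, dtype=float), y, ids


def split_dataset(d: LabeledDataset, train_frac: float = 0.7,
                  seed: int = 0) -> Tuple[List[int], List[int]]:
    """Stratified random train/test split at the tooth level.

    Splitting whole teeth (all replicates together) avoids leakage between
    train and test.  Returns (train tooth ids, test tooth ids), reproducible
    from ``seed``.
    """
    labels = d.labels()
    rng = np.random.default_rng(seed)
    train, test = [], []
    for lab in ("ND", "DM"):
        ids = sorted(t for t, l in labels.items() if l == lab)
        if len(ids) < 2:
            raise ValueError(f"need at least 2 teeth per class; class {lab} has {len(ids)}")
        perm = rng.permutation(len(ids))
        k = int(round(train_frac * len(ids)))
        k = min(max(k, 1), len(ids) - 1)
        train += [ids[i] for i in perm[:k]]
        test += [ids[i] for i in perm[k:]]
    if not train or not test:
        raise ValueError("split produced an empty partition")
    return sorted(train), sorted(test)


def fit_normalizer(X_train: np.ndarray) -> Normalizer:
    """Learn per-feature min/max from training rows only."""
    X = np.asarray(X_train, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("need at least two training rows")
    return Normalizer(mins=X.min(axis=0), maxs=X.max(axis=0))


def apply_normalizer(x: np.ndarray, nrm: Normalizer) -> np.ndarray:
    """(x - min) / (max - min), no clipping."""
    return (np.asarray(x, dtype=float) - nrm.mins) / (nrm.maxs - nrm.mins)


def train_mlp(X: np.ndarray, y: Sequence[str],
              cfg: Optional[MLPConfig] = None) -> TrainedMLP:
    """Fit the (features -> 3 -> 2 -> 1) network on raw (unnormalized) features.

    The min-max normalizer is fitted on the same rows and stored with the
    model.  Non-convergence sets ``converged=False`` but still returns the
    model.
    """
    cfg = cfg or MLPConfig()
    nrm = fit_normalizer(X)
    Xn = apply_normalizer(X, nrm)
    yb = np.array([{"ND": 0, "DM": 1}[l] for l in y])
    model = MLPClassifier(
        hidden_layer_sizes=cfg.hidden_layers, activation=cfg.activation,
        solver=cfg.solver, alpha=cfg.l2_penalty, max_iter=cfg.max_iter,
        random_state=cfg.seed,
    )
    import warnings
    from sklearn.exceptions import ConvergenceWarning
    converged = True
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always", ConvergenceWarning)
        model.fit(Xn, yb)
        converged = not any(issubclass(w.category, ConvergenceWarning) for w in caught)
    return TrainedMLP(model=model, normalizer=nrm, config=cfg, converged=converged)


def predict(m: TrainedMLP, x: np.ndarray) -> Tuple[np.ndarray, List[str]]:
    """Probability of DM and hard labels for feature rows ``x``.

    A probability of exactly 0.5 classifies as DM (screening-oriented tie
    rule, matching the single-neuron classifier).
    """
    x = np.atleast_2d(np.asarray(x, dtype=float))
    if x.shape[1] != len(m.config.features):
        raise ValueError(
            f"expected {len(m.config.features)} features {m.config.features}, got {x.shape[1]}")
    proba = m.model.predict_proba(apply_normalizer(x, m.normalizer))[:, 1]
    labels = ["DM" if p >= 0.5 else "ND" for p in proba]
    return proba, labels


def cross_validate(d: LabeledDataset, cfg: Optional[MLPConfig] = None,
                   k: int = 5, seed: int = 0) -> CVReport:
    """Stratified k-fold cross-validation at the tooth level."""
    cfg = cfg or MLPConfig()
    X, y, _ = dataset_features(d, cfg.features)
    y = np.asarray(y)
    for lab in ("ND", "DM"):
        if np.sum(y == lab) < k:
            raise ValueError(f"class {lab} has fewer than k={k} teeth")
    from sklearn.model_selection import StratifiedKFold
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    acc, rec, aucs = [], [], []
    for tr, te in skf.split(X, y):
        trained = train_mlp(X[tr], list(y[tr]), cfg)
        proba, labels = predict(trained, X[te])
        cm = confusion(list(y[te]), labels)
        rep = scores(cm)
        acc.append(rep.accuracy)
        rec.append(rep.recall)
        aucs.append(roc_auc(proba, list(y[te])).auc)
    return CVReport(accuracy=tuple(acc), recall=tuple(rec), auc=tuple(aucs))
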