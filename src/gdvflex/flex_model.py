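"""The linear GDV flexibility model: transforms, prediction, fitting, CV.

The model is ``RMSF_i = n + Σ_k β_k · O_{i,k}`` where the orbit counts
``O_{i,k}`` are log(1+x)-transformed and z-scored per protein, and the raw
reference RMSF is log-transformed and z-scored per protein.  Because both
sides are standardized within each protein, predictions live on a
dimensionless normalized-log scale and are evaluated by rank correlation;
no back-transform to Å is attempted (the per-protein scale is not
recoverable from coordinates alone).

Published coefficients (consensus across three training replicates of a
globular-protein MD dataset) are available through :func:`published_model`.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence, Union

import numpy as np
from scipy.stats import spearmanr

from .errors import DegenerateInputError, DomainError, ParameterError
from .gdv_core import N_ORBITS

_PUBLISHED_BETAS = (
    -1.91, -0.91, 2.98, 2.96, -0.92, -0.16, 0.12, -0.48,
    0.24, 0.31, 0.42, -0.78, 0.51, -1.73, -1.48,
)


@dataclass(frozen=True)
class ModelCoefficients:
    """Intercept plus the 15 per-orbit regression coefficients."""

    intercept: float
    betas: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.betas) != N_ORBITS:
            raise ParameterError(f"expected {N_ORBITS} betas, got {len(self.betas)}")
        if not np.all(np.isfinite(self.betas)) or not np.isfinite(self.intercept):
            raise ParameterError("coefficients must be finite")

    @property
    def beta_array(self) -> np.ndarray:
        return np.asarray(self.betas, dtype=float)


def published_model() -> ModelCoefficients:
    """The published consensus coefficients (intercept 0; standardized scales)."""
    return ModelCoefficients(intercept=0.0, betas=_PUBLISHED_BETAS)


@dataclass
class RMSFProfile:
    """Per-atom fluctuation values, raw (Å) or normalized (log-z, unitless)."""

    values: np.ndarray
    kind: str = "raw"  # "raw" | "normalized"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.kind not in ("raw", "normalized"):
            raise ParameterError(f"kind must be 'raw' or 'normalized', got {self.kind!r}")

    def __len__(self) -> int:
        return len(self.values)


def _zscore_columns(x: np.ndarray) -> np.ndarray:
    """Column z-scores with sample sd (ddof=1); zero-variance columns -> 0.

    A column of identical values can yield an sd of ~1e-16 instead of an
    exact zero, so degeneracy is judged relative to the column magnitude.
    """
    mean = x.mean(axis=0)
    sd = x.std(axis=0, ddof=1)
    out = np.zeros_like(x)
    ok = sd > 1e-12 * np.maximum(1.0, np.abs(mean))
    out[:, ok] = (x[:, ok] - mean[ok]) / sd[ok]
    return out


def transform_features(gdv: np.ndarray) -> np.ndarray:
    """log(1+count) then per-protein column z-score; N×15 in, N×15 out."""
    gdv = np.asarray(gdv)
    if gdv.ndim != 2 or gdv.shape[1] != N_ORBITS:
        raise ParameterError(f"expected N×{N_ORBITS} orbit counts, got {gdv.shape}")
    if gdv.shape[0] < 2:
        raise DegenerateInputError("need at least 2 atoms to standardize features")
    return _zscore_columns(np.log1p(gdv.astype(float)))


def transform_target(rmsf: Union[RMSFProfile, np.ndarray]) -> np.ndarray:
    """log then per-protein z-score of a raw RMSF profile (values must be > 0)."""
    values = np.asarray(getattr(rmsf, "values", rmsf), dtype=float)
    if np.any(~(values > 0)):
        raise DomainError("raw RMSF values must be strictly positive")
    return _zscore_columns(np.log(values)[:, None])[:, 0]


def predict(features: np.ndarray, model: ModelCoefficients) -> RMSFProfile:
    """Apply the linear model to a transformed feature matrix."""
    features = np.asarray(features, dtype=float)
    if features.ndim != 2 or features.shape[1] != N_ORBITS:
        raise ParameterError(f"expected N×{N_ORBITS} features, got {features.shape}")
    return RMSFProfile(
        model.intercept + features @ model.beta_array, kind="normalized"
    )


@dataclass
class TrainingProtein:
    """One protein's orbit counts, reference fluctuations and Cα mask."""

    protein_id: str
    gdv: np.ndarray
    reference: RMSFProfile
    ca_mask: np.ndarray

    def __post_init__(self) -> None:
        self.gdv = np.asarray(self.gdv)
        self.ca_mask = np.asarray(self.ca_mask, dtype=bool)
        if not (len(self.reference) == self.gdv.shape[0] == len(self.ca_mask)):
            raise ParameterError(f"row misalignment for protein {self.protein_id}")

    def target(self) -> np.ndarray:
        if self.reference.kind == "raw":
            return transform_target(self.reference)
        return self.reference.values


@dataclass
class TrainingSet:
    proteins: list[TrainingProtein] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.proteins)

    def __iter__(self):
        return iter(self.proteins)


def _pooled_design(proteins: Sequence[TrainingProtein]) -> tuple[np.ndarray, np.ndarray]:
    xs, ys = [], []
    for p in proteins:
        xs.append(transform_features(p.gdv))
        ys.append(p.target())
    return np.vstack(xs), np.concatenate(ys)


def fit(train: TrainingSet) -> ModelCoefficients:
    """Pooled OLS over per-protein standardized features and targets.

    A rank-deficient design is reported with a warning and solved by the
    minimum-norm least-squares solution.
    """
    if len(train) < 1:
        raise ParameterError("training set is empty")
    x, y = _pooled_design(train.proteins)
    if x.shape[0] < N_ORBITS + 1:
        raise DegenerateInputError(
            f"need at least {N_ORBITS + 1} pooled atoms, got {x.shape[0]}"
        )
    design = np.column_stack([np.ones(len(x)), x])
    coef, _, rank, _ = np.linalg.lstsq(design, y, rcond=None)
    if rank < design.shape[1]:
        warnings.warn(
            f"rank-deficient design (rank {rank} < {design.shape[1]}); "
            "returning the minimum-norm solution",
            stacklevel=2,
        )
    return ModelCoefficients(intercept=float(coef[0]), betas=tuple(coef[1:]))


@dataclass
class CVResult:
    protein_ids: list[str]
    rhos: np.ndarray
    folds: list[list[str]]

    @property
    def mean_rho(self) -> float:
        return float(np.nanmean(self.rhos))


def cross_validate(train: TrainingSet, k: int = 10, seed: int = 0) -> CVResult:
    """Grouped k-fold CV: folds partition proteins, never atoms within one.

    For each held-out protein the Spearman correlation between predicted and
    reference values is computed at Cα atoms (average ranks for ties).
    """
    n = len(train)
    if n < k:
        raise ParameterError(f"need at least k={k} proteins, got {n}")
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    folds = [list(order[i::k]) for i in range(k)]  # round-robin deal
    ids: list[str] = []
    rhos: list[float] = []
    for fold in folds:
        held = set(fold)
        model = fit(TrainingSet([train.proteins[i] for i in range(n) if i not in held]))
        for i in fold:
            p = train.proteins[i]
            pred = predict(transform_features(p.gdv), model)
            mask = p.ca_mask
            rho = spearmanr(pred.values[mask], p.target()[mask]).statistic
            ids.append(p.protein_id)
            rhos.append(float(rho))
    return CVResult(
        protein_ids=ids,
        rhos=np.asarray(rhos),
        folds=[[train.proteins[i].protein_id for i in f] for f in folds],
    )


# ---------------------------------------------------------------------------
# serialization

_TRANSFORM_SPEC = {"log_offset_features": 1, "log_offset_target": 0, "sd": "sample"}


def save_model(model: ModelCoefficients, path: Union[str, Path]) -> None:
    doc = {
        "intercept": model.intercept,
        "betas": list(model.betas),
        "orbit_order": "O0..O14",
        "transform": _TRANSFORM_SPEC,
    }
    Path(path).write_text(json.dumps(doc, indent=1) + "\n")


def load_model(path: Union[str, Path]) -> ModelCoefficients:
    doc = json.loads(Path(path).read_text())
    if doc.get("orbit_order") != "O0..O14":
        raise ParameterError(f"unsupported orbit order {doc.get('orbit_order')!r}")
    return ModelCoefficients(intercept=float(doc["intercept"]), betas=tuple(doc["betas"]))
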