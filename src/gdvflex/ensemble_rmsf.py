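"""Reference fluctuations from multi-model ensembles (NMR-style).

Models are superposed onto an iteratively refined mean structure by
least-squares rigid-body (Kabsch) fitting on a mask of atoms (Cα by
default), with the determinant constraint that forbids reflections.  The
per-atom RMSF is then the root-mean-square displacement from the atom's mean
position, and the representative conformer is the model closest to the mean
structure in Cα RMSD.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .errors import DegenerateInputError
from .structure_io import AtomTable, Ensemble


def kabsch_rotation(p: np.ndarray, q: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Optimal proper rotation R and centroids so that (p - cp) @ R ≈ q - cq."""
    cp = p.mean(axis=0)
    cq = q.mean(axis=0)
    h = (p - cp).T @ (q - cq)
    u, _, vt = np.linalg.svd(h)
    sign = np.sign(np.linalg.det(u @ vt))
    d = np.array([1.0, 1.0, sign])
    r = (u * d) @ vt
    return r, cp, cq


@dataclass
class AlignedEnsemble:
    """An ensemble after superposition, with its mean structure."""

    atoms: AtomTable  # roster/identity of every model
    coords: np.ndarray  # (n_models, N, 3) superposed coordinates
    mean_coords: np.ndarray  # (N, 3)
    rmsd_to_mean: np.ndarray  # per model, over the superposition mask
    mask: np.ndarray  # atoms used for superposition and RMSD

    @property
    def n_models(self) -> int:
        return self.coords.shape[0]


def superpose_ensemble(
    ens: Ensemble,
    mask: Optional[np.ndarray] = None,
    max_rounds: int = 10,
    tol: float = 1e-6,
) -> AlignedEnsemble:
    """Superpose every model onto an iteratively refined mean structure.

    ``mask`` selects the atoms used for the rigid fit (default: Cα).  The
    mean structure is recomputed after each round of fits until it moves by
    less than ``tol`` Å (RMS) or ``max_rounds`` is reached.
    """
    if len(ens) < 2:
        raise DegenerateInputError("need at least 2 models to superpose")
    atoms = ens.models[0]
    if mask is None:
        mask = atoms.ca_mask
    mask = np.asarray(mask, dtype=bool)
    if mask.sum() < 3:
        raise DegenerateInputError("superposition mask needs at least 3 atoms")
    coords = ens.coords.copy()
    # first reference: the first model (a plain average of unaligned copies
    # can be degenerate); each round refits all models and re-means
    mean = coords[0].copy()
    for _ in range(max_rounds):
        for m in range(coords.shape[0]):
            r, cp, cq = kabsch_rotation(coords[m][mask], mean[mask])
            coords[m] = (coords[m] - cp) @ r + cq
        new_mean = coords.mean(axis=0)
        shift = float(np.sqrt(((new_mean - mean) ** 2).sum(axis=1).mean()))
        mean = new_mean
        if shift < tol:
            break
    if max_rounds < 1:  # no refinement requested: score against the plain mean
        mean = coords.mean(axis=0)
    rmsd = np.sqrt(((coords[:, mask] - mean[mask]) ** 2).sum(axis=2).mean(axis=1))
    return AlignedEnsemble(
        atoms=atoms, coords=coords, mean_coords=mean, rmsd_to_mean=rmsd, mask=mask
    )


def rmsf_from_ensemble(aligned: AlignedEnsemble):
    """Per-atom RMSF: sqrt of mean squared displacement from the atom's mean."""
    from .flex_model import RMSFProfile

    if aligned.n_models < 2:
        raise DegenerateInputError("need at least 2 models for an RMSF")
    mean = aligned.coords.mean(axis=0)
    sq = ((aligned.coords - mean) ** 2).sum(axis=2).mean(axis=0)
    return RMSFProfile(np.sqrt(sq), kind="raw")


def representative_model(aligned: AlignedEnsemble) -> int:
    """Index of the model with minimum masked RMSD to the mean (ties -> lowest)."""
    return int(np.argmin(aligned.rmsd_to_mean))
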