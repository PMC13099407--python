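"""Scoring predictions against references and aggregating across proteins.

Evaluation is residue-level: Spearman rank correlation (average ranks for
ties) between predicted and reference values restricted to Cα atoms.  Rank
correlation makes the scores invariant to the per-protein normalization of
both profiles.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence, Union

import numpy as np
import pandas as pd
from scipy.stats import spearmanr

from .errors import DegenerateInputError, ParameterError
from .flex_model import RMSFProfile


@dataclass(frozen=True)
class ProteinScore:
    protein_id: str
    rho: float
    n_residues: int
    replicate: int = 0


def spearman_ca(
    pred: Union[RMSFProfile, np.ndarray],
    ref: Union[RMSFProfile, np.ndarray],
    ca_mask: np.ndarray,
) -> float:
    """Spearman rho over masked (Cα) positions; NaN if either side is constant."""
    p = np.asarray(getattr(pred, "values", pred), dtype=float)
    r = np.asarray(getattr(ref, "values", ref), dtype=float)
    mask = np.asarray(ca_mask, dtype=bool)
    if not (len(p) == len(r) == len(mask)):
        raise ParameterError("prediction, reference and mask lengths differ")
    p, r = p[mask], r[mask]
    if len(p) < 3:
        raise DegenerateInputError(f"need >= 3 masked atoms, got {len(p)}")
    if np.ptp(p) == 0 or np.ptp(r) == 0:
        warnings.warn("zero variance in a profile; Spearman undefined", stacklevel=2)
        return float("nan")
    return float(spearmanr(p, r).statistic)


@dataclass
class BestOfReplicates:
    per_protein: dict[str, float]
    mean: float
    median: float


def best_of_replicates(
    scores: Mapping[str, Sequence[float]],
) -> BestOfReplicates:
    """Per-protein maximum rho across replicates, with mean/median of maxima."""
    if not scores:
        raise ParameterError("no scores given")
    best = {}
    for pid, reps in scores.items():
        reps = [r for r in np.asarray(list(reps), dtype=float)]
        if not reps:
            raise ParameterError(f"protein {pid} has no replicate scores")
        best[pid] = float(np.nanmax(reps))
    values = np.array(list(best.values()))
    return BestOfReplicates(
        per_protein=best, mean=float(np.mean(values)), median=float(np.median(values))
    )


@dataclass
class ScoreSummary:
    mean: float
    median: float
    q1: float
    q3: float
    n: int
    n_nan_excluded: int
    negative_ids: list[str] = field(default_factory=list)


def summarize(scores: Sequence[ProteinScore]) -> ScoreSummary:
    """Descriptive statistics over per-protein scores, flagging rho < 0.

    NaN scores (undefined correlations) are excluded from the statistics and
    tallied separately.
    """
    if not scores:
        raise ParameterError("no scores to summarize")
    rhos = np.array([s.rho for s in scores], dtype=float)
    nan = np.isnan(rhos)
    ok = rhos[~nan]
    if len(ok) == 0:
        raise DegenerateInputError("all scores are NaN")
    return ScoreSummary(
        mean=float(np.mean(ok)),
        median=float(np.median(ok)),
        q1=float(np.quantile(ok, 0.25)),
        q3=float(np.quantile(ok, 0.75)),
        n=int(len(ok)),
        n_nan_excluded=int(nan.sum()),
        negative_ids=[s.protein_id for s in scores if not np.isnan(s.rho) and s.rho < 0],
    )


def scores_table(scores: Sequence[ProteinScore]) -> pd.DataFrame:
    """Per-protein report as a DataFrame (protein_id, rho, n_residues, replicate)."""
    return pd.DataFrame(
        [(s.protein_id, s.rho, s.n_residues, s.replicate) for s in scores],
        columns=["protein_id", "rho", "n_residues", "replicate"],
    )
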