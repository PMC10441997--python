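"""Null-model-corrected community cohesion.

Cohesion summarizes, per sample, how strongly the community's taxa covary:

    cohesion_pos(s) = sum_i rel(i, s) * connectedness_pos(i)
    cohesion_neg(s) = sum_i rel(i, s) * connectedness_neg(i)

where a taxon's connectedness is its mean positive (resp. negative)
*null-corrected* pairwise correlation with the other taxa.  The null
correction subtracts the mean correlation observed when every taxon's
abundance vector is independently permuted across samples (taxon-shuffle
null), removing the correlation floor induced by compositional and
abundance-distribution effects.  The per-sample ratio
|cohesion_neg| / cohesion_pos is the negative:positive cohesion ratio used
to compare communities.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "null_corrected_correlations",
    "connectedness",
    "cohesion_per_sample",
    "cohesion",
    "CohesionResult",
]


@dataclass
class CohesionResult:
    connectedness: pd.DataFrame   # taxa x {connectedness_pos, connectedness_neg}
    per_sample: pd.DataFrame      # samples x {cohesion_pos, cohesion_neg, ratio}
    null_iterations: int
    seed: int


def null_corrected_correlations(
    rel: pd.DataFrame, iterations: int = 200, seed: int = 0
) -> pd.DataFrame:
    """Observed Pearson correlations minus their taxon-shuffle null mean.

    Each null iteration permutes every taxon's abundance vector across
    samples independently and recomputes the full correlation matrix; the
    mean over iterations is subtracted from the observed matrix.
    Constant taxa get zero corrected correlation (logged).  Deterministic
    given ``seed``.
    """
    if rel.shape[1] < 4:
        raise ValueError("need at least 4 samples for correlation estimates")
    rng = np.random.default_rng(seed)
    x = rel.to_numpy(dtype=float)
    n_taxa, n_samples = x.shape
    constant = x.std(axis=1) == 0
    if constant.any():
        logger.info("cohesion: %d constant taxa set to zero connectedness", constant.sum())

    def corr(mat: np.ndarray) -> np.ndarray:
        with np.errstate(invalid="ignore", divide="ignore"):
            c = np.corrcoef(mat)
        return np.nan_to_num(c, nan=0.0)

    observed = corr(x)
    null_sum = np.zeros_like(observed)
    for _ in range(iterations):
        shuffled = np.empty_like(x)
        for i in range(n_taxa):
            shuffled[i] = x[i, rng.permutation(n_samples)]
        null_sum += corr(shuffled)
    corrected = observed - null_sum / iterations
    corrected[constant, :] = 0.0
    corrected[:, constant] = 0.0
    np.fill_diagonal(corrected, 0.0)
    return pd.DataFrame(corrected, index=rel.index, columns=rel.index)


def connectedness(corrected: pd.DataFrame) -> pd.DataFrame:
    """Mean strictly-positive and strictly-negative corrected correlation per taxon.

    Self-correlations are excluded (the diagonal is zero by construction).
    A taxon with no positive (negative) partners scores 0 on that side.
    """
    c = corrected.to_numpy(dtype=float).copy()
    np.fill_diagonal(c, 0.0)
    pos_mask = c > 0
    neg_mask = c < 0
    with np.errstate(invalid="ignore"):
        pos = np.where(
            pos_mask.any(axis=1),
            np.where(pos_mask, c, 0.0).sum(axis=1) / np.maximum(pos_mask.sum(axis=1), 1),
            0.0,
        )
        neg = np.where(
            neg_mask.any(axis=1),
            np.where(neg_mask, c, 0.0).sum(axis=1) / np.maximum(neg_mask.sum(axis=1), 1),
            0.0,
        )
    return pd.DataFrame(
        {"connectedness_pos": pos, "connectedness_neg": neg}, index=corrected.index
    )


def cohesion_per_sample(
    rel: pd.DataFrame,
    conn: pd.DataFrame,
    null_iterations: int = 200,
    seed: int = 0,
) -> CohesionResult:
    """Abundance-weighted cohesion per sample and the neg:pos ratio.

    Samples with zero positive cohesion get a missing ratio (warned).
    """
    conn = conn.reindex(rel.index)
    if conn.isna().any().any():
        raise ValueError("connectedness table does not cover every taxon")
    w = rel.to_numpy(dtype=float)
    pos = w.T @ conn["connectedness_pos"].to_numpy()
    neg = w.T @ conn["connectedness_neg"].to_numpy()
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(pos > 0, np.abs(neg) / np.where(pos > 0, pos, 1.0), np.nan)
    if np.isnan(ratio).any():
        logger.warning(
            "cohesion ratio undefined for %d sample(s) with zero positive cohesion",
            int(np.isnan(ratio).sum()),
        )
    per_sample = pd.DataFrame(
        {"cohesion_pos": pos, "cohesion_neg": neg, "ratio": ratio}, index=rel.columns
    )
    return CohesionResult(
        connectedness=conn, per_sample=per_sample,
        null_iterations=null_iterations, seed=seed,
    )


def cohesion(
    rel: pd.DataFrame, iterations: int = 200, seed: int = 0
) -> CohesionResult:
    """Convenience: full cohesion computation on one group's table."""
    corrected = null_corrected_correlations(rel, iterations=iterations, seed=seed)
    conn = connectedness(corrected)
    return cohesion_per_sample(rel, conn, null_iterations=iterations, seed=seed)
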