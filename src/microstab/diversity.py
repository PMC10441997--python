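"""Alpha diversity (Chao1), Bray-Curtis distances and classical PCoA."""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

__all__ = ["chao1", "chao1_per_sample", "bray_curtis", "pcoa", "Ordination"]


def chao1(sample_counts) -> float:
    """Bias-corrected Chao1 richness estimate for one sample.

    ``S_obs + F1*(F1-1) / (2*(F2+1))`` where F1 and F2 are the numbers of
    singleton and doubleton taxa.  The bias-corrected form is defined even
    when no doubletons are observed.
    """
    counts = np.asarray(sample_counts)
    if (counts < 0).any():
        raise ValueError("negative counts")
    if not (counts > 0).any():
        raise ValueError("Chao1 undefined for an all-zero sample")
    s_obs = int((counts > 0).sum())
    f1 = int((counts == 1).sum())
    f2 = int((counts == 2).sum())
    return s_obs + f1 * (f1 - 1) / (2.0 * (f2 + 1))


def chao1_per_sample(table: pd.DataFrame) -> pd.Series:
    """Chao1 for every sample column of a count table."""
    return pd.Series({s: chao1(table[s].to_numpy()) for s in table.columns}, name="chao1")


def bray_curtis(table: pd.DataFrame) -> pd.DataFrame:
    """Bray-Curtis dissimilarity between samples: sum|u-v| / sum(u+v).

    Note Bray-Curtis is not a metric (the triangle inequality can fail);
    values lie in [0, 1] for non-negative inputs.
    """
    if table.shape[1] < 2:
        raise ValueError("need at least 2 samples")
    x = table.to_numpy(dtype=float).T
    sums = x.sum(axis=1)
    if (sums == 0).sum() >= 2:
        raise ValueError("Bray-Curtis undefined between two all-zero samples")
    d = squareform(pdist(x, metric="braycurtis"))
    return pd.DataFrame(d, index=table.columns, columns=table.columns)


@dataclass
class Ordination:
    coordinates: pd.DataFrame      # samples x axes
    eigenvalues: np.ndarray        # all eigenvalues, descending (negatives kept)
    proportion_explained: np.ndarray  # over positive eigenvalues, per returned axis


def pcoa(distances: pd.DataFrame, k: int = 2) -> Ordination:
    """Classical scaling (principal coordinate analysis).

    Eigendecomposition of the Gower-centered ``-D**2 / 2`` matrix.  Negative
    eigenvalues (from non-Euclidean dissimilarities such as Bray-Curtis) are
    reported but excluded from the coordinates; if fewer than ``k`` positive
    eigenvalues exist the returned axes are truncated with a warning.
    """
    n = distances.shape[0]
    if k >= n:
        raise ValueError(f"k must be < n_samples ({n})")
    d = distances.to_numpy(dtype=float)
    b = -0.5 * d**2
    centerer = np.eye(n) - np.ones((n, n)) / n
    b = centerer @ b @ centerer
    eigvals, eigvecs = np.linalg.eigh((b + b.T) / 2.0)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]

    n_pos = int((eigvals > 1e-10).sum())
    k_eff = min(k, n_pos)
    if k_eff < k:
        warnings.warn(
            f"only {n_pos} positive eigenvalues; returning {k_eff} axes", stacklevel=2
        )
    coords = eigvecs[:, :k_eff] * np.sqrt(eigvals[:k_eff])
    total_pos = eigvals[:n_pos].sum() if n_pos else 1.0
    return Ordination(
        coordinates=pd.DataFrame(
            coords, index=distances.index,
            columns=[f"PCo{i + 1}" for i in range(k_eff)],
        ),
        eigenvalues=eigvals,
        proportion_explained=eigvals[:k_eff] / total_pos,
    )
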