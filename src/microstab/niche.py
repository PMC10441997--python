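"""Levins niche breadth and pairwise niche overlap.

The resource states are, by default, the samples of a group: a taxon's
"usage" is its abundance distribution across those samples, normalized to
sum to one.  Levins breadth is the inverse Simpson concentration of the
usage vector (1 = specialist on one state, n = perfectly even generalist),
and the Levins overlap of taxon i on taxon j is

    O_ij = sum_s p_is * p_js / sum_s p_is**2

whose symmetrized form (O_ij + O_ji) / 2 is bounded by 1 at identical
usage.  What constitutes a resource state is an ecological modeling choice;
any column partition can be passed in place of raw samples.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["levins_breadth", "levins_overlap", "niche_metrics", "NicheMetrics"]


def _normalize_usage(p) -> np.ndarray:
    p = np.asarray(p, dtype=float)
    total = p.sum()
    if total <= 0:
        raise ValueError("all-zero usage vector")
    return p / total


def levins_breadth(usage) -> float:
    """Levins niche breadth B = 1 / sum(p_s^2) of a usage distribution."""
    p = _normalize_usage(usage)
    return float(1.0 / (p**2).sum())


def levins_overlap(usage_i, usage_j, symmetrize: bool = True) -> float:
    """Levins overlap of two usage distributions.

    The asymmetric form O_ij = sum p_i p_j / sum p_i^2 measures how much of
    taxon i's niche is shared with j; the symmetrized mean of O_ij and O_ji
    (default) is 1 for identical vectors and 0 for disjoint supports.
    """
    pi = _normalize_usage(usage_i)
    pj = _normalize_usage(usage_j)
    cross = float((pi * pj).sum())
    o_ij = cross / float((pi**2).sum())
    if not symmetrize:
        return o_ij
    o_ji = cross / float((pj**2).sum())
    return 0.5 * (o_ij + o_ji)


@dataclass
class NicheMetrics:
    breadth: pd.Series        # per-taxon Levins B
    overlap: pd.DataFrame     # symmetrized pairwise overlap
    mean_overlap: float       # mean over distinct taxon pairs


def niche_metrics(table: pd.DataFrame) -> NicheMetrics:
    """Breadth and pairwise symmetrized overlap for one group's table.

    Taxa with zero total abundance in the group are excluded from both the
    breadth table and the overlap summary.
    """
    present = table.loc[table.sum(axis=1) > 0]
    if present.shape[0] < 2:
        raise ValueError("need at least 2 taxa with positive abundance")
    usage = present.div(present.sum(axis=1), axis=0).to_numpy(dtype=float)
    breadth = pd.Series(1.0 / (usage**2).sum(axis=1), index=present.index, name="levins_b")
    cross = usage @ usage.T
    self_sq = np.diag(cross).copy()
    asym = cross / self_sq[:, None]
    sym = 0.5 * (asym + asym.T)
    overlap = pd.DataFrame(sym, index=present.index, columns=present.index)
    iu = np.triu_indices(len(present), k=1)
    return NicheMetrics(
        breadth=breadth, overlap=overlap, mean_overlap=float(sym[iu].mean())
    )
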