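"""Phylogenetic conservation of perturbation responses.

Three stages:

* :func:`log2_fold_response` — a simple normalized log2-fold-ratio estimator
  of each ASV's response to a treatment (median-of-ratios size-factor
  normalization followed by a pseudocounted ratio of group means).  It is a
  deliberately plain substitute for a shrinkage-based differential-abundance
  fit; externally computed per-ASV log2-fold ratios are accepted anywhere a
  response table is consumed.
* :func:`consentrait` — the consenTRAIT statistic tau_D: the mean
  phylogenetic depth of maximal clades in which at least ``share_threshold``
  (90% by default) of the leaves carry a binary trait, with an upper-tail
  permutation test (conserved traits form deep clades, so large tau_D is
  evidence of conservation).  Positive singleton leaves are attributed to
  undersampling and contribute half their terminal branch length.
* :func:`mantel_correlogram` — distance-class-resolved Mantel permutation
  correlation between pairwise response-magnitude differences and
  phylogenetic (cophenetic) distances.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import dendropy
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "log2_fold_response",
    "cophenetic_distances",
    "consentrait",
    "consentrait_ensemble",
    "mantel_correlogram",
    "ConsenTraitResult",
    "MantelCorrelogram",
]


# ---------------------------------------------------------------------------
# per-ASV responses
# ---------------------------------------------------------------------------

def _size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors (geometric-mean reference).

    Only taxa with strictly positive counts in every sample enter the
    reference; if none exists, fall back to total-count scaling (warned).
    """
    allpos = counts.loc[(counts > 0).all(axis=1)]
    if allpos.empty:
        logger.warning(
            "no taxon observed in every sample; size factors fall back to totals"
        )
        totals = counts.sum(axis=0).astype(float)
        return totals / np.exp(np.log(totals).mean())
    logc = np.log(allpos.to_numpy(dtype=float))
    ref = logc.mean(axis=1)  # per-taxon geometric mean (log scale)
    sf = np.exp(np.median(logc - ref[:, None], axis=0))
    return pd.Series(sf, index=counts.columns)


def log2_fold_response(
    table: pd.DataFrame,
    metadata: pd.Series,
    reference_group: str,
    treatment_group: str,
    pseudocount: float = 0.5,
) -> pd.DataFrame:
    """Per-taxon log2-fold ratio of treatment vs reference group means.

    Counts are size-factor normalized (median-of-ratios), then
    ``ratio = log2((mean_treat + pseudocount) / (mean_ref + pseudocount))``.
    Returns a table with columns log2_fold_ratio, direction, magnitude.
    """
    ref_samples = metadata.index[metadata == reference_group]
    trt_samples = metadata.index[metadata == treatment_group]
    ref_samples = [s for s in ref_samples if s in table.columns]
    trt_samples = [s for s in trt_samples if s in table.columns]
    if len(ref_samples) < 3 or len(trt_samples) < 3:
        raise ValueError("both groups need at least 3 samples")
    sub = table[ref_samples + trt_samples]
    norm = sub / _size_factors(sub)
    mean_ref = norm[ref_samples].mean(axis=1)
    mean_trt = norm[trt_samples].mean(axis=1)
    ratio = np.log2((mean_trt + pseudocount) / (mean_ref + pseudocount))
    return pd.DataFrame(
        {
            "log2_fold_ratio": ratio,
            "direction": np.where(ratio > 0, "positive", "negative"),
            "magnitude": ratio.abs(),
        },
        index=table.index,
    )


# ---------------------------------------------------------------------------
# consenTRAIT
# ---------------------------------------------------------------------------

@dataclass
class ConsenTraitResult:
    tau_d: float
    clades: pd.DataFrame          # size, mean_depth, member leaves per clade
    null_tau: np.ndarray
    p_value: float
    n_permutations: int
    share_threshold: float


class _TraversalCache:
    """Preorder node table with per-node descendant leaves and depths."""

    def __init__(self, tree: dendropy.Tree, leaf_order: list[str]):
        idx = {label: i for i, label in enumerate(leaf_order)}
        self.children: list[list[int]] = []
        self.leaf_sets: list[np.ndarray] = []
        self.depths: list[np.ndarray] = []
        self.terminal_bl: list[float] = []
        node_id: dict = {}
        for node in tree.postorder_node_iter():
            nid = len(self.children)
            node_id[node] = nid
            if node.is_leaf():
                label = node.taxon.label
                if label not in idx:
                    raise ValueError(f"tree leaf {label!r} missing from trait table")
                self.children.append([])
                self.leaf_sets.append(np.array([idx[label]], dtype=int))
                self.depths.append(np.zeros(1))
                self.terminal_bl.append(float(node.edge.length or 0.0))
            else:
                kids = [node_id[c] for c in node.child_nodes()]
                leaves, depth = [], []
                for c in node.child_nodes():
                    cid = node_id[c]
                    bl = float(c.edge.length or 0.0)
                    leaves.append(self.leaf_sets[cid])
                    depth.append(self.depths[cid] + bl)
                self.children.append(kids)
                self.leaf_sets.append(np.concatenate(leaves))
                self.depths.append(np.concatenate(depth))
                self.terminal_bl.append(0.0)
        self.root = node_id[tree.seed_node]


def _tau_d(
    cache: _TraversalCache,
    positive: np.ndarray,
    share_threshold: float,
    include_singletons: bool,
    collect: bool = False,
):
    """tau_D for one binary trait vector; optionally collect clade records."""
    depths: list[float] = []
    records: list[dict] = []
    stack = [cache.root]
    while stack:
        nid = stack.pop()
        leaves = cache.leaf_sets[nid]
        if len(leaves) == 1:
            if positive[leaves[0]] and include_singletons:
                depths.append(0.5 * cache.terminal_bl[nid])
                if collect:
                    records.append(
                        {"size": 1, "mean_depth": 0.5 * cache.terminal_bl[nid],
                         "members": [int(leaves[0])]}
                    )
            continue
        mask = positive[leaves]
        n_pos = int(mask.sum())
        if n_pos and n_pos / len(leaves) >= share_threshold:
            mean_depth = float(cache.depths[nid][mask].mean())
            depths.append(mean_depth)
            if collect:
                records.append(
                    {"size": n_pos, "mean_depth": mean_depth,
                     "members": [int(v) for v in leaves[mask]]}
                )
        else:
            stack.extend(cache.children[nid])
    tau = float(np.mean(depths)) if depths else 0.0
    return (tau, records) if collect else tau


def consentrait(
    tree: dendropy.Tree,
    trait: pd.Series,
    share_threshold: float = 0.9,
    permutations: int = 1000,
    seed: int = 0,
    include_singletons: bool = True,
) -> ConsenTraitResult:
    """Mean phylogenetic depth of trait-conserved clades, with permutation p.

    ``trait`` is a binary (0/1) Series indexed by leaf label; its index must
    equal the tree's leaf set.  The traversal marks the outermost clades
    whose trait-positive fraction reaches ``share_threshold``; nested clades
    inside a qualifying one are not counted again.  The p-value is the
    upper-tail fraction of label permutations with null tau_D at least the
    observed value, with +1 smoothing.
    """
    leaf_labels = sorted(lf.taxon.label for lf in tree.leaf_node_iter())
    if sorted(trait.index) != leaf_labels:
        raise ValueError("trait table leaves do not match the tree's leaf set")
    order = list(trait.index)
    positive = trait.to_numpy().astype(bool)
    if not positive.any():
        raise ValueError("no trait-positive leaf")
    cache = _TraversalCache(tree, order)
    tau, records = _tau_d(cache, positive, share_threshold, include_singletons, collect=True)
    rng = np.random.default_rng(seed)
    null = np.empty(permutations)
    for b in range(permutations):
        null[b] = _tau_d(
            cache, positive[rng.permutation(len(positive))],
            share_threshold, include_singletons,
        )
    p = (1.0 + float((null >= tau).sum())) / (1.0 + permutations)
    clades = pd.DataFrame(
        [
            {"size": r["size"], "mean_depth": r["mean_depth"],
             "members": [order[i] for i in r["members"]]}
            for r in records
        ]
    )
    return ConsenTraitResult(tau, clades, null, p, permutations, share_threshold)


def consentrait_ensemble(
    trees: list[dendropy.Tree],
    trait: pd.Series,
    share_threshold: float = 0.9,
    permutations_per_tree: int = 10,
    seed: int = 0,
    include_singletons: bool = True,
) -> ConsenTraitResult:
    """consenTRAIT pooled over a tree ensemble (e.g. bootstrap trees).

    The observed tau_D is the mean of per-tree values; the permutation null
    pools ``permutations_per_tree`` trait randomizations from every tree.
    """
    if not trees:
        raise ValueError("empty tree collection")
    rng = np.random.default_rng(seed)
    order = list(trait.index)
    positive = trait.to_numpy().astype(bool)
    if not positive.any():
        raise ValueError("no trait-positive leaf")
    leaf_labels = sorted(order)
    taus, null_all, clades = [], [], None
    for tree in trees:
        if sorted(lf.taxon.label for lf in tree.leaf_node_iter()) != leaf_labels:
            raise ValueError("trees have mismatched leaf sets")
        cache = _TraversalCache(tree, order)
        tau, records = _tau_d(cache, positive, share_threshold, include_singletons, True)
        taus.append(tau)
        if clades is None:
            clades = pd.DataFrame(
                [
                    {"size": r["size"], "mean_depth": r["mean_depth"],
                     "members": [order[i] for i in r["members"]]}
                    for r in records
                ]
            )
        for _ in range(permutations_per_tree):
            null_all.append(
                _tau_d(cache, positive[rng.permutation(len(positive))],
                       share_threshold, include_singletons)
            )
    tau_mean = float(np.mean(taus))
    null = np.asarray(null_all)
    p = (1.0 + float((null >= tau_mean).sum())) / (1.0 + len(null))
    return ConsenTraitResult(tau_mean, clades, null, p, len(null), share_threshold)


# ---------------------------------------------------------------------------
# Mantel correlogram
# ---------------------------------------------------------------------------

def cophenetic_distances(tree: dendropy.Tree) -> pd.DataFrame:
    """Leaf-pair patristic distance matrix from a tree with branch lengths."""
    pdm = tree.phylogenetic_distance_matrix()
    leaves = sorted(tree.taxon_namespace, key=lambda t: t.label)
    labels = [t.label for t in leaves]
    n = len(labels)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = pdm.patristic_distance(leaves[i], leaves[j])
    return pd.DataFrame(d, index=labels, columns=labels)


@dataclass
class MantelCorrelogram:
    classes: pd.DataFrame  # class_lo, class_hi, n_pairs, r, p_raw, p_adj
    n_permutations: int


def mantel_correlogram(
    phylo_dist: pd.DataFrame,
    response_diff: pd.DataFrame,
    n_classes: int | None = None,
    permutations: int = 999,
    seed: int = 0,
) -> MantelCorrelogram:
    """Mantel correlation per phylogenetic distance class.

    For each class the statistic is the Pearson correlation between the
    pairwise response-magnitude differences and the class-membership
    indicator over all leaf pairs; a negative value in the shortest class
    means closely related leaves respond most similarly.  Significance is a
    two-sided leaf-label permutation test; p-values receive the progressive
    (Holm-style) correction across classes in increasing-distance order.
    Class count defaults to Sturges' rule on the number of pairs.
    """
    if list(phylo_dist.index) != list(response_diff.index):
        raise ValueError("matrices must share the same leaf order")
    n = phylo_dist.shape[0]
    if n < 10:
        raise ValueError("need at least 10 leaves")
    d = phylo_dist.to_numpy(dtype=float)
    r_mat = response_diff.to_numpy(dtype=float)
    for name, mat in (("phylo_dist", d), ("response_diff", r_mat)):
        if not np.allclose(mat, mat.T):
            raise ValueError(f"{name} is not symmetric")
    iu = np.triu_indices(n, k=1)
    dvec = d[iu]
    rvec = r_mat[iu]
    if rvec.std() == 0:
        raise ValueError("constant response differences: statistic undefined")
    if n_classes is None:
        n_classes = int(np.ceil(np.log2(len(dvec))) + 1)
    edges = np.linspace(dvec.min(), dvec.max(), n_classes + 1)
    edges[-1] = np.nextafter(edges[-1], np.inf)
    which = np.digitize(dvec, edges) - 1

    rng = np.random.default_rng(seed)
    mean_r, sd_r = rvec.mean(), rvec.std()
    n_pairs = len(dvec)

    def class_stats(vec: np.ndarray) -> np.ndarray:
        out = np.full(n_classes, np.nan)
        for k in range(n_classes):
            mask = which == k
            nk = int(mask.sum())
            if nk == 0 or nk == n_pairs:
                continue
            mean_w = nk / n_pairs
            sd_w = np.sqrt(mean_w * (1 - mean_w))
            out[k] = (vec[mask].mean() * mean_w - mean_w * mean_r) / (sd_w * sd_r)
        return out

    obs = class_stats(rvec)
    exceed = np.zeros(n_classes)
    valid = ~np.isnan(obs)
    for _ in range(permutations):
        perm = rng.permutation(n)
        pvec = r_mat[np.ix_(perm, perm)][iu]
        stat = class_stats(pvec)
        exceed[valid] += (np.abs(stat[valid]) >= np.abs(obs[valid])).astype(float)
    p_raw = np.where(valid, (1.0 + exceed) / (1.0 + permutations), np.nan)
    # progressive correction in increasing-distance order
    p_adj = np.full(n_classes, np.nan)
    rank = 0
    for k in range(n_classes):
        if valid[k]:
            rank += 1
            p_adj[k] = min(1.0, p_raw[k] * rank)
    classes = pd.DataFrame(
        {
            "class_lo": edges[:-1],
            "class_hi": np.minimum(edges[1:], dvec.max()),
            "n_pairs": [int((which == k).sum()) for k in range(n_classes)],
            "r": obs,
            "p_raw": p_raw,
            "p_adj": p_adj,
        }
    )
    return MantelCorrelogram(classes=classes, n_permutations=permutations)
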