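"""Co-occurrence network construction and topology.

Edges are Spearman correlations between taxa across a group's samples that
pass both a magnitude threshold (|rho| > 0.6 by default, sign retained as
the edge weight) and a Benjamini-Hochberg FDR threshold (q < 0.01).  Node
abundance attributes carry each taxon's mean relative abundance, which the
stability stage uses as b_j in the abundance-weighted mean interaction
strength.  Topology metrics (topological coefficient, neighborhood
connectivity, clustering) and modularity are computed on the unweighted,
sign-blind skeleton.
"""

from __future__ import annotations

import logging

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

__all__ = [
    "pairwise_spearman",
    "prevalence_filter",
    "build_network",
    "build_group_network",
    "topology_metrics",
    "detect_modules",
    "module_hubs",
]


def prevalence_filter(table: pd.DataFrame, prevalence_min: float = 0.2) -> pd.DataFrame:
    """Drop taxa present (count > 0) in fewer than ``prevalence_min`` of samples."""
    prevalence = (table > 0).mean(axis=1)
    kept = table.loc[prevalence >= prevalence_min]
    if kept.shape[0] < table.shape[0]:
        logger.info(
            "prevalence filter: %d of %d taxa retained",
            kept.shape[0], table.shape[0],
        )
    return kept


def pairwise_spearman(rel: pd.DataFrame) -> pd.DataFrame:
    """All-pairs Spearman correlations with BH-adjusted p-values.

    ``rel`` is a taxa x samples relative-abundance (or count) table; ties
    get average ranks and p-values come from the t approximation of the
    rank correlation.  Constant taxa are skipped (logged).  Returns a long
    table with columns taxon_a, taxon_b, rho, p_raw, q_fdr.
    """
    n_samples = rel.shape[1]
    if n_samples < 4:
        logger.warning("only %d samples; correlation p-values are unreliable", n_samples)
    variable = rel.std(axis=1) > 0
    skipped = rel.index[~variable]
    if len(skipped):
        logger.info("skipping %d constant taxa: %s", len(skipped), list(skipped)[:5])
    sub = rel.loc[variable]
    if sub.shape[0] < 2:
        raise ValueError("fewer than 2 variable taxa; nothing to correlate")
    rho, p = stats.spearmanr(sub.to_numpy().T)
    if sub.shape[0] == 2:  # scipy returns scalars for a single pair
        rho = np.array([[1.0, rho], [rho, 1.0]])
        p = np.array([[0.0, p], [p, 0.0]])
    taxa = list(sub.index)
    ii, jj = np.triu_indices(len(taxa), k=1)
    out = pd.DataFrame(
        {
            "taxon_a": [taxa[i] for i in ii],
            "taxon_b": [taxa[j] for j in jj],
            "rho": rho[ii, jj],
            "p_raw": p[ii, jj],
        }
    )
    out["q_fdr"] = multipletests(out["p_raw"].to_numpy(), method="fdr_bh")[1]
    return out


def build_network(
    correlations: pd.DataFrame,
    rel: pd.DataFrame,
    rho_threshold: float = 0.6,
    q_threshold: float = 0.01,
) -> nx.Graph:
    """Assemble the signed co-occurrence graph from a correlation table.

    An edge exists iff |rho| > rho_threshold and q < q_threshold; its
    ``weight`` is the signed correlation.  Nodes carry ``abundance`` = mean
    relative abundance over the group's samples.  Taxa with no passing edge
    are excluded.  An empty edge set is an error (relax the thresholds).
    """
    if not (0 < rho_threshold <= 1 and 0 < q_threshold <= 1):
        raise ValueError("thresholds must lie in (0, 1]")
    passing = correlations[
        (correlations["rho"].abs() > rho_threshold)
        & (correlations["q_fdr"] < q_threshold)
    ]
    if passing.empty:
        raise ValueError(
            "no correlation passes the thresholds; consider relaxing "
            f"rho_threshold={rho_threshold} / q_threshold={q_threshold}"
        )
    mean_ab = rel.mean(axis=1)
    g = nx.Graph()
    nodes = sorted(set(passing["taxon_a"]) | set(passing["taxon_b"]))
    for t in nodes:
        g.add_node(t, abundance=float(mean_ab.get(t, 0.0)))
    for row in passing.itertuples(index=False):
        g.add_edge(row.taxon_a, row.taxon_b, weight=float(row.rho), q=float(row.q_fdr))
    return g


def build_group_network(
    table: pd.DataFrame,
    rho_threshold: float = 0.6,
    q_threshold: float = 0.01,
    prevalence_min: float = 0.2,
) -> nx.Graph:
    """Prevalence-filter, normalize, correlate and threshold in one call.

    ``table`` holds one group's counts (taxa x samples).
    """
    from .core_io import to_relative_abundance

    filtered = prevalence_filter(table, prevalence_min)
    rel = to_relative_abundance(filtered)
    corr = pairwise_spearman(rel)
    return build_network(corr, rel, rho_threshold, q_threshold)


def topology_metrics(net: nx.Graph) -> pd.DataFrame:
    """Per-node topological coefficient, neighborhood connectivity, clustering.

    The topological coefficient of a node n with degree >= 2 is the mean of
    J(n, m) / k_n over every other node m sharing at least one neighbor
    with n, where J counts shared neighbors plus one if n and m are
    adjacent; nodes of degree < 2 score 0.  Neighborhood connectivity is
    the mean degree of a node's neighbors.  All three are computed on the
    unweighted skeleton.
    """
    if net.number_of_nodes() == 0:
        raise ValueError("empty network")
    skeleton = nx.Graph(net.edges())
    skeleton.add_nodes_from(net.nodes())
    clustering = nx.clustering(skeleton)
    degree = dict(skeleton.degree())
    rows = {}
    for n in skeleton.nodes():
        neigh = set(skeleton[n])
        k = degree[n]
        nc = float(np.mean([degree[v] for v in neigh])) if neigh else 0.0
        if k < 2:
            tc = 0.0
        else:
            shares = {}
            for v in neigh:
                for m in skeleton[v]:
                    if m != n:
                        shares[m] = shares.get(m, 0) + 1
            if shares:
                vals = [
                    (j + (1 if skeleton.has_edge(n, m) else 0)) / k
                    for m, j in shares.items()
                ]
                tc = float(np.mean(vals))
            else:
                tc = 0.0
        rows[n] = {
            "topological_coefficient": tc,
            "neighborhood_connectivity": nc,
            "clustering_coefficient": clustering[n],
        }
    df = pd.DataFrame.from_dict(rows, orient="index").sort_index()
    df.attrs["network_means"] = df.mean().to_dict()
    return df


def detect_modules(
    net: nx.Graph, seed: int = 0, method: str = "cnm"
) -> tuple[dict, float]:
    """Partition the network into modules and report Newman modularity Q.

    Greedy Clauset-Newman-Moore agglomeration on the sign-blind skeleton
    with |weight| as the edge weight (default); ``method="louvain"`` uses
    seeded Louvain instead.  Nodes are processed in lexicographic order so
    the result is deterministic.  Module ids are assigned to the node
    attribute ``module``.
    """
    skeleton = nx.Graph()
    skeleton.add_nodes_from(sorted(net.nodes()))
    for u, v, data in sorted(net.edges(data=True)):
        skeleton.add_edge(u, v, weight=abs(data.get("weight", 1.0)))
    if method == "cnm":
        communities = nx.community.greedy_modularity_communities(skeleton, weight="weight")
    elif method == "louvain":
        communities = nx.community.louvain_communities(skeleton, weight="weight", seed=seed)
    else:
        raise ValueError(f"unknown module detection method {method!r}")
    communities = sorted((sorted(c) for c in communities), key=lambda c: (-len(c), c))
    assignment = {}
    for mid, members in enumerate(communities):
        for node in members:
            assignment[node] = mid
    q = nx.community.modularity(skeleton, [set(c) for c in communities], weight="weight")
    nx.set_node_attributes(net, assignment, "module")
    return assignment, float(q)


def module_hubs(net: nx.Graph, top_n: int = 5) -> pd.DataFrame:
    """Rank nodes by within-module degree z-score (Guimera-Amaral).

    z_i = (k_within(i) - mean_within(module)) / sd_within(module); modules
    of size 1 or with zero spread give z = 0.  The top ``top_n`` nodes are
    flagged as module hubs.
    """
    modules = nx.get_node_attributes(net, "module")
    if len(modules) != net.number_of_nodes():
        raise ValueError("run detect_modules first: nodes lack module assignments")
    within = {
        n: sum(1 for v in net[n] if modules[v] == modules[n]) for n in net.nodes()
    }
    df = pd.DataFrame(
        {"module": pd.Series(modules), "within_degree": pd.Series(within)}
    )
    z = np.zeros(len(df))
    for _, idx in df.groupby("module").groups.items():
        k = df.loc[idx, "within_degree"].to_numpy(dtype=float)
        sd = k.std(ddof=0)
        if len(k) > 1 and sd > 0:
            z[df.index.get_indexer(idx)] = (k - k.mean()) / sd
        # else: z stays 0 (degenerate module, logged)
    df["z_within"] = z
    df = df.sort_values(["z_within", "within_degree"], ascending=False, kind="stable")
    df["is_hub"] = False
    df.iloc[: min(top_n, len(df)), df.columns.get_loc("is_hub")] = True
    return df
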