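"""Network robustness (wMIS extinction cascades) and vulnerability.

Robustness removes a set of nodes from the co-occurrence network and lets
secondary extinctions cascade: after each round, every live node whose
abundance-weighted mean interaction strength

    wMIS_i = sum_{j != i, live} b_j * s_ij / sum_{j != i, live} b_j

is zero or negative is removed (s_ij is the signed edge weight, zero for
non-adjacent pairs; b_j the node's relative abundance).  All non-positive
nodes in a round are removed simultaneously, so the fixed point does not
depend on processing order.  Robustness is the surviving fraction of the
original nodes.  Vulnerability measures the largest relative drop of global
efficiency (mean inverse shortest-path length on the unweighted sign-blind
skeleton) caused by deleting any single node.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "wmis",
    "extinction_cascade",
    "robustness",
    "vulnerability",
    "RobustnessResult",
    "VulnerabilityResult",
]


@dataclass
class RobustnessResult:
    removal_strategy: str
    removal_fraction: float | None
    hub_count: int | None
    repetitions: int
    proportions: np.ndarray  # surviving-node proportion per repetition
    seed: int | None

    @property
    def mean(self) -> float:
        return float(self.proportions.mean())

    @property
    def sd(self) -> float:
        return float(self.proportions.std(ddof=1)) if len(self.proportions) > 1 else 0.0


@dataclass
class VulnerabilityResult:
    global_efficiency: float
    node_vulnerability: pd.Series  # V_i = (E - E_-i) / E

    @property
    def network_vulnerability(self) -> float:
        return float(self.node_vulnerability.max())


def _arrays(net: nx.Graph):
    nodes = sorted(net.nodes())
    index = {n: i for i, n in enumerate(nodes)}
    n = len(nodes)
    b = np.array([net.nodes[v].get("abundance", 1.0) for v in nodes], dtype=float)
    s = np.zeros((n, n))
    for u, v, data in net.edges(data=True):
        w = data.get("weight", 1.0)
        s[index[u], index[v]] = w
        s[index[v], index[u]] = w
    return nodes, b, s


def wmis(i, net: nx.Graph, live=None) -> float:
    """Abundance-weighted mean interaction strength of node ``i``.

    ``live`` restricts the community to a subset of nodes (default: all).
    With no other live node the convention is wMIS = 0, which the cascade
    rule treats as extinct/isolated.
    """
    nodes, b, s = _arrays(net)
    index = {n: k for k, n in enumerate(nodes)}
    mask = np.zeros(len(nodes), dtype=bool)
    mask[[index[v] for v in (live if live is not None else nodes)]] = True
    k = index[i]
    if not mask[k]:
        raise ValueError(f"node {i!r} is not live")
    mask[k] = False
    denom = b[mask].sum()
    if denom <= 0:
        return 0.0
    return float(s[k, mask] @ b[mask] / denom)


def _cascade_mask(b: np.ndarray, s: np.ndarray, alive: np.ndarray) -> np.ndarray:
    """Run the synchronous extinction cascade on boolean state ``alive``."""
    alive = alive.copy()
    while True:
        idx = np.flatnonzero(alive)
        if idx.size == 0:
            break
        bsub = b[idx]
        denom = bsub.sum() - bsub  # sum over other live nodes, per node
        numer = s[np.ix_(idx, idx)] @ bsub  # diagonal of s is zero
        with np.errstate(divide="ignore", invalid="ignore"):
            w = np.where(denom > 0, numer / np.where(denom > 0, denom, 1.0), 0.0)
        dead = w <= 0
        if not dead.any():
            break
        alive[idx[dead]] = False
    return alive


def extinction_cascade(net: nx.Graph, removed) -> set:
    """Surviving node set after removing ``removed`` and cascading extinctions.

    Every survivor has strictly positive wMIS over the surviving community;
    the result is a fixed point (re-running the cascade removes nothing).
    """
    nodes, b, s = _arrays(net)
    index = {n: k for k, n in enumerate(nodes)}
    alive = np.ones(len(nodes), dtype=bool)
    for r in removed:
        alive[index[r]] = False
    alive = _cascade_mask(b, s, alive)
    return {nodes[k] for k in np.flatnonzero(alive)}


def robustness(
    net: nx.Graph,
    strategy: str = "random",
    fraction: float = 0.5,
    hub_count: int = 5,
    repetitions: int = 100,
    seed: int = 0,
) -> RobustnessResult:
    """Surviving-node proportion under node removal plus extinction cascade.

    ``strategy="random"`` removes ``floor(fraction * n)`` uniformly chosen
    nodes in each of ``repetitions`` repetitions; ``strategy="module_hubs"``
    deterministically removes the top ``hub_count`` within-module-degree
    hubs once (requires module assignments).
    """
    if net.number_of_nodes() == 0:
        raise ValueError("empty network")
    nodes, b, s = _arrays(net)
    n = len(nodes)
    if strategy == "random":
        if not 0 <= fraction < 1:
            raise ValueError("removal fraction must be in [0, 1)")
        rng = np.random.default_rng(seed)
        n_remove = int(np.floor(fraction * n))
        props = np.empty(repetitions)
        for r in range(repetitions):
            alive = np.ones(n, dtype=bool)
            alive[rng.choice(n, size=n_remove, replace=False)] = False
            props[r] = _cascade_mask(b, s, alive).sum() / n
        return RobustnessResult("random", fraction, None, repetitions, props, seed)
    elif strategy == "module_hubs":
        from .network import module_hubs

        hubs = module_hubs(net, top_n=hub_count)
        remove = list(hubs.index[hubs["is_hub"]])
        survivors = extinction_cascade(net, remove)
        props = np.array([len(survivors) / n])
        return RobustnessResult("module_hubs", None, hub_count, 1, props, None)
    raise ValueError(f"unknown removal strategy {strategy!r}")


def _global_efficiency(g: nx.Graph) -> float:
    """Mean inverse hop distance over ordered node pairs (0 if disconnected)."""
    n = g.number_of_nodes()
    if n < 2:
        return 0.0
    total = 0.0
    for _, lengths in nx.all_pairs_shortest_path_length(g):
        total += sum(1.0 / d for d in lengths.values() if d > 0)
    return total / (n * (n - 1))


def vulnerability(net: nx.Graph) -> VulnerabilityResult:
    """Relative efficiency loss from single-node deletions.

    V_i = (E - E_-i) / E where E is global efficiency and E_-i the
    efficiency of the network without node i (over the remaining nodes'
    pairs).  The network's vulnerability is max_i V_i.
    """
    if net.number_of_nodes() < 3:
        raise ValueError("vulnerability needs at least 3 nodes")
    skeleton = nx.Graph(net.edges())
    skeleton.add_nodes_from(net.nodes())
    e = _global_efficiency(skeleton)
    if e == 0:
        raise ValueError("edgeless network: global efficiency is zero")
    vuln = {}
    for v in skeleton.nodes():
        sub = skeleton.copy()
        sub.remove_node(v)
        vuln[v] = (e - _global_efficiency(sub)) / e
    series = pd.Series(vuln).sort_index()
    return VulnerabilityResult(global_efficiency=e, node_vulnerability=series)
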