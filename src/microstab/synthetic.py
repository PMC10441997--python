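"""Synthetic community, neutral-assembly and trait/tree generators.

These generators produce inputs with the statistical structure the analysis
stages assume, so the whole pipeline can be exercised and validated without
sequencing data:

* :func:`simulate_correlated_community` — compositional count tables whose
  taxa carry a block (module) correlation structure, built from a Gaussian
  copula with a one-factor-per-block latent model and lognormal abundance
  marginals, then multinomial read sampling at a fixed depth.
* :func:`simulate_neutral_assembly` — local communities evolved under
  Hubbell-style zero-sum death/replacement dynamics with immigration from a
  fixed metacommunity at rate ``m``; the generative counterpart of the Sloan
  neutral community model.
* :func:`simulate_tree_and_traits` — Yule trees with either phylogenetically
  random or clade-conserved binary traits, plus a continuous response evolved
  by Brownian motion along branches.

All generators are bit-reproducible under a fixed seed.
"""

from __future__ import annotations

import logging
import random as _pyrandom
from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "CommunityScenario",
    "NeutralScenario",
    "TraitScenario",
    "simulate_correlated_community",
    "simulate_neutral_assembly",
    "simulate_tree_and_traits",
    "block_assignments",
    "balanced_scenario",
    "unbalanced_scenario",
]


@dataclass
class CommunityScenario:
    """Parameters of the block-correlated compositional community generator.

    ``module_blocks`` is a list of ``(size, within_block_correlation)``
    pairs; taxa beyond the blocks' total are independent background taxa.
    ``cross_block_correlation`` is the common correlation of the block
    latent factors.  ``positive_fraction`` is the fraction of block taxa
    loading positively on their block factor; the complementary taxa load
    negatively (deterministically, the first taxa of each block), giving
    strong negative pairwise correlations inside the block.
    ``abundance_sigma`` is the lognormal spread of mean abundances across
    taxa (larger = fewer effective taxa); ``fluctuation_sigma`` is the
    within-taxon lognormal fluctuation across samples.
    """

    n_taxa: int = 60
    n_samples: int = 50
    depth: int = 20000
    module_blocks: list[tuple[int, float]] = field(default_factory=lambda: [(10, 0.8)] * 6)
    cross_block_correlation: float = 0.0
    positive_fraction: float = 1.0
    negative_loading: float | None = None
    abundance_sigma: float = 1.0
    fluctuation_sigma: float = 1.0
    rank_abundance_by_block: bool = False
    seed: int = 0

    def validate(self) -> None:
        sizes = sum(s for s, _ in self.module_blocks)
        if sizes > self.n_taxa:
            raise ValueError("module blocks exceed n_taxa")
        for s, r in self.module_blocks:
            if not -1.0 <= r <= 1.0:
                raise ValueError(f"within-block correlation {r} outside [-1, 1]")
        if not -1.0 <= self.cross_block_correlation <= 1.0:
            raise ValueError("cross_block_correlation outside [-1, 1]")
        if not 0.0 <= self.positive_fraction <= 1.0:
            raise ValueError("positive_fraction outside [0, 1]")
        if self.depth < 1 or self.n_samples < 2 or self.n_taxa < 2:
            raise ValueError("degenerate scenario dimensions")


def block_assignments(scenario: CommunityScenario) -> pd.Series:
    """Block label per taxon ('B0', 'B1', ..., 'none' for background taxa)."""
    labels = []
    for b, (size, _) in enumerate(scenario.module_blocks):
        labels += [f"B{b}"] * size
    labels += ["none"] * (scenario.n_taxa - len(labels))
    return pd.Series(labels, index=_taxon_ids(scenario.n_taxa))


def _taxon_ids(n: int) -> list[str]:
    return [f"T{i:04d}" for i in range(n)]


def _sample_ids(n: int) -> list[str]:
    return [f"S{i:04d}" for i in range(n)]


def _factor_correlation(k: int, rho: float) -> np.ndarray:
    """Equicorrelated factor matrix, PSD-repaired by eigenvalue clipping.

    A change of any entry by more than 0.1 during repair makes the scenario
    infeasible and raises.
    """
    corr = np.full((k, k), rho, dtype=float)
    np.fill_diagonal(corr, 1.0)
    w, v = np.linalg.eigh(corr)
    if w.min() < -1e-12:
        logger.warning("factor correlation matrix not PSD; clipping eigenvalues")
        w = np.clip(w, 0.0, None)
        fixed = (v * w) @ v.T
        d = np.sqrt(np.diag(fixed))
        fixed = fixed / np.outer(d, d)
        if np.abs(fixed - corr).max() > 0.1:
            raise ValueError(
                "PSD repair changed a factor correlation by more than 0.1; "
                "scenario infeasible"
            )
        corr = fixed
    return corr


def simulate_correlated_community(scenario: CommunityScenario) -> pd.DataFrame:
    """Generate a taxa x samples count table under the scenario.

    Per sample: (1) draw block factors from the (repaired) factor
    correlation matrix and build each taxon's latent Gaussian as
    ``sign * sqrt(r) * factor + sqrt(1-r) * noise``; (2) map monotonically to
    lognormal abundances ``base_i * exp(fluctuation_sigma * z)``; (3) draw
    reads by multinomial sampling at ``depth``.
    """
    scenario.validate()
    rng = np.random.default_rng(scenario.seed)
    n, s = scenario.n_taxa, scenario.n_samples
    k = len(scenario.module_blocks)

    # per-taxon factor index (-1 = background), loading sign and strength
    factor_idx = np.full(n, -1, dtype=int)
    sign = np.ones(n)
    strength = np.zeros(n)
    pos = 0
    neg_r = scenario.negative_loading
    for b, (size, r) in enumerate(scenario.module_blocks):
        n_neg = int(round((1.0 - scenario.positive_fraction) * size))
        for i in range(size):
            factor_idx[pos + i] = b
            if i < n_neg:
                sign[pos + i] = -1.0
                r_i = r if neg_r is None else neg_r
            else:
                r_i = r
            strength[pos + i] = np.sqrt(abs(r_i)) * np.sign(r_i)
        pos += size

    if k:
        fcorr = _factor_correlation(k, scenario.cross_block_correlation)
        chol = np.linalg.cholesky(fcorr + 1e-12 * np.eye(k))
        factors = rng.standard_normal((s, k)) @ chol.T
    else:
        factors = np.zeros((s, 0))
    noise = rng.standard_normal((s, n))

    z = np.empty((s, n))
    for i in range(n):
        if factor_idx[i] >= 0:
            lam = sign[i] * strength[i]
            z[:, i] = lam * factors[:, factor_idx[i]] + np.sqrt(1 - lam**2) * noise[:, i]
        else:
            z[:, i] = noise[:, i]

    base = np.exp(scenario.abundance_sigma * rng.standard_normal(n))
    if scenario.rank_abundance_by_block:
        # dominant guild: earlier blocks receive the larger mean abundances
        base = np.sort(base)[::-1]
    abundance = base[None, :] * np.exp(scenario.fluctuation_sigma * z)
    probs = abundance / abundance.sum(axis=1, keepdims=True)

    counts = np.empty((n, s), dtype=np.int64)
    for j in range(s):
        counts[:, j] = rng.multinomial(scenario.depth, probs[j])
    return pd.DataFrame(counts, index=_taxon_ids(n), columns=_sample_ids(s))


@dataclass
class NeutralScenario:
    """Parameters of the Hubbell neutral local-community simulator.

    Each of ``n_samples`` local communities of ``local_size`` individuals is
    evolved independently: at every step one individual dies uniformly and is
    replaced by an immigrant from the metacommunity with probability
    ``migration``, otherwise by the offspring of another local individual.
    ``burn_in`` is measured in generations (one generation = ``local_size``
    death/replacement events).  If ``metacommunity_abundances`` is None, a
    lognormal metacommunity with spread ``metacommunity_sigma`` is drawn.
    """

    metacommunity_taxa: int = 500
    local_size: int = 1000
    migration: float = 0.2
    burn_in: int = 50
    n_samples: int = 50
    metacommunity_abundances: np.ndarray | None = None
    metacommunity_sigma: float = 2.0
    seed: int = 0

    def validate(self) -> None:
        if not 0.0 < self.migration < 1.0:
            raise ValueError("migration must be in (0, 1)")
        if self.local_size < 10:
            raise ValueError("local_size must be >= 10")
        if self.n_samples < 1 or self.metacommunity_taxa < 2:
            raise ValueError("degenerate scenario dimensions")


def simulate_neutral_assembly(scenario: NeutralScenario) -> pd.DataFrame:
    """Evolve independent neutral local communities and return their counts.

    Returns a taxa x samples table over the full metacommunity taxon set
    (taxa never sampled locally appear as all-zero rows and are handled by
    the occupancy stages downstream).
    """
    scenario.validate()
    rng = np.random.default_rng(scenario.seed)
    S = scenario.metacommunity_taxa
    if scenario.metacommunity_abundances is not None:
        p = np.asarray(scenario.metacommunity_abundances, dtype=float)
        if len(p) != S or (p < 0).any() or p.sum() <= 0:
            raise ValueError("invalid metacommunity abundances")
    else:
        p = np.exp(scenario.metacommunity_sigma * rng.standard_normal(S))
    p = p / p.sum()
    cum = np.cumsum(p)

    C, N, m = scenario.n_samples, scenario.local_size, scenario.migration
    # community state: taxon index of each individual slot
    ind = np.searchsorted(cum, rng.random((C, N))).astype(np.int32)
    rows = np.arange(C)

    steps = scenario.burn_in * N
    chunk = 4096
    done = 0
    while done < steps:
        b = min(chunk, steps - done)
        deaths = rng.integers(0, N, size=(b, C))
        migrate = rng.random((b, C)) < m
        migrants = np.searchsorted(cum, rng.random((b, C))).astype(np.int32)
        # parent slot chosen uniformly among the other N-1 individuals
        offsets = rng.integers(1, N, size=(b, C))
        for t in range(b):
            parents = ind[rows, (deaths[t] + offsets[t]) % N]
            ind[rows, deaths[t]] = np.where(migrate[t], migrants[t], parents)
        done += b

    counts = np.zeros((S, C), dtype=np.int64)
    for c in range(C):
        counts[:, c] = np.bincount(ind[c], minlength=S)
    return pd.DataFrame(counts, index=_taxon_ids(S), columns=_sample_ids(C))


@dataclass
class TraitScenario:
    """Parameters of the Yule tree + trait generator.

    ``trait_mode`` is ``"clade_conserved"`` (all leaves of
    ``n_positive_clades`` disjoint internal clades of roughly ``clade_size``
    leaves are trait-positive) or ``"random"`` (the same number of positive
    leaves scattered uniformly).  A continuous response evolves by Brownian
    motion with rate ``brownian_var`` along branches regardless of mode.
    """

    n_leaves: int = 64
    birth_rate: float = 1.0
    trait_mode: str = "clade_conserved"
    n_positive_clades: int = 2
    clade_size: int = 8
    brownian_var: float = 1.0
    seed: int = 0

    def validate(self) -> None:
        if self.trait_mode not in ("clade_conserved", "random"):
            raise ValueError(f"unknown trait_mode {self.trait_mode!r}")
        if self.n_leaves < 4:
            raise ValueError("need at least 4 leaves")
        if self.trait_mode == "clade_conserved":
            if self.n_positive_clades * self.clade_size > self.n_leaves:
                raise ValueError("requested clades larger than available leaves")


def _yule_tree(n_leaves: int, birth_rate: float, seed: int) -> dendropy.Tree:
    tree = dendropy.model.birthdeath.birth_death_tree(
        birth_rate=birth_rate,
        death_rate=0.0,
        num_extant_tips=n_leaves,
        rng=_pyrandom.Random(seed),
    )
    # stable leaf labels independent of simulator-internal naming
    for i, leaf in enumerate(tree.leaf_node_iter()):
        leaf.taxon.label = f"L{i:04d}"
    return tree


def simulate_tree_and_traits(scenario: TraitScenario) -> tuple[dendropy.Tree, pd.DataFrame]:
    """Simulate a Yule tree with binary traits and Brownian responses.

    Returns the tree and a per-leaf table with columns ``trait`` (0/1) and
    ``response`` (signed Brownian value; its absolute value serves as the
    response magnitude in correlogram analyses).
    """
    scenario.validate()
    rng = np.random.default_rng(scenario.seed)
    tree = _yule_tree(scenario.n_leaves, scenario.birth_rate, scenario.seed)
    leaves = [lf.taxon.label for lf in tree.leaf_node_iter()]

    trait = pd.Series(0, index=leaves, dtype=int)
    if scenario.trait_mode == "clade_conserved":
        trait[_conserved_clade_leaves(tree, scenario)] = 1
    else:
        n_pos = min(scenario.n_positive_clades * scenario.clade_size, len(leaves))
        chosen = rng.choice(len(leaves), size=n_pos, replace=False)
        trait.iloc[chosen] = 1

    # Brownian motion from the root along branch lengths
    values = {}
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            values[node] = 0.0
        else:
            bl = node.edge.length or 0.0
            values[node] = values[node.parent_node] + rng.normal(
                0.0, np.sqrt(scenario.brownian_var * bl)
            )
    response = pd.Series(
        {lf.taxon.label: values[lf] for lf in tree.leaf_node_iter()}, dtype=float
    )
    table = pd.DataFrame({"trait": trait, "response": response.reindex(trait.index)})
    return tree, table


def _conserved_clade_leaves(tree: dendropy.Tree, scenario: TraitScenario) -> list[str]:
    """Pick disjoint internal clades closest in size to ``clade_size``."""
    candidates = []
    for node in tree.preorder_internal_node_iter():
        if node.parent_node is None:
            continue
        node_leaves = [lf.taxon.label for lf in node.leaf_iter()]
        if 2 <= len(node_leaves) <= 2 * scenario.clade_size:
            candidates.append((abs(len(node_leaves) - scenario.clade_size), node_leaves))
    candidates.sort(key=lambda t: (t[0], t[1]))
    chosen: list[list[str]] = []
    used: set[str] = set()
    for _, node_leaves in candidates:
        if used.isdisjoint(node_leaves):
            chosen.append(node_leaves)
            used.update(node_leaves)
        if len(chosen) == scenario.n_positive_clades:
            break
    if len(chosen) < scenario.n_positive_clades:
        raise ValueError(
            f"could only place {len(chosen)} of {scenario.n_positive_clades} "
            "disjoint conserved clades on this tree"
        )
    return sorted(used)


# ---------------------------------------------------------------------------
# Shipped scenario pair for the balanced- vs unbalanced-community contrast
# ---------------------------------------------------------------------------

def balanced_scenario(seed: int = 0) -> CommunityScenario:
    """A diverse, strongly modular community with real negative associations.

    Six tight guilds of ten taxa: half of each guild cooperates (strong
    positive loadings forming dense cliques), half antagonizes it through
    weaker negative loadings whose pairwise correlations feed negative
    cohesion but stay below the network edge threshold.  Guild factors are
    mutually weakly anticorrelated and abundances are even.  The resulting
    co-occurrence network is a set of clean positive cliques: highly
    modular, robust to random loss and with near-zero vulnerability, while
    the community keeps a high negative:positive cohesion ratio.
    """
    return CommunityScenario(
        n_taxa=60,
        n_samples=50,
        depth=20000,
        module_blocks=[(10, 0.85)] * 6,
        cross_block_correlation=-0.1,
        positive_fraction=0.5,
        negative_loading=0.10,
        abundance_sigma=1.0,
        fluctuation_sigma=1.0,
        seed=seed,
    )


def unbalanced_scenario(seed: int = 0) -> CommunityScenario:
    """A selection-stressed community: one dominant guild plus satellites.

    A single large, tightly co-oscillating guild holds the majority of the
    biomass (the taxa favored by the selective pressure; mean abundances
    are rank-assigned to it) and dominates the edge set, collapsing
    modularity.  The remaining taxa form many weakly linked two-taxon
    satellite pairs whose single borderline edge makes them prone to
    isolation during removal experiments, so robustness drops and
    vulnerability rises, while the community's association mass is
    overwhelmingly positive (low negative:positive cohesion ratio) and
    niche overlap is high.
    """
    return CommunityScenario(
        n_taxa=80,
        n_samples=50,
        depth=20000,
        module_blocks=[(30, 0.95)] + [(2, 0.7)] * 25,
        cross_block_correlation=0.15,
        positive_fraction=1.0,
        abundance_sigma=0.5,
        fluctuation_sigma=1.0,
        rank_abundance_by_block=True,
        seed=seed,
    )
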