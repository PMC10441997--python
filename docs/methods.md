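# Methods

This note records the models implemented in `microstab`, the assumptions
behind them, the defaults and why they were chosen, and what the synthetic
validation study does and does not demonstrate.

## Input model and table hygiene

All stages operate on a taxa × samples matrix of non-negative integer read
counts. Samples are assumed exchangeable within a group; libraries are made
comparable by rarefaction (random subsampling without replacement to a
common depth, implemented as a multivariate hypergeometric draw). Samples
below the target depth are dropped rather than resampled with replacement,
matching standard practice; taxa reduced to zero are kept as rows so the
taxon namespace is stable across stages. The depth is data-dependent and
therefore configurable; `16866` is recorded as the documented default for
real mouse-gut 16S runs, while synthetic studies choose depths matched to
their scenario. Rarefaction is applied before all stages by default (a flag
disables it); relative abundances are per-sample proportions.

## Co-occurrence networks

Within each sample group, taxa observed in fewer than 20% of samples are
removed before correlation: rare taxa produce spuriously perfect rank
correlations and would dominate the edge set. The paper-standard thresholds
are kept as defaults: Spearman |ρ| > 0.6 with average-rank ties, p-values
from the t approximation, and Benjamini–Hochberg FDR q < 0.01 across all
tested pairs. The magnitude threshold is applied to |ρ| so that negative
associations — required for negative cohesion and for meaningful signs in
the interaction-strength cascade — are retained as edges with negative
weight. Node abundance is the group-mean relative abundance.

Topology metrics (topological coefficient, neighborhood connectivity,
local clustering) and modularity are computed on the unweighted, sign-blind
skeleton; modularity uses greedy Clauset–Newman–Moore agglomeration with
|ρ| as edge weight and lexicographic node order, which makes the partition
deterministic without a seed (seeded Louvain is available behind a flag).
Module hubs are the top five nodes by within-module degree z-score
(Guimerà–Amaral); degenerate modules (size one, or zero degree spread)
score z = 0.

## Cohesion

Connectedness of taxon *i* is the mean of its strictly positive (resp.
strictly negative) *null-corrected* Pearson correlations with all other
taxa. The null correction subtracts the mean correlation over 200
taxon-shuffle permutations (each taxon's abundance vector permuted
independently across samples), removing the correlation floor that
compositionality and the abundance distribution induce. Cohesion of a
sample is the relative-abundance-weighted sum of connectedness values, and
the per-sample |negative|:positive ratio is summarized per group by the
median (per-sample values are emitted so any other summary can be
recomputed). Pearson on relative abundances is used for this backbone —
the cohesion method's original choice — while the network stage uses
Spearman; both are configurable. Cohesion is computed within groups, since
group-wise distributions are what the ratio is compared across.

## Robustness and vulnerability

The abundance-weighted mean interaction strength of node *i* over the live
community is `wMIS_i = Σ_{j≠i} b_j s_ij / Σ_{j≠i} b_j`, with s_ij the
signed edge weight (zero for non-adjacent pairs) and the sum over all other
live nodes. After an initial removal, every live node with wMIS ≤ 0 is
removed *synchronously* in each round until all survivors are strictly
positive. Synchronous removal makes the fixed point independent of node
processing order; the fixed point is idempotent. A node with no live
neighbors has wMIS = 0 and is therefore extinct — isolation is lethal under
this rule, which is what couples robustness to network sparsity. Robustness
is the mean surviving fraction over 100 random-removal repetitions at
removal fraction 0.5 (both configurable), or the single deterministic
result of removing the top five module hubs. Abundances are never rescaled
during the cascade; the wMIS denominator renormalizes automatically.

One consequence worth stating plainly: a network whose edges are all
positive suffers no secondary extinctions beyond isolation, so under this
cascade rule the *sign composition alone* cannot make a positively
connected network less robust — lower robustness of positive-dominated
communities arises through their sparser, more skewed network structure
(see the scenario design below).

Vulnerability uses global efficiency `E = mean over ordered pairs of
1/d_ij` with unweighted hop distances (correlation weights are not
distances) and disconnected pairs contributing zero. For each node, E is
recomputed on the graph without it, over the remaining nodes' pairs;
`V_i = (E − E_{−i})/E`, and the network's vulnerability is max_i V_i.

## Neutral community model

Detection frequency is predicted as `freq(p) = 1 − BetaCDF(d; Nm·p,
Nm(1−p))`. Nm is fitted by bounded least squares on log₁₀ Nm ∈ [−3, 7];
R² = 1 − SSE/SST (negative values are reported, not clipped); m = Nm/N with
N the uniform post-rarefaction reads per sample. Confidence intervals and
the 95% prediction band come from a nonparametric bootstrap over ASVs
(1000 replicates by default), and each ASV is partitioned as above / within
/ below the band.

The detection limit defaults to `d = 1/(2N)`, the continuity-corrected
midpoint: an ASV is detected when at least one read is present, which in
the continuous beta approximation corresponds to crossing half a read, not
a full read. This choice matters. The generative counterpart implemented
here is a Moran death–replacement process whose stationary abundance law is
Dirichlet-multinomial with concentration γ = m(N−1)/(1−m) rather than the
beta law with γ = Nm that the fitting formula assumes; with `d = 1/N` the
combined approximation error inflates fitted m by ×1.2 (m = 0.05) to ×2.1
(m = 0.6). With the midpoint correction the two biases cancel to within
±10% across m ∈ [0.05, 0.6] at N = 1000, making the fitted m an honest
estimate of the simulator's migration probability. Users who need the
uncorrected convention can pass `detection_limit` explicitly.

## Phylogenetic conservation of responses

Per-ASV responses are log₂-fold ratios of treatment versus reference group
means after median-of-ratios size-factor normalization (geometric-mean
reference over taxa detected in every sample; total-count fallback when no
such taxon exists), with a pseudocount of 0.5 on the normalized means. This
is deliberately a plain estimator — no dispersion shrinkage, no Wald test —
and externally computed log₂-fold-change tables are accepted wherever a
response table is consumed.

consenTRAIT: a preorder traversal marks the outermost clades whose
trait-positive leaf fraction reaches the 90% threshold; nested qualifying
clades are not counted again. A clade's depth is the mean path length from
its root node to its trait-positive leaves; τ_D is the mean over clades.
Positive leaves not covered by any qualifying clade are treated as
undersampled singletons contributing half their terminal branch length
(configurable off). Significance is the upper tail of the trait-label
permutation distribution with +1 smoothing (conserved responses form deeper
clades). The ensemble variant averages τ_D over bootstrap trees and pools
the null (10 randomizations per tree by default). Conservation is tested
separately for positive-response and negative-response indicators.

Mantel correlograms relate |response magnitude difference| to cophenetic
distance. Distance classes are equal-width bins with the class count from
Sturges' rule on the number of leaf pairs; the per-class statistic is the
Pearson correlation between the pairwise differences and the class
indicator, significance by two-sided leaf-label permutation (999 by
default, same permutations across classes), and progressive
(Holm/Bonferroni-style, increasing-distance order) correction of the raw
p-values. Because classes within one dataset share permutations and
information, calibration of the per-class type-I error is assessed class by
class across independent datasets, not pooled across classes.

## Levins niche metrics

Breadth B = 1/Σ p_s² over a taxon's usage distribution; overlap
O_ij = Σ p_i p_j / Σ p_i², reported symmetrized as (O_ij + O_ji)/2, which
is 1 for identical usage and 0 for disjoint support. The resource states
are the samples of a group — the paper-level analyses never define the
state space, so this choice is prominent in the output metadata and any
column partition can be substituted. Taxa absent from a group are excluded
from its summary, which is the mean symmetrized overlap over taxon pairs.

## Synthetic data: what it emulates, and what it does not

`simulate_correlated_community` draws, per sample, block factors from an
equicorrelated factor matrix (PSD-repaired by eigenvalue clipping; a repair
that moves any correlation by more than 0.1 aborts), builds each taxon's
latent Gaussian from a signed loading on its block factor, maps it
monotonically to lognormal abundance, and samples reads multinomially at
fixed depth. This controls the sign and strength of taxon–taxon
correlation independently of the abundance distribution.

A hard constraint discovered while designing the scenarios deserves
emphasis: on the relative-abundance scale, the biomass-weighted common mode
of the community is removed by normalization (closure). A community-wide
positive factor is therefore *unobservable*, and for K equal-biomass blocks
the observed between-block correlation is forced to −(within)/(K−1)
regardless of the latent factor correlation. Real compositional data obey
the same constraint; the generator does not evade it, it works within it.

The shipped scenario pair encodes two community architectures at identical
depth (20 000) and sample count (50):

* **balanced** — six guilds of ten taxa (within-guild loading 0.85), half
  of each guild loading negatively at 0.10 so that antagonistic
  correlations (~−0.3 observed) feed negative cohesion while staying below
  the 0.6 edge threshold; guild factors weakly anticorrelated (−0.1); even
  abundances. Its network is six clean positive cliques: Q ≈ 0.83,
  robustness ≈ 0.47, vulnerability ≈ 0.
* **unbalanced** — one dominant guild of thirty taxa (loading 0.95) holding
  the majority of biomass (mean abundances rank-assigned to it), plus 25
  two-taxon satellite pairs with a single borderline edge each (loading
  0.7), factor cross-correlation +0.15, lognormal spread 0.5. Its network
  is one big clique plus fragile satellites: Q ≈ 0.08, robustness ≈ 0.34
  (satellite isolation), vulnerability ≈ 0.03–0.2, association mass
  overwhelmingly positive, niche overlap high.

`simulate_neutral_assembly` evolves independent local communities by
zero-sum Moran death–replacement with immigration (one uniform death per
step; replacement is a metacommunity draw with probability m, otherwise the
offspring of a uniformly chosen other local individual), with a burn-in of
50 generations (one generation = N events) from a metacommunity-multinomial
start — several times the 1/m relaxation time for every m studied.
`simulate_tree_and_traits` draws Yule trees (birth rate 1), marks either
disjoint clades of ~8 leaves or an equal number of scattered leaves as
trait-positive, and evolves a continuous response by Brownian motion along
branches.

None of the generators model sequencing error, chimeras, taxonomic
mis-assignment, overdispersion beyond the lognormal fluctuation, or true
ecological dynamics (no births/deaths between samples, no time series).
Passing the validation study therefore shows that the *estimators measure
what they claim on data with known structure* — not that any particular
biological claim holds in real gut communities.

## Validation study sizes and numerical choices

The test suite validates every exact computation (cohesion, wMIS, cascade,
topology, hub z-scores, vulnerability, Levins overlap, BH adjustment)
against independent loop-level reimplementations on dozens of random
instances of ≤ 12 taxa, plus analytic fixed points (P₃/K₃ vulnerability,
clique robustness, symmetric-tree τ_D, uniform/point-mass breadth).
Stochastic checks use sizes chosen to give stable Monte-Carlo estimates on
one CPU: neutral-model recovery at N = 1000, 50 samples, 500 metacommunity
taxa, 10 replicates per migration level; permutation-test calibration on
64-leaf trees with 200 null replicates (KS at α = 0.01) and a
100-replicate power check; the direction contrast on 10 seed replicates of
the scenario pair. Permutation counts in tests (199–299) are smaller than
the shipped defaults (999–1000); the discreteness of the +1-smoothed
permutation p-value at B permutations caps the achievable α = 0.05
rejection rate at ⌊0.05(B+1)⌋/(B+1), which the calibration assertions
account for.

Floating-point policy: correlation matrices are cleaned of NaN (constant
taxa → zero, logged); eigenvalues below 1e-10 are treated as non-positive
in classical scaling; PCoA reports negative eigenvalues rather than
applying Lingoes/Cailliez corrections; all TSV output is serialized with 10
significant digits; every random stage takes an explicit seed, and the
pipeline derives per-stage seeds from the global seed by a stable hash of
the stage name so adding a stage never shifts another stage's stream.

## Known limitations

* Spearman-threshold networks inherit compositional bias; SparCC-style
  corrections are out of scope by design.
* The wMIS cascade treats isolation as extinction; communities whose taxa
  plausibly persist without detected partners will look less robust than
  they are.
* The NCM fit assumes a uniform N across samples (post-rarefaction) and
  exchangeable local communities; its m is only as meaningful as those
  assumptions.
* consenTRAIT depends on a rooted tree with branch lengths in consistent
  units; τ_D values are comparable only within one tree (or one bootstrap
  ensemble).
* The log₂-fold-ratio estimator is not a substitute for a shrinkage-based
  differential-abundance model when per-taxon inference matters.
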