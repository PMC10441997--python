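# microstab

Stability analysis of microbial communities from 16S amplicon (ASV) count
tables: co-occurrence network construction and topology, community cohesion,
robustness under extinction cascades, network vulnerability, Sloan's neutral
community model, phylogenetic conservation of perturbation responses
(consenTRAIT and Mantel correlograms), and Levins niche breadth/overlap.

## Who this is for

Microbial ecologists who want to go beyond composition ("who is there") to
community *stability*: how tightly taxa covary, whether the network would
survive random species loss, how much of assembly is neutral versus
selective, and whether responses to a perturbation (a diet shift, an
antibiotic) are phylogenetically conserved. Every stage works on a plain
taxa × samples integer count table (TSV), optional sample metadata, and an
optional Newick tree, and every stage is also backed by a seeded synthetic
generator so the whole pipeline can be exercised and validated without any
sequencing data.

## The quantities at the core

* **Co-occurrence network** — edges between ASVs with Spearman |ρ| > 0.6 and
  Benjamini–Hochberg *q* < 0.01 across a group's samples; signed ρ is the
  edge weight s<sub>ij</sub>, node abundance b<sub>j</sub> is the group-mean
  relative abundance. Per-node topology: topological coefficient,
  neighborhood connectivity, clustering; modularity *Q* by greedy
  Clauset–Newman–Moore; module hubs by within-module degree *z*-score.
* **Cohesion** — per sample, `cohesion± = Σᵢ abundanceᵢ × connectedness±ᵢ`
  where a taxon's connectedness is its mean positive (negative)
  null-model-corrected Pearson correlation with other taxa (taxon-shuffle
  null). The per-sample |negative|:positive ratio summarizes how much of a
  community's association mass is antagonistic.
* **Robustness** — abundance-weighted mean interaction strength of node *i*,
  `wMIS_i = Σ_{j≠i} b_j s_ij / Σ_{j≠i} b_j`; after removing a node set,
  every live node with wMIS ≤ 0 goes extinct, synchronously, until all
  survivors have wMIS > 0. Robustness is the surviving fraction after
  removing 50% of nodes at random (or the top five module hubs).
* **Vulnerability** — max over nodes of the relative drop in global
  efficiency (mean inverse shortest-path length) caused by deleting that
  node.
* **Neutral community model** — detection frequency of an ASV with mean
  relative abundance *p* predicted as `1 − BetaCDF(d; Nm·p, Nm(1−p))`;
  *Nm* fitted by least squares, *m = Nm/N*, with bootstrap confidence
  intervals and an above/within/below partition against the 95% prediction
  band.
* **consenTRAIT τ_D** — mean phylogenetic depth of the outermost clades in
  which ≥ 90% of leaves share a binary trait (e.g. "responds positively to
  the treatment"), with an upper-tail permutation test.
* **Mantel correlogram** — per distance class, the permutation correlation
  between pairwise response-magnitude differences and phylogenetic
  distance; a negative statistic at short distances means related taxa
  respond alike.
* **Levins niche breadth/overlap** — `B = 1/Σ p_s²` over resource states
  (a group's samples by default) and the symmetrized pairwise overlap
  `O_ij = Σ p_i p_j / Σ p_i²`.

## Worked example

Simulate a selection-stressed ("unbalanced") community — one dominant,
tightly co-oscillating guild plus many weakly attached satellite taxa — and
measure its network stability:

```sh
microstab simulate community --preset unbalanced --seed 1 --out community.tsv
microstab network   --table community.tsv --outdir net --seed 1
microstab cohesion  --table community.tsv --iterations 200 --seed 1 --out cohesion.tsv
microstab stability --table community.tsv --fraction 0.5 --reps 100 --seed 1 --out stability.json
```

which prints / produces:

```
nodes=62 edges=455 Q=0.0588
robustness_mean 0.357  sd 0.031  vulnerability 0.032
median neg:pos cohesion ratio 0.542
```

Read: the co-occurrence network is large but barely modular (*Q* ≈ 0.06 —
one guild dominates the edge set), and after randomly removing half of the
taxa only ~36% of nodes survive the extinction cascade (many satellites end
up isolated, and isolated nodes are extinct under the wMIS rule). The
balanced preset (`--preset balanced`) gives the opposite profile: six clean
modules (*Q* ≈ 0.83), robustness ≈ 0.47 (essentially only the removed nodes
are lost), near-zero vulnerability and a higher negative:positive cohesion
ratio.

The full pipeline (rarefaction → diversity → per-group networks → cohesion →
robustness/vulnerability → neutral model → consenTRAIT/correlograms → niche)
runs from a YAML config:

```sh
microstab run --config pipeline.yaml --seed 1 --outdir results/
```

with `pipeline.yaml` naming the count table, metadata, tree and per-stage
parameters (see `microstab.pipeline.PipelineConfig` for all keys and
defaults). Every output carries its stage parameters and seed in a header,
and a `manifest.json` lists all artifacts; two runs with the same config and
seed are byte-identical.

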