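"""End-to-end pipeline orchestration with config, seeding and manifests.

The pipeline runs rarefaction, diversity, per-group network construction
and topology, cohesion, robustness/vulnerability, the neutral model fit,
niche metrics and (when a tree is available) the phylogenetic-conservation
stages.  Every output file carries its stage parameters and seed in a
commented metadata header, and a JSON manifest lists all artifacts.  One
global seed fans out to per-stage child seeds through a stable hash of the
stage name, so adding or removing a stage never shifts another stage's
random stream.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import cohesion as cohesion_mod
from . import core_io, diversity, network, neutral, niche, phylo, stability

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_pipeline", "stage_seed"]

#: documented default depth for real 16S runs; synthetic runs set their own
REAL_DATA_RAREFACTION_DEPTH = 16866


def stage_seed(global_seed: int, stage: str) -> int:
    """Derive a stable per-stage child seed from the global seed."""
    return (int(global_seed) * 1_000_003 + zlib.crc32(stage.encode())) % (2**31)


@dataclass
class PipelineConfig:
    table: str
    metadata: str | None = None
    tree: str | None = None
    responses: str | None = None
    outdir: str = "microstab_out"
    seed: int = 0
    rarefy: bool = True
    rarefaction_depth: int | None = None  # None: smallest sample total
    rho_threshold: float = 0.6
    q_threshold: float = 0.01
    prevalence_min: float = 0.2
    cohesion_iterations: int = 200
    removal_fraction: float = 0.5
    robustness_repetitions: int = 100
    hub_count: int = 5
    ncm_bootstrap: int = 1000
    share_threshold: float = 0.9
    consentrait_permutations: int = 1000
    mantel_permutations: int = 999
    reference_group: str | None = None
    treatment_group: str | None = None

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)


def _write_tsv(df: pd.DataFrame, path: Path, params: dict) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for k, v in params.items():
            fh.write(f"# {k}={v}\n")
        df.to_csv(fh, sep="\t", float_format="%.10g")


def _write_json(obj, path: Path, params: dict) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump({"params": params, "result": obj}, fh, indent=1, sort_keys=True)


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all stages and return the run manifest (also written to disk)."""
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"seed": config.seed, "artifacts": []}

    def artifact(name: str) -> Path:
        manifest["artifacts"].append(name)
        return out / name

    # echo the configuration verbatim
    with open(artifact("config.json"), "w", encoding="utf-8") as fh:
        json.dump(dataclasses.asdict(config), fh, indent=1, sort_keys=True)

    def stage(name):
        def wrap(fn):
            try:
                return fn()
            except Exception as exc:  # noqa: BLE001 - report the failing stage
                raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
        return wrap

    table = stage("read_table")(lambda: core_io.read_asv_table(config.table))
    groups: pd.Series | None = None
    if config.metadata:
        meta = stage("read_metadata")(lambda: core_io.read_metadata(config.metadata))
        missing = [s for s in table.columns if s not in meta.index]
        if missing:
            raise RuntimeError(f"pipeline stage 'read_metadata' failed: samples without group: {missing}")
        groups = meta.loc[table.columns]

    depth = config.rarefaction_depth
    if config.rarefy:
        if depth is None:
            depth = int(table.sum(axis=0).min())
        seed = stage_seed(config.seed, "rarefy")
        table = stage("rarefy")(lambda: core_io.rarefy(table, depth, seed))
        if groups is not None:
            groups = groups.loc[table.columns]
        _write_tsv(table, artifact("rarefied_table.tsv"), {"stage": "rarefy", "depth": depth, "seed": seed})
    reads_per_sample = depth if config.rarefy else float(table.sum(axis=0).mean())

    # ---- diversity ----------------------------------------------------
    def run_diversity():
        alpha = diversity.chao1_per_sample(table).to_frame()
        if groups is not None:
            alpha["group"] = groups
        _write_tsv(alpha, artifact("alpha_diversity.tsv"), {"stage": "diversity", "index": "chao1"})
        bc = diversity.bray_curtis(table)
        _write_tsv(bc, artifact("bray_curtis.tsv"), {"stage": "diversity"})
        ord_res = diversity.pcoa(bc, k=min(3, bc.shape[0] - 1))
        _write_tsv(
            ord_res.coordinates, artifact("pcoa_coordinates.tsv"),
            {"stage": "diversity",
             "proportion_explained": list(np.round(ord_res.proportion_explained, 6))},
        )
    stage("diversity")(run_diversity)

    # ---- per-group stages ---------------------------------------------
    group_tables = (
        {g: table.loc[:, groups.index[groups == g]] for g in groups.unique()}
        if groups is not None else {"all": table}
    )
    summary_rows = {}
    for gname, gtab in sorted(group_tables.items()):
        row = _run_group(gname, gtab, config, reads_per_sample, artifact)
        summary_rows[gname] = row
    _write_tsv(
        pd.DataFrame.from_dict(summary_rows, orient="index"),
        artifact("group_summary.tsv"), {"stage": "summary"},
    )

    # ---- phylogenetic stages ------------------------------------------
    if config.tree and Path(config.tree).exists():
        stage("phylo")(lambda: _run_phylo(table, groups, config, artifact))
    elif config.tree:
        logger.warning("tree path %s not found; skipping phylogenetic stages", config.tree)

    with open(out / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return manifest


def _run_group(gname, gtab, config, reads_per_sample, artifact) -> dict:
    row: dict = {"n_samples": gtab.shape[1]}
    seed_net = stage_seed(config.seed, f"network:{gname}")
    try:
        net = network.build_group_network(
            gtab, config.rho_threshold, config.q_threshold, config.prevalence_min
        )
    except ValueError as exc:
        logger.warning("group %s: network not built (%s)", gname, exc)
        return row
    topo = network.topology_metrics(net)
    modules, q = network.detect_modules(net, seed=seed_net)
    hubs = network.module_hubs(net, top_n=config.hub_count)
    node_table = topo.join(hubs[["module", "z_within", "is_hub"]])
    _write_tsv(node_table, artifact(f"network_nodes_{gname}.tsv"),
               {"stage": "network", "group": gname, "modularity": q})
    edges = pd.DataFrame(
        [(u, v, d["weight"], d["q"]) for u, v, d in net.edges(data=True)],
        columns=["taxon_a", "taxon_b", "rho", "q_fdr"],
    )
    _write_tsv(edges.set_index("taxon_a"), artifact(f"network_edges_{gname}.tsv"),
               {"stage": "network", "group": gname,
                "rho_threshold": config.rho_threshold, "q_threshold": config.q_threshold})
    row.update(n_nodes=net.number_of_nodes(), n_edges=net.number_of_edges(), modularity=q)

    seed_coh = stage_seed(config.seed, f"cohesion:{gname}")
    rel = core_io.to_relative_abundance(gtab)
    coh = cohesion_mod.cohesion(rel, iterations=config.cohesion_iterations, seed=seed_coh)
    _write_tsv(coh.per_sample, artifact(f"cohesion_{gname}.tsv"),
               {"stage": "cohesion", "group": gname,
                "iterations": config.cohesion_iterations, "seed": seed_coh})
    row["cohesion_ratio_median"] = float(coh.per_sample["ratio"].median())

    if net.number_of_nodes() < 3:
        logger.warning("group %s: network too small for stability analysis", gname)
        return row
    seed_rob = stage_seed(config.seed, f"robustness:{gname}")
    rob = stability.robustness(
        net, "random", fraction=config.removal_fraction,
        repetitions=config.robustness_repetitions, seed=seed_rob,
    )
    hub_rob = stability.robustness(net, "module_hubs", hub_count=config.hub_count)
    vuln = stability.vulnerability(net)
    _write_json(
        {
            "robustness_random": {"mean": rob.mean, "sd": rob.sd,
                                  "proportions": rob.proportions.tolist()},
            "robustness_module_hubs": hub_rob.mean,
            "global_efficiency": vuln.global_efficiency,
            "network_vulnerability": vuln.network_vulnerability,
            "node_vulnerability": vuln.node_vulnerability.round(10).to_dict(),
        },
        artifact(f"stability_{gname}.json"),
        {"stage": "stability", "group": gname, "fraction": config.removal_fraction,
         "repetitions": config.robustness_repetitions, "seed": seed_rob},
    )
    row.update(robustness_mean=rob.mean, vulnerability=vuln.network_vulnerability)

    seed_ncm = stage_seed(config.seed, f"ncm:{gname}")
    try:
        fit = neutral.fit_ncm(
            neutral.occurrence_stats(gtab), n_reads=reads_per_sample,
            bootstrap=config.ncm_bootstrap, seed=seed_ncm,
        )
        _write_tsv(fit.per_asv, artifact(f"ncm_asv_{gname}.tsv"),
                   {"stage": "ncm", "group": gname, "m": fit.m, "R2": fit.r2})
        _write_json(
            {"m": fit.m, "Nm": fit.nm, "R2": fit.r2, "ci95_m": list(fit.ci95_m),
             "ci95_R2": list(fit.ci95_r2), "detection_limit": fit.detection_limit,
             "N": fit.n_reads,
             "partition_counts": fit.partition_counts.to_dict()},
            artifact(f"ncm_fit_{gname}.json"),
            {"stage": "ncm", "group": gname, "bootstrap": config.ncm_bootstrap,
             "seed": seed_ncm},
        )
        row.update(ncm_m=fit.m, ncm_r2=fit.r2)
    except ValueError as exc:
        logger.warning("group %s: NCM fit skipped (%s)", gname, exc)

    nm = niche.niche_metrics(gtab)
    _write_tsv(nm.breadth.to_frame(), artifact(f"niche_breadth_{gname}.tsv"),
               {"stage": "niche", "group": gname, "mean_overlap": nm.mean_overlap,
                "states": "samples within group"})
    row["mean_niche_overlap"] = nm.mean_overlap
    return row


def _run_phylo(table, groups, config, artifact) -> None:
    tree = core_io.read_tree(config.tree)
    leaves = {lf.taxon.label for lf in tree.leaf_node_iter()}
    if config.responses:
        resp = pd.read_csv(config.responses, sep="\t", index_col=0, comment="#")
        if "log2_fold_ratio" not in resp.columns:
            raise ValueError("responses table needs a log2_fold_ratio column")
    elif groups is not None and config.reference_group and config.treatment_group:
        resp = phylo.log2_fold_response(
            table, groups, config.reference_group, config.treatment_group
        )
    else:
        logger.warning("no responses available; skipping phylogenetic stages")
        return
    resp = resp.loc[resp.index.intersection(leaves)]
    sub_leaves = sorted(resp.index)
    if len(sub_leaves) < len(leaves):
        tree = tree.extract_tree_with_taxa_labels(sub_leaves)
    ratio = resp["log2_fold_ratio"]

    seed_ct = stage_seed(config.seed, "consentrait")
    results = {}
    for direction, positive in (("positive", ratio > 0), ("negative", ratio < 0)):
        if positive.sum() == 0:
            logger.warning("no %s-responding taxa; consenTRAIT skipped", direction)
            continue
        res = phylo.consentrait(
            tree, positive.astype(int), config.share_threshold,
            config.consentrait_permutations, seed=seed_ct,
        )
        results[direction] = {"tau_D": res.tau_d, "p_value": res.p_value,
                              "n_clades": len(res.clades)}
    _write_json(results, artifact("consentrait.json"),
                {"stage": "consentrait", "threshold": config.share_threshold,
                 "permutations": config.consentrait_permutations, "seed": seed_ct})

    seed_mg = stage_seed(config.seed, "mantelgram")
    dist = phylo.cophenetic_distances(tree)
    mag = ratio.abs().reindex(dist.index).to_numpy()
    diff = pd.DataFrame(np.abs(mag[:, None] - mag[None, :]),
                        index=dist.index, columns=dist.columns)
    gram = phylo.mantel_correlogram(
        dist, diff, permutations=config.mantel_permutations, seed=seed_mg
    )
    _write_tsv(gram.classes, artifact("mantel_correlogram.tsv"),
               {"stage": "mantelgram", "permutations": config.mantel_permutations,
                "seed": seed_mg})
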