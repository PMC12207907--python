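"""End-to-end orchestration: simulate/ingest -> rarefy -> alpha diversity ->
specificity-occupancy -> beta partition + distance-decay -> null-model
assembly -> co-occurrence network -> PERMANOVA/VPA, from one YAML config.

Every stochastic stage receives a stage-specific seed derived by hashing
(global seed, stage name), so adding a stage never perturbs the randomness
of earlier ones. Re-running a config reproduces all outputs byte-identically
(the manifest records parameters, seeds, and SHA-256 checksums).
"""

from __future__ import annotations

import hashlib
import itertools
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from skbio import TreeNode

from continuum_assembly import assembly, beta, diversity, multivariate, network
from continuum_assembly import spec_occu as so
from continuum_assembly.datamodel import (
    CommunityTable, read_community_table, read_newick_tree,
    read_sample_metadata, validate_dataset, write_community_table)
from continuum_assembly.simulate import SimulationParams, simulate_metacommunity

logger = logging.getLogger(__name__)

STAGES = ("data", "rarefy", "alpha", "spec_occu", "beta", "distance_decay",
          "assembly", "network", "stats")


def stage_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage seed below 2**31."""
    digest = hashlib.blake2s(f"{global_seed}:{stage}".encode(),
                             digest_size=4).digest()
    return int.from_bytes(digest, "little") % (2 ** 31)


def load_config(path) -> dict:
    with open(path) as fh:
        config = yaml.safe_load(fh)
    if "seed" not in config:
        raise ValueError("config must set a global 'seed'")
    if ("simulation" not in config) == ("input" not in config):
        raise ValueError("config needs exactly one of 'simulation' or 'input'")
    return config


def _checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: dict, output_dir) -> dict:
    """Run every stage and write TSV outputs plus a JSON run manifest."""
    out = Path(output_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = int(config["seed"])
    manifest = {"seed": seed, "config": config, "stages": {}}
    t0 = time.time()

    # ---- stage 1: data (simulate or ingest) --------------------------
    if "simulation" in config:
        params = SimulationParams(**config["simulation"],
                                  seed=stage_seed(seed, "simulate"))
        table, meta, tree, truth = simulate_metacommunity(params)
        truth_df = pd.DataFrame({"niche_optimum": truth.niche_optima})
        truth_df.to_csv(out / "ground_truth.tsv", sep="\t", index_label="taxon_id")
    else:
        paths = config["input"]
        table = read_community_table(paths["table"],
                                     orientation=paths.get(
                                         "orientation", "samples_as_rows"))
        meta = read_sample_metadata(paths["metadata"])
        tree = read_newick_tree(paths["tree"]) if paths.get("tree") else None
        _, table = validate_dataset(table, meta, tree,
                                    strict=paths.get("strict", False))
    grouping_col = config.get("grouping", "region")
    if grouping_col not in meta.columns:
        raise ValueError(f"grouping column {grouping_col!r} not in metadata")
    for col in config.get("vpa", {}).get("env_columns", []):
        if col not in meta.columns:
            raise ValueError(f"VPA env column {col!r} not in metadata")
    write_community_table(table, out / "community.tsv")
    meta.to_csv(out / "metadata.csv")
    if tree is not None:
        tree.write(str(out / "tree.nwk"), format="newick")
    _record(manifest, "data", out, ["community.tsv", "metadata.csv"]
            + (["tree.nwk"] if tree is not None else [])
            + (["ground_truth.tsv"] if "simulation" in config else []))

    # ---- stage 2: rarefaction ----------------------------------------
    depth = config.get("rarefaction_depth") or int(table.data.sum(axis=1).min())
    rare = diversity.rarefy(table, depth, seed=stage_seed(seed, "rarefy"))
    write_community_table(rare, out / "rarefied.tsv")
    meta = meta.loc[rare.sample_ids]
    _record(manifest, "rarefy", out, ["rarefied.tsv"], depth=depth)

    # ---- stage 3: alpha diversity ------------------------------------
    alpha = diversity.alpha_diversity(rare, tree=tree)
    alpha.to_csv(out / "alpha_diversity.tsv", sep="\t", index_label="sample_id")
    _record(manifest, "alpha", out, ["alpha_diversity.tsv"])

    # ---- stage 4: specificity-occupancy ------------------------------
    so_cfg = config.get("spec_occu", {})
    records = so.spec_occu_table(rare, meta[grouping_col],
                                 top_n=so_cfg.get("top_n", 1000))
    records = so.call_specialists(records, cutoff=so_cfg.get("cutoff", 0.7))
    records.to_csv(out / "spec_occu.tsv", sep="\t", index=False)
    _record(manifest, "spec_occu", out, ["spec_occu.tsv"])

    # ---- stage 5: beta diversity -------------------------------------
    bc = beta.dissimilarity_matrix(rare, metric="bray_curtis")
    km = beta.geographic_distance_matrix(meta)
    part = beta.partition_beta(rare, mode="pairwise")
    kml = km.to_data_frame().stack()
    part["km"] = [kml.loc[(i, j)] for i, j in zip(part["i"], part["j"])]
    bcl = bc.to_data_frame().stack()
    part["bray_curtis"] = [bcl.loc[(i, j)] for i, j in zip(part["i"], part["j"])]
    part.to_csv(out / "beta_partition.tsv", sep="\t", index=False)
    _record(manifest, "beta", out, ["beta_partition.tsv"])

    # ---- stage 6: distance-decay -------------------------------------
    dd = beta.distance_decay(km, bc, n_perm=config.get("n_perm", 999),
                             seed=stage_seed(seed, "distance_decay"))
    pd.DataFrame([dd]).to_csv(out / "distance_decay.tsv", sep="\t", index=False)
    _record(manifest, "distance_decay", out, ["distance_decay.tsv"])

    # ---- stage 7: assembly null model --------------------------------
    acfg = config.get("assembly", {})
    if tree is None:
        raise ValueError("assembly stage requires a phylogenetic tree")
    pairs = list(itertools.combinations(rare.sample_ids, 2))
    max_pairs = acfg.get("max_pairs")
    if max_pairs and len(pairs) > max_pairs:
        rng = np.random.default_rng(stage_seed(seed, "assembly_pairs"))
        pairs = [pairs[k] for k in
                 sorted(rng.choice(len(pairs), size=max_pairs, replace=False))]
    pair_bins = assembly.assembly_analysis(
        rare, tree, pairs=pairs,
        metric=acfg.get("metric", "beta_mpd"),
        bin_size_limit=acfg.get("bin_size_limit", 64),
        n_rand=acfg.get("n_rand", 999),
        seed=stage_seed(seed, "assembly"))
    pair_bins.to_csv(out / "assembly_pair_bins.tsv", sep="\t", index=False)
    grouping = {(i, j): (meta.loc[i, grouping_col]
                         if meta.loc[i, grouping_col] == meta.loc[j, grouping_col]
                         else "between")
                for i, j in pairs}
    fractions = assembly.aggregate_processes(pair_bins, grouping)
    fractions.to_csv(out / "assembly_fractions.tsv", sep="\t",
                     index_label="group")
    _record(manifest, "assembly", out,
            ["assembly_pair_bins.tsv", "assembly_fractions.tsv"])

    # ---- stage 8: co-occurrence network ------------------------------
    ncfg = config.get("network", {})
    water = meta.index[meta["habitat"] == "water"]
    net_table = rare.subset_samples([s for s in rare.sample_ids if s in set(water)]) \
        if len(water) >= 4 else rare
    filtered = network.filter_taxa(
        net_table,
        min_rel_abund=ncfg.get("min_rel_abund", 0.0001),
        min_occurrence=ncfg.get("min_occurrence", 0.20))
    if ncfg.get("rmt", False):
        scan = network.rmt_threshold(filtered)
        threshold = scan["threshold"]
    else:
        threshold = ncfg.get("threshold", network.RMT_PRESET_WHOLE)
    net = network.correlation_edges(filtered, threshold,
                                    fdr_alpha=ncfg.get("fdr_alpha", 0.05))
    net.edge_table().to_csv(out / "network_edges.tsv", sep="\t", index=False)
    topo = network.network_topology(net)
    topo.to_csv(out / "network_topology.tsv", sep="\t", header=["value"])
    subnet = network.sample_subnetwork_features(net, net_table)
    subnet.to_csv(out / "subnetwork_features.tsv", sep="\t",
                  index_label="sample_id")
    robust = network.robustness(net, removal_fraction=0.5,
                                reps=ncfg.get("robustness_reps", 100),
                                seed=stage_seed(seed, "network"))
    pd.DataFrame([{k: robust[k] for k in ("mean", "sd")}]).to_csv(
        out / "network_robustness.tsv", sep="\t", index=False)
    _record(manifest, "network", out,
            ["network_edges.tsv", "network_topology.tsv",
             "subnetwork_features.tsv", "network_robustness.tsv"],
            threshold=float(threshold))

    # ---- stage 9: multivariate stats ---------------------------------
    vcfg = config.get("vpa", {})
    env_cols = vcfg.get("env_columns",
                        ["salinity", "temperature", "pH", "DO"])
    perm = multivariate.permanova(bc, meta[grouping_col],
                                  n_perm=config.get("n_perm", 999),
                                  seed=stage_seed(seed, "stats"),
                                  factor=grouping_col)
    env = meta.loc[net_table.sample_ids, env_cols].astype(float)
    retained, trace = multivariate.vif_select(
        env, threshold=vcfg.get("vif_threshold", 10.0))
    biotic = subnet.select_dtypes(float)
    biotic = biotic.loc[:, biotic.notna().all() & (biotic.nunique() > 1)]
    n = len(net_table.sample_ids)
    max_biotic = max(0, n - 2 - len(retained) - 1)
    biotic = biotic.iloc[:, :max_biotic]
    vpa = multivariate.variation_partition(
        net_table, env[retained], biotic if biotic.shape[1] else None)
    stats = {"permanova_r2": perm.r_squared, "permanova_f": perm.pseudo_f,
             "permanova_p": perm.p_value, "vif_retained": ",".join(retained),
             **vpa.as_dict()}
    pd.DataFrame([stats]).to_csv(out / "stats.tsv", sep="\t", index=False)
    _record(manifest, "stats", out, ["stats.tsv"])

    manifest["runtime_seconds"] = round(time.time() - t0, 2)
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return manifest


def _record(manifest: dict, stage: str, out: Path, files, **extra) -> None:
    manifest["stages"][stage] = {
        "outputs": {f: _checksum(out / f) for f in files},
        **extra,
    }
    logger.info("stage %s complete (%d output file(s))", stage, len(files))
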