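"""End-to-end pipeline driver: qc -> preprocess -> differential ->
cluster -> correlate -> network -> enrich.

Every threshold of the analysis is a named config key with the study
value as default (TQC CV < 30%, blank < 10% of TQC, log2 offset 1,
FDR < 0.05, GP lengthscale 6, minimum cluster size 10, stage-1 filter
R^2 > 0.6 / p-adj < 0.05, stage-2 filter R^2 > 0.7 / p-adj < 0.01,
network q < 1e-12).  ``run_all`` executes the stages in order, writes
every intermediate table to the output directory and returns a
manifest recording seeds and per-stage record counts; with a fixed seed
the outputs are byte-identical across reruns.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .association import correlate_features, feature_table, filter_stage
from .clustering import DEFAULT_ALPHAS, ClusterSet, cluster_trajectories
from .differential import run_differential
from .io import (
    AbundanceMatrix,
    ExpressionMatrix,
    PipelineError,
    RunManifest,
    read_abundance_table,
    read_expression_table,
    read_gene_list,
    read_gmt,
    write_abundance_table,
    write_expression_table,
    write_network,
)
from .network import (
    extract_network,
    fit_ggm,
    hypergeom_enrich,
    node_type_counts,
    split_by_lipid_class,
)
from .preprocess import (
    adjust_donor_effects,
    compute_cv_table,
    log_transform,
    qc_filter,
    quantile_normalize,
    zscore_rows,
)
from .simulate import SynthConfig, generate_dataset, synthetic_gene_sets

log = logging.getLogger("lipidyn")

__all__ = ["PipelineConfig", "load_config", "save_config", "run_all"]


@dataclass
class PipelineConfig:
    """All inputs, thresholds and seeds of one pipeline run."""

    # inputs: either file paths or a synthetic-data block
    abundance_path: str | None = None
    abundance_samples: str | None = None
    expression_path: str | None = None
    expression_samples: str | None = None
    pathway_genes_path: str | None = None
    gmt_path: str | None = None
    simulate: SynthConfig | None = None

    # QC
    qc_enabled: bool = True
    cv_max: float = 30.0              # TQC CV% threshold
    blank_max: float = 0.10           # blank mean < 10% of TQC mean

    # preprocessing
    log_offset: float = 1.0

    # differential testing
    fdr: float = 0.05
    time_categorical: bool = True

    # clustering
    lengthscale: float = 6.0
    signal_variance: float = 1.0
    noise_variance: float | None = None
    alphas: tuple = DEFAULT_ALPHAS
    runs_per_alpha: int = 10
    n_sweeps: int = 60
    min_cluster_size: int = 10
    resolution_clusters: str | list = "auto"

    # association stages
    association_pairing: str = "timepoint_means"
    stage1_r2: float = 0.6
    stage1_padj: float = 0.05
    stage2_r2: float = 0.7
    stage2_padj: float = 0.01

    # network
    network_pairing: str = "timepoint_means"
    q_max: float = 1e-12
    eta0: float = 0.9
    class_split_a: tuple = ("Gb3", "Gb4")
    class_split_b: tuple = ("CE",)

    seed: int = 0

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        if self.simulate is not None:
            d["simulate"] = dataclasses.asdict(self.simulate)
        for k, v in d.items():
            if isinstance(v, tuple):
                d[k] = list(v)
        if isinstance(d.get("simulate"), dict):
            for k, v in d["simulate"].items():
                if isinstance(v, tuple):
                    d["simulate"][k] = list(v)
        return d


def load_config(path: str | Path) -> PipelineConfig:
    raw = yaml.safe_load(Path(path).read_text()) or {}
    sim = raw.pop("simulate", None)
    cfg = PipelineConfig(**raw)
    if sim is not None:
        cfg.simulate = SynthConfig(**sim)
    return cfg


def save_config(config: PipelineConfig, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(config.to_dict(), sort_keys=True))


# ---------------------------------------------------------------------------

def _stage(name: str):
    def wrap(fn):
        def inner(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as exc:
                raise PipelineError(f"stage {name!r} failed: {exc}") from exc
        return inner
    return wrap


def _load_inputs(config: PipelineConfig):
    if config.simulate is not None:
        sim = dataclasses.replace(config.simulate, seed=config.seed)
        lipidome, expression, truth = generate_dataset(sim)
        pathway_genes = truth.pathway_genes
        gene_sets = (
            read_gmt(config.gmt_path) if config.gmt_path
            else synthetic_gene_sets(sim, truth)
        )
        return lipidome, expression, pathway_genes, gene_sets, truth
    if not (config.abundance_path and config.abundance_samples):
        raise PipelineError("config names neither input files nor a simulate block")
    lipidome = read_abundance_table(config.abundance_path, config.abundance_samples)
    expression = None
    if config.expression_path:
        expression = read_expression_table(
            config.expression_path, config.expression_samples or config.abundance_samples
        )
    pathway_genes = (
        read_gene_list(config.pathway_genes_path) if config.pathway_genes_path else []
    )
    gene_sets = read_gmt(config.gmt_path) if config.gmt_path else None
    return lipidome, expression, pathway_genes, gene_sets, None


def _detect_resolution_clusters(clusters: ClusterSet, config: PipelineConfig) -> list[int]:
    """Major clusters whose posterior mean rises into the last time point.

    A cluster is resolution-phase when its posterior mean peaks at the
    last time point, the 8h -> 16h increment dominates its dynamic
    range, and the net baseline -> 16h increase does too (excluding
    early-drop/late-recovery shapes that merely return to baseline);
    falls back to the steepest late riser if none qualifies strictly.
    """
    if config.resolution_clusters != "auto":
        return [int(c) for c in config.resolution_clusters]
    picked, rises = [], {}
    for cid in clusters.major_clusters:
        mu = clusters.posteriors[cid].mean
        rise = mu[-1] - mu[-2]
        rises[cid] = rise
        span = mu.max() - mu.min()
        if (rise > 0 and mu[-1] >= mu.max() - 1e-9
                and rise >= span / 2 and mu[-1] - mu[0] >= span / 2):
            picked.append(cid)
    if not picked and rises:
        picked = [max(rises, key=lambda c: rises[c])]
    return sorted(picked)


def run_all(config: PipelineConfig, out_dir: str | Path) -> RunManifest:
    """Execute the full pipeline and write all intermediate tables."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(config.to_dict(), version=__version__)
    manifest.seeds["pipeline"] = config.seed
    counts = manifest.stage_counts
    fmt = dict(sep="\t", float_format="%.10g")

    lipidome, expression, pathway_genes, gene_sets, truth = _stage("load")(_load_inputs)(config)
    counts["lipids_input"] = lipidome.values.shape[0]
    if config.simulate is not None:
        write_abundance_table(lipidome, out / "abundance_raw.tsv", out / "lipid_samples.tsv")
        if expression is not None:
            write_expression_table(expression, out / "expression.tsv", out / "expression_samples.tsv")
    if truth is not None:
        (out / "truth.json").write_text(json.dumps({
            "cluster_labels": {k: int(v) for k, v in truth.cluster_labels.items()},
            "resolution_lipids": list(truth.resolution_lipids),
            "planted_edges": [[a, b, s] for a, b, s in truth.planted_edges],
        }, indent=2, sort_keys=True) + "\n")

    # --- qc ---------------------------------------------------------------
    if config.qc_enabled:
        filtered, qc_report = _stage("qc")(qc_filter)(lipidome, config.cv_max, config.blank_max)
        qc_report.to_csv(out / "qc_report.tsv", **fmt)
    else:
        filtered = lipidome
    cv_table = _stage("qc")(compute_cv_table)(filtered)
    cv_table.to_csv(out / "cv_table.tsv", **fmt)
    counts["lipids_pass_qc"] = filtered.values.shape[0]
    log.info("qc: %d/%d lipids kept", counts["lipids_pass_qc"], counts["lipids_input"])

    # --- preprocess -------------------------------------------------------
    pre = _stage("preprocess")(
        lambda m: log_transform(quantile_normalize(m).biological(), config.log_offset)
    )(filtered)
    write_abundance_table(pre, out / "preprocessed_log2.tsv")

    # --- differential -----------------------------------------------------
    diff = _stage("differential")(run_differential)(pre, config.fdr, config.time_categorical)
    diff.to_csv(out / "differential.tsv", **fmt)
    sig = diff.index[diff["significant"]]
    counts["lipids_significant"] = int(len(sig))
    log.info("differential: %d significant lipids at FDR<%g", len(sig), config.fdr)

    # --- clustering -------------------------------------------------------
    resid = _stage("cluster")(lambda m: zscore_rows(adjust_donor_effects(m)))(
        pre.subset_features(sig)
    )
    clusters = _stage("cluster")(cluster_trajectories)(
        resid,
        lengthscale=config.lengthscale,
        signal_variance=config.signal_variance,
        noise_variance=config.noise_variance,
        alphas=config.alphas,
        runs_per_alpha=config.runs_per_alpha,
        seed=config.seed,
        n_sweeps=config.n_sweeps,
        min_size=config.min_cluster_size,
    )
    manifest.seeds["clustering"] = config.seed
    counts["lipids_clustered"] = int(len(clusters.labels))
    counts["clusters_total"] = len(clusters.posteriors)
    counts["clusters_major"] = len(clusters.major_clusters)
    counts["lipids_in_major_clusters"] = int(
        clusters.labels.isin(clusters.major_clusters).sum()
    )
    labels_df = pd.DataFrame({
        "cluster": clusters.labels,
        "lipid_class": filtered.features.loc[clusters.labels.index, "lipid_class"],
        "is_major": clusters.labels.isin(clusters.major_clusters),
    })
    labels_df.index.name = "feature_id"
    labels_df.to_csv(out / "cluster_labels.tsv", **fmt)
    post_rows = []
    for cid in sorted(clusters.posteriors):
        p = clusters.posteriors[cid]
        for t, (mu, var) in enumerate(zip(p.mean, np.diag(p.covariance))):
            post_rows.append((cid, t, mu, var, p.member_count))
    pd.DataFrame(
        post_rows, columns=["cluster", "grid_index", "mean", "variance", "n_lipids"]
    ).to_csv(out / "cluster_posteriors.tsv", index=False, **fmt)
    (out / "display_order.json").write_text(
        json.dumps({"display_order": [int(c) for c in clusters.display_order],
                    "noise_clusters": [int(c) for c in clusters.noise_clusters]},
                   sort_keys=True) + "\n")
    composition = (
        labels_df[labels_df["is_major"]]
        .groupby(["cluster", "lipid_class"]).size().rename("n_lipids").reset_index()
    )
    composition.to_csv(out / "cluster_composition.tsv", index=False, **fmt)
    log.info("clustering: %d clusters (%d major)",
             counts["clusters_total"], counts["clusters_major"])

    if expression is None:
        manifest.to_json(out / "manifest.json")
        return manifest

    # --- association ------------------------------------------------------
    res_clusters = _detect_resolution_clusters(clusters, config)
    counts["resolution_clusters"] = len(res_clusters)
    res_lipids = list(clusters.labels.index[clusters.labels.isin(res_clusters)])
    counts["resolution_lipids"] = len(res_lipids)
    pathway = [g for g in pathway_genes if g in expression.values.index]
    lip_tab = feature_table(pre.subset_features(res_lipids), config.association_pairing)
    gene_tab = feature_table(expression, config.association_pairing).loc[pathway]

    stage1 = _stage("correlate")(correlate_features)(lip_tab, gene_tab)
    stage1_kept = filter_stage(stage1, config.stage1_r2, config.stage1_padj)
    stage1_kept.to_csv(out / "stage1_correlations.tsv", index=False, **fmt)
    s1_lipids = sorted(stage1_kept["feature_a"].unique())
    s1_genes = sorted(stage1_kept["feature_b"].unique())
    counts["stage1_lipids"] = len(s1_lipids)
    counts["stage1_genes"] = len(s1_genes)
    log.info("stage 1: %d lipids x %d pathway transcripts retained",
             len(s1_lipids), len(s1_genes))

    genomewide = [g for g in expression.values.index if g not in set(pathway)]
    tx_tab = feature_table(expression, config.association_pairing).loc[genomewide]
    stage2 = _stage("correlate")(correlate_features)(gene_tab.loc[s1_genes], tx_tab)
    stage2_kept = filter_stage(stage2, config.stage2_r2, config.stage2_padj)
    stage2_kept.to_csv(out / "stage2_correlations.tsv", index=False, **fmt)
    s2_genes = sorted(stage2_kept["feature_a"].unique())
    s2_tx = sorted(stage2_kept["feature_b"].unique())
    counts["stage2_genes"] = len(s2_genes)
    counts["stage2_transcripts"] = len(s2_tx)

    # --- network ----------------------------------------------------------
    lip_net = feature_table(pre.subset_features(res_lipids), config.network_pairing)
    expr_net = feature_table(expression, config.network_pairing)
    data = pd.concat([lip_net, expr_net.loc[s1_genes], expr_net.loc[s2_tx]])
    node_types = {**{l: "lipid" for l in res_lipids},
                  **{g: "pathway_gene" for g in s1_genes},
                  **{t: "transcript" for t in s2_tx}}
    ggm = _stage("network")(fit_ggm)(data, node_types, config.eta0)
    manifest.seeds["network"] = config.seed
    ggm.edges.to_csv(out / "ggm_edges.tsv", index=False, **fmt)
    lipid_classes = {
        l: filtered.features.loc[l, "lipid_class"] for l in res_lipids
    }
    net = extract_network(ggm.edges, config.q_max, node_types, lipid_classes)
    write_network(net, out / "network_edges.tsv", "edge_tsv")
    write_network(net, out / "network.sif", "sif")
    write_network(net, out / "network.graphml", "graphml")
    type_counts = node_type_counts(net)
    counts["network_edges"] = net.number_of_edges()
    for t, c in type_counts.items():
        counts[f"network_nodes_{t}"] = c
    (out / "network_counts.json").write_text(
        json.dumps({"lambda": ggm.lam, "kappa": ggm.kappa,
                    "node_counts": type_counts,
                    "n_edges": net.number_of_edges()}, indent=2, sort_keys=True) + "\n")
    log.info("network: %d edges at q<%g (lambda=%.3f, kappa=%.1f)",
             net.number_of_edges(), config.q_max, ggm.lam, ggm.kappa)

    # --- class split + enrichment ----------------------------------------
    a_only, b_only, shared = split_by_lipid_class(
        net, set(config.class_split_a), set(config.class_split_b)
    )
    (out / "class_split.json").write_text(json.dumps({
        "class_a": sorted(config.class_split_a), "class_b": sorted(config.class_split_b),
        "genes_a_only": sorted(a_only), "genes_b_only": sorted(b_only),
        "genes_shared": sorted(shared),
    }, indent=2, sort_keys=True) + "\n")
    counts["genes_class_a_only"] = len(a_only)
    counts["genes_class_b_only"] = len(b_only)
    counts["genes_shared"] = len(shared)

    if gene_sets is not None and len(gene_sets):
        universe = [v for v, t in node_types.items() if t != "lipid"]
        for name, query in [("a_only", a_only), ("b_only", b_only), ("shared", shared)]:
            if not query:
                continue
            enr = _stage("enrich")(hypergeom_enrich)(query, gene_sets, universe)
            enr.to_csv(out / f"enrichment_{name}.tsv", index=False, **fmt)
            counts[f"enriched_terms_{name}"] = int((enr["p_adjusted"] < 0.05).sum())

    manifest.to_json(out / "manifest.json")
    return manifest
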