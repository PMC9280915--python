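"""Synthetic-data generator: planted structure and determinism."""

import dataclasses

import numpy as np
import pandas as pd
import pytest

from lipidyn.io import PipelineError
from lipidyn.preprocess import qc_filter
from lipidyn.simulate import (
    CLUSTER_SHAPES,
    SynthConfig,
    generate_dataset,
    generate_lipidome,
    generate_qc_samples,
    generate_transcriptome,
    synthetic_gene_sets,
)

SMALL = dict(n_donors=4, n_clusters=3, lipids_per_cluster=6,
             cluster_shapes=("early_down", "peak_3h", "resolution"),
             n_pathway_genes=8, n_transcripts=10, n_planted_edges=2)


def test_noise_free_limit_reproduces_cluster_means():
    cfg = SynthConfig(**SMALL, noise_sd=0.0, donor_effect_sd=0.0, seed=0)
    lip, truth = generate_lipidome(cfg)
    log2 = np.log2(lip.values.to_numpy())
    times = lip.samples["time_hours"].to_numpy()
    for i, fid in enumerate(lip.values.index):
        shape = CLUSTER_SHAPES[truth.cluster_shapes[truth.cluster_labels[fid]]](times)
        centered = log2[i] - log2[i][times == 0].mean()
        np.testing.assert_allclose(centered, cfg.amplitude * shape, atol=1e-9)


def test_generator_is_deterministic():
    cfg = SynthConfig(**SMALL, seed=42)
    lip1, expr1, t1 = generate_dataset(cfg)
    lip2, expr2, t2 = generate_dataset(cfg)
    pd.testing.assert_frame_equal(lip1.values, lip2.values)
    pd.testing.assert_frame_equal(expr1.values, expr2.values)
    assert t1.planted_edges == t2.planted_edges


def test_lipids_per_cluster_contract():
    with pytest.raises(PipelineError):
        SynthConfig(lipids_per_cluster=0)
    with pytest.raises(PipelineError, match="increasing"):
        SynthConfig(time_points=(0, 3, 1))


def test_high_cv_classes_have_inflated_baseline_cv():
    """Gb3 lipids get a donor-effect sd several-fold larger, so their
    baseline CV% exceeds the median of other classes almost surely."""
    wins = 0
    n_sim = 100
    for seed in range(n_sim):
        cfg = SynthConfig(n_donors=8, n_clusters=2, lipids_per_cluster=8,
                          cluster_shapes=("early_down", "resolution"),
                          high_cv_classes=("Gb3",), high_cv_factor=5.0,
                          n_tqc=2, seed=seed)
        lip, truth = generate_lipidome(cfg)
        t0 = lip.samples.index[lip.samples["time_hours"] == 0]
        vals = lip.values[list(t0)]
        cv = 100 * vals.std(axis=1, ddof=1) / vals.mean(axis=1)
        is_gb3 = lip.features["lipid_class"] == "Gb3"
        if cv[is_gb3].mean() > cv[~is_gb3].median():
            wins += 1
    assert wins >= 0.95 * n_sim


def test_donor_offset_moments_converge():
    """Across many seeds the mean donor-offset variance matches the
    configured donor_effect_sd^2 within 10%."""
    variances = []
    for seed in range(200):
        cfg = SynthConfig(n_donors=6, n_clusters=2, lipids_per_cluster=4,
                          cluster_shapes=("early_down", "resolution"),
                          high_cv_classes=(), donor_effect_sd=0.4, seed=seed)
        _, truth = generate_lipidome(cfg)
        variances.append(truth.donor_offsets.to_numpy().var(ddof=1))
    assert np.mean(variances) == pytest.approx(0.16, rel=0.10)


# --- QC columns ------------------------------------------------------------

def test_qc_columns_contracts():
    cfg = SynthConfig(**SMALL, tqc_cv=0.0, seed=3)
    lip, truth = generate_lipidome(cfg)
    full = generate_qc_samples(cfg, lip, truth)
    tqc = full.values[full.sample_ids("tqc")]
    cv = 100 * tqc.std(axis=1, ddof=1) / tqc.mean(axis=1)
    noisy = set(truth.tqc_noisy_lipids)
    clean = [l for l in full.values.index if l not in noisy]
    np.testing.assert_allclose(cv[clean], 0.0, atol=1e-9)
    blanks = full.values[full.sample_ids("blank")]
    non_contam = [l for l in full.values.index if l not in set(truth.contaminant_lipids)]
    assert (blanks.loc[non_contam].to_numpy() == 0).all()
    with pytest.raises(PipelineError, match="n_tqc"):
        generate_qc_samples(dataclasses.replace(cfg, n_tqc=1), lip, truth)


def test_contaminants_fail_blank_rule_downstream():
    cfg = SynthConfig(**SMALL, blank_contaminant_fraction=0.15, seed=4)
    lip, truth = generate_lipidome(cfg)
    full = generate_qc_samples(cfg, lip, truth)
    _, report = qc_filter(full, cv_max=30.0, blank_max=0.10)
    for lipid in truth.contaminant_lipids:
        assert report.loc[lipid, "reason"] == "present_in_blank"


def test_generated_matrices_survive_write_read_validation(tmp_path):
    from lipidyn.io import read_abundance_table, read_expression_table, \
        write_abundance_table, write_expression_table
    lip, expr, truth = generate_dataset(SynthConfig(**SMALL, seed=5))
    write_abundance_table(lip, tmp_path / "a.tsv", tmp_path / "s.tsv")
    back = read_abundance_table(tmp_path / "a.tsv", tmp_path / "s.tsv")
    np.testing.assert_allclose(back.values.to_numpy(), lip.values.to_numpy())
    write_expression_table(expr, tmp_path / "e.tsv", tmp_path / "es.tsv")
    read_expression_table(tmp_path / "e.tsv", tmp_path / "es.tsv")


# --- transcriptome ---------------------------------------------------------

def test_null_partial_correlations_without_planted_edges():
    """With no planted edges, gene-gene sample partial correlations stay
    small at n = 55 (median |pcor| of null pairs below 0.2)."""
    from lipidyn.network import partial_correlations, shrink_correlation
    cfg = SynthConfig(n_clusters=3, lipids_per_cluster=10,
                      cluster_shapes=("early_down", "peak_3h", "resolution"),
                      n_pathway_genes=25, n_transcripts=25,
                      planted_edges=[], seed=6)
    lip, truth = generate_lipidome(cfg)
    expr, truth = generate_transcriptome(cfg, truth, lip)
    X = expr.values.to_numpy().T  # 55 samples x 50 genes
    R, _ = shrink_correlation(X)
    pc = partial_correlations(R)
    iu = np.triu_indices(pc.shape[0], 1)
    assert np.median(np.abs(pc[iu])) < 0.2
    assert len(iu[0]) >= 1000


def test_single_planted_edge_sign_recovery():
    """A planted lipid-gene edge at +0.6 recovers a positive sample
    partial correlation in >= 99/100 seeds at n = 55."""
    from lipidyn.network import partial_correlations, shrink_correlation
    hits = 0
    for seed in range(100):
        cfg = SynthConfig(n_clusters=2, lipids_per_cluster=4,
                          cluster_shapes=("early_down", "resolution"),
                          n_pathway_genes=5, n_transcripts=0, seed=seed)
        lip, truth = generate_lipidome(cfg)
        lipid = truth.resolution_lipids[0]
        cfg = dataclasses.replace(cfg, planted_edges=[(lipid, "LPG001", 0.6)])
        lip, truth = generate_lipidome(cfg)
        expr, truth = generate_transcriptome(cfg, truth, lip)
        x = np.log2(lip.values.loc[lipid].to_numpy() + 1)
        data = np.column_stack([x, expr.values.to_numpy().T])
        R, _ = shrink_correlation(data)
        pc = partial_correlations(R)
        if pc[0, 1] > 0:  # gene LPG001 is the first expression row
            hits += 1
    assert hits >= 99


def test_planted_forest_requires_single_parent():
    cfg = SynthConfig(**SMALL, seed=1,
                      planted_edges=[("A", "G1", 0.5), ("B", "G1", 0.5)])
    lip, truth = generate_lipidome(cfg)
    with pytest.raises(PipelineError, match="forest"):
        generate_transcriptome(cfg, truth, lip)
    with pytest.raises(PipelineError, match="strength"):
        SynthConfig(**SMALL, planted_edges=[("A", "G1", 1.5)])


def test_synthetic_gene_sets_contains_planted_program():
    lip, expr, truth = generate_dataset(SynthConfig(**SMALL, seed=7))
    coll = synthetic_gene_sets(SynthConfig(**SMALL, seed=7), truth)
    coupled = set(coll.genes("RESOLUTION_COUPLED"))
    planted_children = {b for _, b, _ in truth.planted_edges}
    assert planted_children <= coupled
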