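"""Recovery metrics against planted synthetic ground truth.

Used to score how well a pipeline run recovers what the synthetic-data
generator planted: cluster-label agreement (adjusted Rand index), the
integrity of the resolution-phase cluster, and planted lipid-gene edge
recovery in the partial-correlation network.
"""

from __future__ import annotations

import json
from pathlib import Path

import networkx as nx
import pandas as pd
from sklearn.metrics import adjusted_rand_score

from .simulate import SyntheticTruth

__all__ = [
    "clustering_ari",
    "resolution_binary_ari",
    "edge_recovery",
    "score_run_dir",
]


def clustering_ari(truth_labels: pd.Series, found_labels: pd.Series) -> float:
    """Adjusted Rand index between planted and recovered partitions,
    over the lipids present in both."""
    common = found_labels.index.intersection(truth_labels.index)
    return float(adjusted_rand_score(truth_labels.loc[common], found_labels.loc[common]))


def resolution_binary_ari(
    resolution_lipids, found_labels: pd.Series, detected_clusters
) -> float:
    """ARI of the two-block partition induced by the resolution cluster.

    Truth side: resolution lipids vs the rest; found side: members of
    the detected resolution cluster(s) vs the rest.  Equals 1 when the
    detected resolution cluster contains exactly the planted lipids.
    """
    res = set(resolution_lipids)
    det = set(detected_clusters)
    truth_bin = [lip in res for lip in found_labels.index]
    found_bin = [c in det for c in found_labels]
    return float(adjusted_rand_score(truth_bin, found_bin))


def edge_recovery(
    truth: SyntheticTruth | set, network: nx.Graph
) -> tuple[int, int, int]:
    """Planted lipid-gene edge recovery in a thresholded network.

    Returns (n_planted, n_recovered, n_false_positive) where false
    positives are detected lipid-gene edges that were not planted;
    lipid-lipid and gene-gene edges are not counted (the planted truth
    constrains only the lipid-gene support).
    """
    if isinstance(truth, SyntheticTruth):
        planted = truth.planted_lipid_gene_edges()
    else:
        planted = {frozenset(e) for e in truth}
    detected = set()
    for u, v in network.edges():
        tu = network.nodes[u].get("node_type")
        tv = network.nodes[v].get("node_type")
        if {tu, tv} == {"lipid", "pathway_gene"}:
            detected.add(frozenset((u, v)))
    recovered = len(planted & detected)
    fp = len(detected - planted)
    return len(planted), recovered, fp


def score_run_dir(out_dir: str | Path) -> dict:
    """Score a finished ``run_all`` output directory against its truth.json."""
    out = Path(out_dir)
    truth = json.loads((out / "truth.json").read_text())
    labels = pd.read_csv(out / "cluster_labels.tsv", sep="\t", index_col=0)
    truth_labels = pd.Series(truth["cluster_labels"])
    ari = clustering_ari(truth_labels, labels["cluster"])

    # detected resolution clusters = clusters of the lipids entering stage 1
    s1 = pd.read_csv(out / "stage1_correlations.tsv", sep="\t")
    net_edges = pd.read_csv(out / "network_edges.tsv", sep="\t")
    res_lipids = set(truth["resolution_lipids"])
    lipids_in_net = set()
    for _, row in net_edges.iterrows():
        if row["source_type"] == "lipid":
            lipids_in_net.add(row["source"])
        if row["target_type"] == "lipid":
            lipids_in_net.add(row["target"])
    planted = {
        frozenset(e[:2]) for e in truth["planted_edges"]
        if set(e[:2]) & res_lipids
    }
    detected = {
        frozenset((row["source"], row["target"]))
        for _, row in net_edges.iterrows()
        if {row["source_type"], row["target_type"]} == {"lipid", "pathway_gene"}
    }
    return {
        "clustering_ari": ari,
        "n_planted_edges": len(planted),
        "n_recovered_edges": len(planted & detected),
        "n_false_positive_edges": len(detected - planted),
        "n_stage1_pairs": int(len(s1)),
    }
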