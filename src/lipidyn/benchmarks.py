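"""Benchmark experiments on synthetic data with planted ground truth.

Each function runs one self-contained experiment — generating its
inputs, running the corresponding pipeline machinery, and scoring the
result against the planted truth or an independent oracle (brute-force
formula, Monte-Carlo estimate, exact combinatorial summation).  The
test suite asserts thresholds on these outputs; the reproduction script
reports them.
"""

from __future__ import annotations

import dataclasses
import math
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import adjusted_rand_score, roc_auc_score

from .clustering import (
    ClusterPosterior,
    cluster_trajectories,
    symmetric_kl_mvn,
    vi_distance,
)
from .differential import estimate_prior, run_differential
from .evaluate import resolution_binary_ari
from .fixtures import fixture_pipeline_config
from .io import AbundanceMatrix
from .network import (
    edge_significance,
    extract_network,
    partial_correlations,
    shrink_correlation,
)
from .pipeline import run_all
from .preprocess import (
    adjust_donor_effects,
    log_transform,
    quantile_normalize,
    zscore_rows,
)
from .simulate import SynthConfig, generate_lipidome

__all__ = [
    "clustering_recovery",
    "vi_metric_suite",
    "symmetric_kl_vs_monte_carlo",
    "moderated_f_null_rejection",
    "prior_recovery",
    "shrinkage_lambda_vs_bruteforce",
    "ggm_edge_auroc",
    "null_network_empty_fraction",
    "hypergeom_vs_exact_summation",
    "end_to_end_fixture",
]


def _seed(base: int, salt: int) -> int:
    return int(np.random.SeedSequence((base, salt)).generate_state(1)[0] % (2 ** 31))


# ---------------------------------------------------------------------------
# clustering
# ---------------------------------------------------------------------------

def clustering_recovery(
    seed: int = 0,
    n_clusters: int = 6,
    lipids_per_cluster: int = 25,
    runs_per_alpha: int = 10,
    n_sweeps: int = 60,
) -> dict:
    """Full-schedule DP-GP recovery of six planted trajectory clusters.

    Generates a 150-lipid, 11-donor, 5-time-point lipidome at the
    default (moderate) noise level, runs the complete preprocessing
    chain and the full 10 x 5-alpha clustering schedule, and scores the
    VI-selected run against the planted labels.
    """
    cfg = SynthConfig(n_clusters=n_clusters, lipids_per_cluster=lipids_per_cluster,
                      seed=_seed(seed, 1))
    lipidome, truth = generate_lipidome(cfg)
    z = zscore_rows(adjust_donor_effects(log_transform(quantile_normalize(lipidome).biological())))
    clusters = cluster_trajectories(
        z, runs_per_alpha=runs_per_alpha, seed=_seed(seed, 2), n_sweeps=n_sweeps
    )
    ari = adjusted_rand_score(
        truth.cluster_labels.loc[clusters.labels.index], clusters.labels
    )
    return {
        "ari": float(ari),
        "n_lipids": int(len(clusters.labels)),
        "n_runs": runs_per_alpha * 5,
        "n_clusters_found": int(clusters.labels.nunique()),
    }


def vi_metric_suite(seed: int = 0, n_triples: int = 100) -> dict:
    """Metric axioms of the VI distance on random partition triples,
    plus the worked three-item example."""
    rng = np.random.default_rng(_seed(seed, 3))
    max_violation = 0.0
    for _ in range(n_triples):
        n = int(rng.integers(5, 40))
        parts = [rng.integers(0, rng.integers(2, 6), size=n) for _ in range(3)]
        d01 = vi_distance(parts[0], parts[1])
        d12 = vi_distance(parts[1], parts[2])
        d02 = vi_distance(parts[0], parts[2])
        assert vi_distance(parts[0], parts[0]) == 0.0
        assert abs(d01 - vi_distance(parts[1], parts[0])) <= 1e-12
        max_violation = max(max_violation, d02 - (d01 + d12))
    return {
        "triangle_max_violation": float(max_violation),
        "worked_example_nats": vi_distance([1, 1, 2], [1, 2, 2]),
        "n_triples": n_triples,
    }


def symmetric_kl_vs_monte_carlo(
    seed: int = 0, n_pairs: int = 20, n_samples: int = 1_000_000, dim: int = 5
) -> dict:
    """Closed-form symmetric KL vs a Monte-Carlo estimate.

    KL(P||Q) is estimated as the average log density ratio under
    samples from P (and symmetrically for Q); the maximum relative
    error over random Gaussian pairs is reported.
    """
    rng = np.random.default_rng(_seed(seed, 4))
    max_rel_err = 0.0
    for _ in range(n_pairs):
        mus = [rng.normal(0, 1, dim) for _ in range(2)]
        covs = []
        for _ in range(2):
            A = rng.normal(0, 1, (dim, dim))
            covs.append(A @ A.T + 0.5 * np.eye(dim))
        closed = symmetric_kl_mvn(
            ClusterPosterior(mus[0], covs[0], 1), ClusterPosterior(mus[1], covs[1], 1)
        )
        mc = 0.0
        for (mu_a, cov_a), (mu_b, cov_b) in [((mus[0], covs[0]), (mus[1], covs[1])),
                                             ((mus[1], covs[1]), (mus[0], covs[0]))]:
            x = rng.multivariate_normal(mu_a, cov_a, size=n_samples)
            la = stats.multivariate_normal.logpdf(x, mu_a, cov_a)
            lb = stats.multivariate_normal.logpdf(x, mu_b, cov_b)
            mc += float(np.mean(la - lb))
        max_rel_err = max(max_rel_err, abs(mc - closed) / closed)
    return {"max_rel_err": float(max_rel_err), "n_pairs": n_pairs}


# ---------------------------------------------------------------------------
# differential testing
# ---------------------------------------------------------------------------

def _null_matrix(rng, n_features, n_donors=11, times=(0, 0.5, 3, 8, 16),
                 donor_sd=0.5) -> AbundanceMatrix:
    rows = []
    for d in range(n_donors):
        for t in times:
            rows.append((f"D{d:02d}_T{t:g}", f"D{d:02d}", float(t), "biological"))
    samples = pd.DataFrame(
        rows, columns=["sample_id", "donor_id", "time_hours", "sample_type"]
    ).set_index("sample_id")
    codes = pd.Categorical(samples["donor_id"]).codes
    Y = (rng.standard_normal((n_features, len(samples)))
         + donor_sd * rng.standard_normal((n_features, n_donors))[:, codes] + 8.0)
    fids = [f"L{i}" for i in range(n_features)]
    return AbundanceMatrix(
        pd.DataFrame(Y, index=fids, columns=samples.index),
        pd.DataFrame({"lipid_class": "PC"}, index=fids),
        samples, "log",
    )


def moderated_f_null_rejection(seed: int = 0, n_features: int = 2000) -> dict:
    """Rejection rate of the moderated F-test on a pure-null simulation
    (no time effect, Gaussian noise, donor effects present)."""
    rng = np.random.default_rng(_seed(seed, 5))
    res = run_differential(_null_matrix(rng, n_features))
    frac = float((res["p_value"] < 0.05).mean())
    lo, hi = stats.binom.ppf([0.005, 0.995], n_features, 0.05) / n_features
    return {"rejection_rate": frac, "interval": (float(lo), float(hi)),
            "n_features": n_features}


def prior_recovery(seed: int = 0, n_features: int = 5000,
                   d0: float = 4.0, s0_sq: float = 2.0, df: int = 10) -> dict:
    """Recovery of a known scaled-inverse-chi-square variance prior from
    compound-sampled residual variances."""
    rng = np.random.default_rng(_seed(seed, 6))
    sigma2 = d0 * s0_sq / rng.chisquare(d0, size=n_features)
    s2 = sigma2 * rng.chisquare(df, size=n_features) / df
    prior = estimate_prior(s2, df)
    return {"d0": float(prior.d0), "s0_sq": float(prior.s0_sq),
            "true_d0": d0, "true_s0_sq": s0_sq, "n_features": n_features}


# ---------------------------------------------------------------------------
# shrinkage GGM
# ---------------------------------------------------------------------------

def _bruteforce_lambda(X: np.ndarray) -> float:
    """Direct double-loop evaluation of the optimal shrinkage intensity."""
    n, p = X.shape
    Z = (X - X.mean(axis=0)) / X.std(axis=0, ddof=1)
    num = den = 0.0
    for i in range(p):
        for j in range(p):
            if i == j:
                continue
            w = Z[:, i] * Z[:, j]
            r = w.sum() / (n - 1)
            num += n / (n - 1) ** 3 * ((w - w.mean()) ** 2).sum()
            den += r * r
    return min(1.0, num / den)


def shrinkage_lambda_vs_bruteforce(seed: int = 0, n_reps: int = 25) -> dict:
    """Vectorized lambda vs the brute-force formula on random 10 x 8 data."""
    rng = np.random.default_rng(_seed(seed, 7))
    max_diff = 0.0
    for _ in range(n_reps):
        X = rng.standard_normal((10, 8))
        _, lam = shrink_correlation(X)
        max_diff = max(max_diff, abs(lam - _bruteforce_lambda(X)))
    return {"max_abs_diff": float(max_diff), "n_reps": n_reps}


def _planted_ggm(rng, p=60, n=40, k=30, strength=0.4, max_degree=2):
    omega = np.eye(p)
    deg = np.zeros(p, dtype=int)
    pairs = []
    while len(pairs) < k:
        i, j = rng.integers(p, size=2)
        key = (min(i, j), max(i, j))
        if i != j and deg[i] < max_degree and deg[j] < max_degree and key not in pairs:
            pairs.append(key)
            deg[i] += 1
            deg[j] += 1
            omega[i, j] = omega[j, i] = strength * rng.choice([-1, 1])
    assert np.linalg.eigvalsh(omega).min() > 0.01
    sigma = np.linalg.inv(omega)
    d = np.sqrt(np.diag(sigma))
    sigma = sigma / np.outer(d, d)
    X = rng.multivariate_normal(np.zeros(p), sigma, size=n)
    return X, set(pairs)


def ggm_edge_auroc(seed: int = 0, p: int = 60, n: int = 40, k: int = 30) -> dict:
    """AUROC of the |partial correlation| ranking for planted edges."""
    rng = np.random.default_rng(_seed(seed, 8))
    X, pairs = _planted_ggm(rng, p, n, k)
    R, lam = shrink_correlation(X)
    pc = partial_correlations(R)
    iu = np.triu_indices(p, 1)
    truth = np.array([(i, j) in pairs for i, j in zip(*iu)], dtype=float)
    auroc = roc_auc_score(truth, np.abs(pc[iu]))
    return {"auroc": float(auroc), "lambda": float(lam),
            "n_vars": p, "n_samples": n, "n_edges": k}


def null_network_empty_fraction(seed: int = 0, n_runs: int = 100,
                                p: int = 60, n: int = 40,
                                q_max: float = 1e-12) -> dict:
    """Fraction of all-null simulations yielding an empty network at the
    stringent q threshold."""
    import warnings as _warnings
    empty = 0
    for r in range(n_runs):
        rng = np.random.default_rng(_seed(seed, 9_000 + r))
        X = rng.standard_normal((n, p))
        R, _ = shrink_correlation(X)
        pc = partial_correlations(R)
        with _warnings.catch_warnings():
            _warnings.simplefilter("ignore")
            edges, _ = edge_significance(pc, n_effective=n)
        net = extract_network(edges, q_max)
        empty += net.number_of_edges() == 0
    return {"empty_fraction": empty / n_runs, "n_runs": n_runs}


# ---------------------------------------------------------------------------
# enrichment
# ---------------------------------------------------------------------------

def hypergeom_vs_exact_summation(seed: int = 0, n_configs: int = 1000) -> dict:
    """Hypergeometric tail p-values vs exact integer-arithmetic summation."""
    rng = np.random.default_rng(_seed(seed, 10))
    max_err = 0.0
    for _ in range(n_configs):
        N = int(rng.integers(10, 200))
        K = int(rng.integers(1, N))
        n = int(rng.integers(1, N))
        k = int(rng.integers(0, min(K, n) + 1))
        p_impl = float(stats.hypergeom.sf(k - 1, N, K, n))
        tot = math.comb(N, n)
        tail = sum(
            math.comb(K, x) * math.comb(N - K, n - x)
            for x in range(k, min(K, n) + 1)
        )
        max_err = max(max_err, abs(p_impl - tail / tot))
    return {"max_abs_err": float(max_err), "n_configs": n_configs}


# ---------------------------------------------------------------------------
# end to end
# ---------------------------------------------------------------------------

def end_to_end_fixture(seed: int = 1, out_dir: str | Path = "scratch/e2e",
                       check_rerun: bool = True) -> dict:
    """Full pipeline on the packaged synthetic fixture.

    Scores resolution-cluster integrity (two-block ARI between planted
    resolution membership and the pipeline's detected resolution
    cluster), planted lipid-gene edge recovery at the fixture q
    threshold, and byte-level reproducibility of a rerun.
    """
    import json

    out = Path(out_dir)
    cfg = fixture_pipeline_config(seed)
    manifest = run_all(cfg, out / "run1")

    truth = json.loads((out / "run1" / "truth.json").read_text())
    labels = pd.read_csv(out / "run1" / "cluster_labels.tsv", sep="\t", index_col=0)

    # detected resolution clusters: lipid variables that entered the network
    s1 = pd.read_csv(out / "run1" / "stage1_correlations.tsv", sep="\t")
    res_detected = set()
    ggm = pd.read_csv(out / "run1" / "ggm_edges.tsv", sep="\t")
    lipid_vars = {
        v for v in pd.concat([ggm["source"], ggm["target"]]).unique()
        if v in labels.index
    }
    detected_clusters = set(labels.loc[sorted(lipid_vars), "cluster"].unique())
    res_ari = resolution_binary_ari(
        truth["resolution_lipids"], labels["cluster"], detected_clusters
    )

    planted = {
        frozenset(e[:2]) for e in truth["planted_edges"]
        if set(e[:2]) & set(truth["resolution_lipids"])
    }
    net = pd.read_csv(out / "run1" / "network_edges.tsv", sep="\t")
    lip_gene = net[
        net.apply(lambda r: {r["source_type"], r["target_type"]}
                  == {"lipid", "pathway_gene"}, axis=1)
    ] if len(net) else net
    detected = {frozenset((r.source, r.target)) for r in lip_gene.itertuples()}

    identical = None
    if check_rerun:
        run_all(cfg, out / "run2")
        identical = True
        for p1 in sorted((out / "run1").iterdir()):
            p2 = out / "run2" / p1.name
            if not p2.exists() or p1.read_bytes() != p2.read_bytes():
                identical = False
    return {
        "resolution_ari": float(res_ari),
        "n_planted_edges": len(planted),
        "n_recovered_edges": len(planted & detected),
        "n_false_positive_edges": len(detected - planted),
        "rerun_byte_identical": identical,
        "n_lipids": manifest.stage_counts["lipids_input"],
        "stage_counts": manifest.stage_counts,
    }
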