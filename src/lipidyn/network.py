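"""Shrinkage partial-correlation (Gaussian graphical model) networks.

The sample correlation matrix of {resolution lipids + pathway
transcripts + genome-wide transcripts} is shrunk toward the identity
with the analytic optimal intensity

    lambda* = sum_{i != j} Var-hat(r_ij) / sum_{i != j} r_ij^2

(clipped to [0, 1]), which keeps the estimate positive definite when
variables far outnumber samples.  Full-order partial correlations are
the scaled negative inverse: pcor_ij = -Omega_ij / sqrt(Omega_ii
Omega_jj) with Omega = R*^-1.  Edge significance uses the null density
f0(r; kappa) proportional to (1 - r^2)^((kappa-3)/2) with kappa fitted
by maximum likelihood to the central bulk of the observed partial
correlations; q-values are Benjamini-Hochberg over all edges, and the
network keeps edges with q below a stringent threshold (default
1e-12 at full scale).  Gene sets attached to lipid-class-specific
subnetworks are tested with a one-sided hypergeometric test.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import optimize, special, stats

from .differential import bh_adjust
from .io import GeneSetCollection, PipelineError

__all__ = [
    "GGMResult",
    "shrink_correlation",
    "partial_correlations",
    "fit_null_kappa",
    "edge_significance",
    "fit_ggm",
    "extract_network",
    "node_type_counts",
    "split_by_lipid_class",
    "hypergeom_enrich",
]


@dataclass
class GGMResult:
    variables: list[str]
    node_types: dict[str, str]
    lam: float
    pcor: np.ndarray
    kappa: float
    edges: pd.DataFrame = field(default_factory=pd.DataFrame)


def shrink_correlation(data) -> tuple[np.ndarray, float]:
    """Identity-target shrinkage estimate of the correlation matrix.

    ``data`` is samples x variables.  Returns (R*, lambda) with
    R* = lambda I + (1 - lambda) R and the closed-form optimal lambda
    computed from the unbiased variance estimates of the sample
    correlations: Var-hat(r_ij) = n / (n-1)^3 * sum_k (w_kij - wbar)^2
    with w_kij the products of the centred, sd-scaled data.
    """
    X = np.asarray(data, dtype=float)
    n, p = X.shape
    if n < 3:
        raise PipelineError("need at least 3 samples")
    sd = X.std(axis=0, ddof=1)
    if (sd == 0).any():
        j = int(np.argmax(sd == 0))
        raise PipelineError(f"constant variable at column {j}")
    Z = (X - X.mean(axis=0)) / sd
    R = Z.T @ Z / (n - 1)
    np.fill_diagonal(R, 1.0)

    # Var-hat(r_ij) without materialising the n x p x p product tensor:
    # sum_k w^2 = (Z^2)' (Z^2), sum_k w = (n-1) R
    W2 = (Z ** 2).T @ (Z ** 2)
    var_r = n / (n - 1.0) ** 3 * (W2 - ((n - 1.0) * R) ** 2 / n)
    off = ~np.eye(p, dtype=bool)
    denom = float((R[off] ** 2).sum())
    num = float(var_r[off].sum())
    lam = 1.0 if denom == 0 else min(1.0, max(0.0, num / denom))
    R_star = lam * np.eye(p) + (1.0 - lam) * R
    return R_star, lam


def partial_correlations(R_star: np.ndarray) -> np.ndarray:
    """Full-order partial correlations from a positive definite matrix."""
    R_star = np.asarray(R_star, dtype=float)
    try:
        np.linalg.cholesky(R_star)
    except np.linalg.LinAlgError as exc:
        raise PipelineError("matrix is not positive definite") from exc
    omega = np.linalg.inv(R_star)
    d = np.sqrt(np.diag(omega))
    pcor = -omega / np.outer(d, d)
    np.fill_diagonal(pcor, 1.0)
    return pcor


def _offdiag_pairs(p: int):
    iu = np.triu_indices(p, k=1)
    return iu


def fit_null_kappa(pcor_values: np.ndarray, eta0: float = 0.9) -> float:
    """Maximum-likelihood kappa of the null density (1-r^2)^((kappa-3)/2).

    Only the central bulk (|r| at or below the eta0 quantile of |r|) is
    treated as null.  Under this family r^2 ~ Beta(1/2, (kappa-1)/2),
    so the normaliser is the Beta function B(1/2, (kappa-1)/2).
    """
    r = np.asarray(pcor_values, dtype=float)
    cut = np.quantile(np.abs(r), eta0)
    bulk = r[np.abs(r) <= cut]
    bulk = bulk[np.abs(bulk) < 1.0 - 1e-12]
    if bulk.size < 5:
        raise PipelineError("too few null partial correlations to fit kappa")
    log1mr2 = np.log1p(-bulk ** 2)

    def nll(kappa: float) -> float:
        return -(
            (kappa - 3.0) / 2.0 * log1mr2.sum()
            - bulk.size * (special.betaln(0.5, (kappa - 1.0) / 2.0))
        )

    res = optimize.minimize_scalar(nll, bounds=(3.0 + 1e-6, 1e7), method="bounded")
    return float(res.x)


def null_pvalues(pcor_values, kappa: float) -> np.ndarray:
    """Two-sided p-values under the null density (1-r^2)^((kappa-3)/2).

    Under this family r^2 ~ Beta(1/2, (kappa-1)/2), so
    P(|R| >= |r|) is the corresponding Beta survival function; kappa = 3
    is the uniform null, where P(|R| >= r) = 1 - |r|.
    """
    r = np.asarray(pcor_values, dtype=float)
    return stats.beta.sf(r ** 2, 0.5, (kappa - 1.0) / 2.0)


def edge_significance(
    pcor: np.ndarray,
    n_effective: float | None = None,
    eta0: float = 0.9,
    variables: list[str] | None = None,
) -> tuple[pd.DataFrame, float]:
    """Two-sided p and BH q for every off-diagonal partial correlation.

    The null treats |pcor|^2 as Beta(1/2, (kappa-1)/2); kappa is fitted
    from the central bulk of the observed values.  When the fit lands on
    the kappa <= 3 boundary, the fallback kappa = n_effective - p + 1
    (floored at 4) is used with a warning.
    """
    pcor = np.asarray(pcor, dtype=float)
    p_vars = pcor.shape[0]
    iu = _offdiag_pairs(p_vars)
    r = pcor[iu]
    kappa = fit_null_kappa(r, eta0)
    if kappa <= 3.0 + 1e-4:
        fallback = 4.0
        if n_effective is not None:
            fallback = max(4.0, float(n_effective) - p_vars + 1.0)
        warnings.warn(
            f"kappa estimate at boundary ({kappa:.3f}); falling back to {fallback:.1f}"
        )
        kappa = fallback
    pvals = null_pvalues(r, kappa)
    qvals = bh_adjust(pvals)
    names = variables if variables is not None else list(range(p_vars))
    edges = pd.DataFrame({
        "source": np.asarray(names, dtype=object)[iu[0]],
        "target": np.asarray(names, dtype=object)[iu[1]],
        "pcor": r,
        "p": pvals,
        "q": qvals,
    })
    return edges, kappa


def fit_ggm(
    data: pd.DataFrame,
    node_types: dict[str, str],
    eta0: float = 0.9,
) -> GGMResult:
    """Shrinkage GGM over a variables x observations table.

    ``data`` rows are variables (lipids and transcripts), columns are
    paired observations; ``node_types`` maps each variable to lipid /
    pathway_gene / transcript.
    """
    names = list(data.index)
    X = data.to_numpy(dtype=float).T  # samples x variables
    R_star, lam = shrink_correlation(X)
    pcor = partial_correlations(R_star)
    edges, kappa = edge_significance(pcor, n_effective=X.shape[0], eta0=eta0,
                                     variables=names)
    return GGMResult(names, dict(node_types), lam, pcor, kappa, edges)


def extract_network(
    edges: pd.DataFrame,
    q_max: float = 1e-12,
    node_types: dict[str, str] | None = None,
    lipid_classes: dict[str, str] | None = None,
    keep_nodes: list[str] | None = None,
) -> nx.Graph:
    """Threshold edges at q < q_max into an undirected typed graph."""
    g = nx.Graph()
    node_types = node_types or {}
    lipid_classes = lipid_classes or {}
    for node in keep_nodes or []:
        g.add_node(node)
    kept = edges[edges["q"] < q_max]
    for row in kept.itertuples(index=False):
        g.add_edge(row.source, row.target, pcor=float(row.pcor),
                   p=float(row.p), q=float(row.q))
    for node in g.nodes:
        g.nodes[node]["node_type"] = node_types.get(node, "transcript")
        if node in lipid_classes:
            g.nodes[node]["lipid_class"] = lipid_classes[node]
    return g


def node_type_counts(network: nx.Graph) -> dict[str, int]:
    counts: dict[str, int] = {}
    for _, data in network.nodes(data=True):
        t = data.get("node_type", "transcript")
        counts[t] = counts.get(t, 0) + 1
    return dict(sorted(counts.items()))


def split_by_lipid_class(
    network: nx.Graph, class_a: set[str], class_b: set[str]
) -> tuple[set[str], set[str], set[str]]:
    """Split genes by adjacency to two lipid-class groups.

    Returns (genes adjacent only to class-a lipids, only to class-b,
    adjacent to both); classes within each group are unioned.
    """
    def lipids_of(classes: set[str]) -> set[str]:
        return {
            n for n, d in network.nodes(data=True)
            if d.get("node_type") == "lipid" and d.get("lipid_class") in classes
        }

    la, lb = lipids_of(class_a), lipids_of(class_b)
    if not la:
        warnings.warn(f"no lipid nodes with class in {sorted(class_a)}")
    if not lb:
        warnings.warn(f"no lipid nodes with class in {sorted(class_b)}")

    def neighbours(lipids: set[str]) -> set[str]:
        out: set[str] = set()
        for lip in lipids:
            out |= {
                n for n in network.neighbors(lip)
                if network.nodes[n].get("node_type") != "lipid"
            }
        return out

    na, nb = neighbours(la), neighbours(lb)
    return na - nb, nb - na, na & nb


def hypergeom_enrich(
    query, collection: GeneSetCollection, universe
) -> pd.DataFrame:
    """One-sided hypergeometric enrichment of a gene list against sets.

    For each term with K universe members and overlap k with the
    n-gene query drawn from an N-gene universe, p = P(X >= k) under
    Hypergeometric(N, K, n); BH adjustment across terms; rows sorted by
    ascending p.
    """
    query = {g.upper() for g in query}
    universe = {g.upper() for g in universe}
    if not query:
        raise PipelineError("empty query gene set")
    if not query <= universe:
        raise PipelineError("query genes must be a subset of the universe")
    N, n = len(universe), len(query)
    rows = []
    for term, (_, genes) in collection.sets.items():
        members = set(genes) & universe
        if not members:
            continue
        K = len(members)
        overlap = sorted(members & query)
        k = len(overlap)
        p = float(stats.hypergeom.sf(k - 1, N, K, n)) if k > 0 else 1.0
        rows.append((term, k, K, n, N, min(p, 1.0), ";".join(overlap)))
    out = pd.DataFrame(
        rows, columns=["term", "overlap", "term_size", "query_size",
                       "universe_size", "p_value", "overlapping_genes"],
    )
    if len(out):
        out["p_adjusted"] = bh_adjust(out["p_value"].to_numpy())
        out = out.sort_values(["p_value", "term"], kind="stable").reset_index(drop=True)
    else:
        out["p_adjusted"] = []
    return out[["term", "overlap", "term_size", "query_size", "universe_size",
                "p_value", "p_adjusted", "overlapping_genes"]]
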