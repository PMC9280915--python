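"""Shrinkage GGM estimation, edge significance, network ops and enrichment."""

import networkx as nx
import numpy as np
import pytest
from scipy.special import comb

from lipidyn.io import GeneSetCollection, PipelineError
from lipidyn.network import (
    edge_significance,
    extract_network,
    fit_ggm,
    fit_null_kappa,
    hypergeom_enrich,
    node_type_counts,
    null_pvalues,
    partial_correlations,
    shrink_correlation,
    split_by_lipid_class,
)


# --- shrinkage -------------------------------------------------------------

def test_lambda_zero_in_zero_variance_of_r_limit():
    # duplicated balanced +-1 pattern: r = 1 and every per-sample product
    # equals the mean, so the variance estimate of r vanishes -> lambda 0
    x = np.array([1.0, -1.0, 1.0, -1.0, 1.0, -1.0])
    X = np.column_stack([x, x])
    R, lam = shrink_correlation(X)
    assert lam == pytest.approx(0.0, abs=1e-12)
    assert R[0, 1] == pytest.approx(1.0)


def test_lambda_clipped_to_identity_when_correlations_vanish():
    # exactly orthogonal balanced designs: sum r^2 = 0, so the optimal
    # lambda formula blows up and is clipped to 1 -> R* is the identity
    X = np.array([[1, 1], [1, -1], [-1, 1], [-1, -1]], dtype=float)
    R, lam = shrink_correlation(X)
    assert lam == 1.0
    np.testing.assert_allclose(R, np.eye(2))


def test_lambda_in_unit_interval_and_eigenvalue_floor(rng):
    for _ in range(10):
        X = rng.standard_normal((8, 12))
        R, lam = shrink_correlation(X)
        assert 0.0 <= lam <= 1.0
        assert np.linalg.eigvalsh(R).min() >= lam - 1e-10


def test_constant_variable_rejected(rng):
    X = rng.standard_normal((10, 3))
    X[:, 1] = 2.0
    with pytest.raises(PipelineError, match="column 1"):
        shrink_correlation(X)


# --- partial correlations --------------------------------------------------

def test_pcor_worked_cases():
    R = np.full((3, 3), 0.5)
    np.fill_diagonal(R, 1.0)
    pc = partial_correlations(R)
    off = pc[~np.eye(3, dtype=bool)]
    np.testing.assert_allclose(off, 1 / 3)
    np.testing.assert_allclose(partial_correlations(np.eye(4)), np.eye(4))
    R2 = np.array([[1.0, 0.37], [0.37, 1.0]])
    assert partial_correlations(R2)[0, 1] == pytest.approx(0.37)


def test_pcor_requires_positive_definite():
    R = np.array([[1.0, 1.1], [1.1, 1.0]])
    with pytest.raises(PipelineError):
        partial_correlations(R)


def test_pcor_support_recovery_tightens_with_n():
    """Population-zero partial correlations shrink toward 0 as n grows."""
    rng = np.random.default_rng(3)
    omega = np.eye(6)
    omega[0, 1] = omega[1, 0] = 0.4
    omega[2, 3] = omega[3, 2] = -0.4
    sigma = np.linalg.inv(omega)
    null_pairs = [(0, 2), (0, 3), (1, 4), (4, 5), (2, 5)]
    maxes = []
    for n in (200, 2000):
        X = rng.multivariate_normal(np.zeros(6), sigma, size=n)
        R, _ = shrink_correlation(X)
        pc = partial_correlations(R)
        maxes.append(max(abs(pc[i, j]) for i, j in null_pairs))
        assert abs(pc[0, 1]) > 0.25 and abs(pc[2, 3]) > 0.25
    assert maxes[1] < maxes[0] < 0.2


# --- edge significance -----------------------------------------------------

def test_null_pvalue_worked_cases():
    assert null_pvalues(0.0, kappa=10.0) == pytest.approx(1.0)
    # kappa = 3 is the uniform null: P(|R| >= 0.5) = 0.5
    assert null_pvalues(0.5, kappa=3.0) == pytest.approx(0.5)


def test_kappa_mle_recovers_generating_value(rng):
    kappa = 40.0
    r2 = rng.beta(0.5, (kappa - 1) / 2, size=20000)
    r = np.sqrt(r2) * rng.choice([-1, 1], size=20000)
    est = fit_null_kappa(r, eta0=1.0)
    assert est == pytest.approx(kappa, rel=0.1)


def test_edge_significance_table(rng):
    p = 8
    pc = np.eye(p)
    iu = np.triu_indices(p, 1)
    pc[iu] = rng.uniform(-0.3, 0.3, size=len(iu[0]))
    pc = pc + pc.T - np.diag(np.diag(pc))
    edges, kappa = edge_significance(pc, n_effective=30,
                                     variables=[f"v{i}" for i in range(p)])
    assert len(edges) == p * (p - 1) // 2
    assert (edges["q"] >= edges["p"] - 1e-15).all()
    assert kappa > 3


# --- network extraction / splitting ---------------------------------------

def _edges_df(rows):
    import pandas as pd
    return pd.DataFrame(rows, columns=["source", "target", "pcor", "p", "q"])


def test_extract_network_thresholds_and_counts():
    edges = _edges_df([
        ("Gb3_1", "g1", 0.5, 1e-20, 1e-16),
        ("CE_1", "g2", -0.4, 1e-15, 1e-11),
        ("g1", "g2", 0.2, 0.01, 0.05),
    ])
    types = {"Gb3_1": "lipid", "CE_1": "lipid", "g1": "pathway_gene", "g2": "transcript"}
    classes = {"Gb3_1": "Gb3", "CE_1": "CE"}
    net = extract_network(edges, q_max=1e-12, node_types=types, lipid_classes=classes)
    assert net.number_of_edges() == 1
    assert node_type_counts(net) == {"lipid": 1, "pathway_gene": 1}
    empty = extract_network(edges, q_max=1e-30)
    assert empty.number_of_edges() == 0


def test_split_by_lipid_class_set_logic():
    net = nx.Graph()
    for n, t, c in [("gb3", "lipid", "Gb3"), ("gb4", "lipid", "Gb4"),
                    ("ce", "lipid", "CE")]:
        net.add_node(n, node_type="lipid", lipid_class=c)
    for g in ["g1", "g2", "g3", "g4"]:
        net.add_node(g, node_type="transcript")
    net.add_edge("gb3", "g1")
    net.add_edge("ce", "g2")
    net.add_edge("gb3", "g3"); net.add_edge("ce", "g3")
    net.add_edge("gb3", "g4"); net.add_edge("gb4", "g4")  # classes unioned
    a, b, shared = split_by_lipid_class(net, {"Gb3", "Gb4"}, {"CE"})
    assert a == {"g1", "g4"} and b == {"g2"} and shared == {"g3"}
    with pytest.warns(UserWarning, match="no lipid nodes"):
        split_by_lipid_class(net, {"SM"}, {"CE"})
    empty_a, empty_b, empty_s = split_by_lipid_class(nx.Graph(), {"Gb3"}, {"CE"})
    assert empty_a == empty_b == empty_s == set()


# --- enrichment ------------------------------------------------------------

def test_hypergeom_worked_values():
    universe = [f"G{i}" for i in range(20)]
    coll = GeneSetCollection({
        "FULL": ("all five", universe[:5]),
        "MISS": ("disjoint", universe[10:15]),
    })
    res = hypergeom_enrich(universe[:5], coll, universe).set_index("term")
    assert res.loc["FULL", "p_value"] == pytest.approx(1 / comb(20, 5, exact=True))
    assert res.loc["MISS", "p_value"] == 1.0  # k = 0

    uni10 = [f"G{i}" for i in range(10)]
    coll2 = GeneSetCollection({"HALF": ("five of ten", uni10[:5])})
    res2 = hypergeom_enrich([uni10[0], uni10[9]], coll2, uni10)  # k = 1 of 2
    assert res2["p_value"].iloc[0] == pytest.approx(7 / 9)


def test_hypergeom_contracts():
    coll = GeneSetCollection({"T": ("d", ["A", "B"])})
    with pytest.raises(PipelineError, match="empty"):
        hypergeom_enrich([], coll, ["A", "B"])
    with pytest.raises(PipelineError, match="subset"):
        hypergeom_enrich(["Z"], coll, ["A", "B"])


def test_fit_ggm_end_to_end_small(rng):
    import pandas as pd
    x = rng.standard_normal(30)
    data = pd.DataFrame({
        "lip": x,
        "gene": 0.9 * x + 0.3 * rng.standard_normal(30),
        "noise1": rng.standard_normal(30),
        "noise2": rng.standard_normal(30),
        "noise3": rng.standard_normal(30),
    }).T
    res = fit_ggm(data, {"lip": "lipid", "gene": "pathway_gene"})
    best = res.edges.sort_values("p").iloc[0]
    assert {best.source, best.target} == {"lip", "gene"}
    assert 0 <= res.lam <= 1
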