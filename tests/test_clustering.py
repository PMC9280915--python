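"""DP-GP trajectory clustering, VI comparison and cluster ordering."""

import numpy as np
import pandas as pd
import pytest

from lipidyn.clustering import (
    ClusterPosterior,
    ClusteringRun,
    GPSpec,
    cluster_posterior,
    fit_dpgp_run,
    order_clusters,
    select_noise_variance,
    select_representative_run,
    symmetric_kl_mvn,
    trajectories_from_matrix,
    vi_distance,
)
from lipidyn.io import PipelineError

from conftest import make_matrix

GRID5 = np.array([2.0, 2.707, 3.732, 4.828, 6.0])


def _two_shape_data(n_per=20, n_donors=3, noise=0.0, seed=0):
    rng = np.random.default_rng(seed)
    shapes = np.array([[1, 0.5, 0, -0.5, -1.0], [-1, -0.5, 0, 0.5, 1.0]])
    arr = np.empty((2 * n_per, n_donors, 5))
    labels = np.repeat([0, 1], n_per)
    for i, lab in enumerate(labels):
        arr[i] = shapes[lab] + noise * rng.standard_normal((n_donors, 5))
    return arr, labels


# --- sampler ---------------------------------------------------------------

def test_two_separated_shapes_recovered_exactly():
    from sklearn.metrics import adjusted_rand_score
    arr, truth = _two_shape_data(noise=0.05)
    spec = GPSpec(GRID5, noise_variance=0.05)
    run = fit_dpgp_run(arr, spec, alpha=1e-3, seed=1, n_sweeps=20)
    assert adjusted_rand_score(truth, run.labels) == 1.0


def test_identical_lipids_form_single_confident_cluster():
    arr = np.tile(np.array([0.0, 0.5, 1.0, 0.5, 0.0]), (15, 3, 1))
    arr += 1e-3 * np.random.default_rng(0).standard_normal(arr.shape)
    run = fit_dpgp_run(arr, GPSpec(GRID5, noise_variance=0.1), 1e-3, seed=2, n_sweeps=20)
    assert run.labels.nunique() == 1
    assert (run.membership_prob.max(axis=1) >= 0.99).all()


def test_fixed_seed_reproducible_and_membership_consistent():
    arr, _ = _two_shape_data(noise=0.3, seed=3)
    spec = GPSpec(GRID5, noise_variance=0.2)
    r1 = fit_dpgp_run(arr, spec, 1e-2, seed=7, n_sweeps=20)
    r2 = fit_dpgp_run(arr, spec, 1e-2, seed=7, n_sweeps=20)
    pd.testing.assert_series_equal(r1.labels, r2.labels)
    np.testing.assert_allclose(r1.membership_prob.to_numpy(),
                               r2.membership_prob.to_numpy())
    # labels are the argmax of the membership rows
    assert (r1.membership_prob.idxmax(axis=1) == r1.labels).all()
    np.testing.assert_allclose(r1.membership_prob.sum(axis=1), 1.0)


def test_sampler_contracts():
    arr, _ = _two_shape_data()
    with pytest.raises(PipelineError, match="sweeps"):
        fit_dpgp_run(arr, GPSpec(GRID5), 1e-3, 0, n_sweeps=5)
    bad = arr.copy()
    bad[0, 0, 0] = np.nan
    with pytest.raises(PipelineError, match="finite"):
        fit_dpgp_run(bad, GPSpec(GRID5), 1e-3, 0, n_sweeps=20)


def test_exchangeability_under_lipid_permutation():
    arr, _ = _two_shape_data(noise=0.3, seed=5)
    spec = GPSpec(GRID5, noise_variance=0.2)
    base = fit_dpgp_run(arr, spec, 1e-2, seed=9, n_sweeps=30)
    perm = np.random.default_rng(1).permutation(arr.shape[0])
    permuted = fit_dpgp_run(arr[perm], spec, 1e-2, seed=9, n_sweeps=30)
    assert vi_distance(base.labels.to_numpy()[perm], permuted.labels.to_numpy()) == 0.0


def test_noise_variance_moment_estimator():
    rng = np.random.default_rng(2)
    arr = np.zeros((40, 8, 5)) + 0.5 * rng.standard_normal((40, 8, 5))
    est = select_noise_variance(arr)
    assert est == pytest.approx(0.25, rel=0.1)


# --- cluster posterior -----------------------------------------------------

def _identity_spec(sn2=1.0):
    # near-delta kernel: lengthscale so short the grid points decouple
    return GPSpec(GRID5, lengthscale=1e-3, signal_variance=1.0, noise_variance=sn2)


def test_posterior_identity_kernel_single_member():
    y = np.array([1.0, -2.0, 0.5, 3.0, -1.0])
    post = cluster_posterior(y[None, :], _identity_spec(1.0))
    np.testing.assert_allclose(post.mean, y / 2, atol=1e-6)
    np.testing.assert_allclose(post.covariance, np.eye(5) / 2, atol=1e-6)


def test_posterior_limits():
    y = np.array([1.0, -2.0, 0.5, 3.0, -1.0])
    tight = cluster_posterior(y[None, :], _identity_spec(1e-8))
    np.testing.assert_allclose(tight.mean, y, atol=1e-5)
    assert np.abs(tight.covariance).max() < 1e-6
    many = cluster_posterior(np.tile(y, (5000, 1)), _identity_spec(1.0))
    np.testing.assert_allclose(many.mean, y, atol=1e-3)


# --- VI --------------------------------------------------------------------

def test_vi_worked_values():
    assert vi_distance([1, 1, 2], [1, 1, 2]) == 0.0
    assert vi_distance([1, 1, 2], [1, 2, 2]) == pytest.approx(0.9242, abs=1e-4)
    n = 17
    assert vi_distance(range(n), [0] * n) == pytest.approx(np.log(n))


def test_vi_contract():
    with pytest.raises(PipelineError):
        vi_distance([1, 2], [1, 2, 3])


# --- run selection ---------------------------------------------------------

def _mk_run(labels, alpha, seed):
    labels = pd.Series(labels)
    prob = pd.get_dummies(labels).astype(float)
    return ClusteringRun(alpha, seed, labels, prob, 20)


def test_select_representative_prefers_consensus():
    a = [0, 0, 1, 1, 2, 2]
    b = [0, 1, 1, 0, 2, 2]
    runs = [_mk_run(a, 0.01, 1), _mk_run(a, 0.01, 2), _mk_run(b, 0.01, 3)]
    best = select_representative_run(runs)
    assert best.seed in (1, 2)


def test_select_representative_across_alpha_groups_and_ties():
    cons = [0, 0, 1, 1]
    messy1 = [0, 1, 0, 1]
    messy2 = [0, 1, 1, 0]
    runs = [
        _mk_run(cons, 0.1, 5), _mk_run(cons, 0.1, 6),
        _mk_run(messy1, 0.01, 1), _mk_run(messy2, 0.01, 2),
    ]
    assert select_representative_run(runs).alpha == 0.1
    # all identical: tie broken by (alpha, seed)
    runs = [_mk_run(cons, 0.1, 9), _mk_run(cons, 0.1, 3),
            _mk_run(cons, 0.01, 8), _mk_run(cons, 0.01, 4)]
    best = select_representative_run(runs)
    assert (best.alpha, best.seed) == (0.01, 4)
    with pytest.raises(PipelineError):
        select_representative_run([])


# --- symmetric KL ----------------------------------------------------------

def _g(mu, var):
    mu = np.atleast_1d(np.asarray(mu, float))
    cov = np.atleast_2d(np.asarray(var, float))
    return ClusterPosterior(mu, cov, 1)


def test_symmetric_kl_worked_values():
    assert symmetric_kl_mvn(_g(0, 1), _g(0, 1)) == 0.0
    assert symmetric_kl_mvn(_g(0, 1), _g(1, 1)) == pytest.approx(1.0)
    # variance-only case: the log-determinant terms cancel
    assert symmetric_kl_mvn(_g(0, 1), _g(0, 2)) == pytest.approx(0.25)
    with pytest.raises(PipelineError):
        symmetric_kl_mvn(_g([0, 0], np.eye(2)), _g(0, 1))


def test_symmetric_kl_nonnegative_random(rng):
    for _ in range(20):
        A = rng.standard_normal((4, 4))
        B = rng.standard_normal((4, 4))
        a = _g(rng.standard_normal(4), A @ A.T + 0.1 * np.eye(4))
        b = _g(rng.standard_normal(4), B @ B.T + 0.1 * np.eye(4))
        assert symmetric_kl_mvn(a, b) >= 0.0
        assert symmetric_kl_mvn(a, b) == pytest.approx(symmetric_kl_mvn(b, a))


# --- ordering --------------------------------------------------------------

def test_order_clusters_noise_rule_and_grouping():
    posts = {}
    # two tight pairs: clusters 0,1 near mean 0; clusters 2,3 near mean 5
    for cid, (mu, n) in enumerate([(0.0, 12), (0.2, 15), (5.0, 20), (5.2, 11)]):
        posts[cid] = ClusterPosterior(np.full(3, mu), np.eye(3) * 0.1, n)
    posts[4] = ClusterPosterior(np.zeros(3), np.eye(3), 9)  # < 10 lipids: noise
    major, order, noise = order_clusters(posts, min_size=10)
    assert noise == [4]
    assert set(major) == {0, 1, 2, 3}
    pos = {c: i for i, c in enumerate(order)}
    assert abs(pos[0] - pos[1]) == 1 and abs(pos[2] - pos[3]) == 1


def test_order_single_major_cluster():
    posts = {7: ClusterPosterior(np.zeros(3), np.eye(3), 30)}
    major, order, noise = order_clusters(posts, min_size=10)
    assert order == [7] and noise == []


# --- matrix reshaping ------------------------------------------------------

def test_trajectories_from_matrix_shapes_and_missing(rng):
    m = make_matrix(rng.normal(0, 1, (4, 10)), donors=("A", "B"),
                    times=(0, 0.5, 3, 8, 16), transform_state="zscore")
    arr, grid, ids, times = trajectories_from_matrix(m)
    assert arr.shape == (4, 2, 5)
    np.testing.assert_allclose(grid, np.sqrt([0, 0.5, 3, 8, 16]) + 2)
    incomplete = make_matrix(rng.normal(0, 1, (2, 9)), donors=("A", "B"),
                             times=(0, 0.5, 3, 8, 16), transform_state="zscore")
    incomplete.values = incomplete.values.iloc[:, :-1]
    incomplete.samples = incomplete.samples.iloc[:-1]
    with pytest.raises(PipelineError, match="missing time point"):
        trajectories_from_matrix(incomplete)
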