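"""Trajectory clustering with a Dirichlet-process mixture of Gaussian processes.

Model: each cluster has a latent mean function f_c ~ GP(0, K) evaluated on
the transformed time grid (sqrt(t) + 2, squared-exponential kernel with
lengthscale 6 and unit signal variance by default); each member lipid
contributes its per-donor trajectories as conditionally independent
replicates f_c + N(0, sigma_n^2 I).  Cluster assignments follow a Chinese
restaurant process with concentration alpha and are sampled by collapsed
Gibbs, where the marginal likelihood of a trajectory set is available in
closed form on the T-point grid.

Several runs (seeds x alpha values) are compared with the variation of
information (VI) distance between their partitions, and the run with the
smallest mean VI to the other runs of its alpha group is selected.
Cluster Gaussian posteriors are then compared by symmetric
Kullback-Leibler divergence and ordered by complete-linkage hierarchical
clustering; clusters below the minimum size (default 10 lipids) are set
aside as noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .io import AbundanceMatrix, PipelineError
from .preprocess import transform_time

__all__ = [
    "GPSpec",
    "ClusteringRun",
    "ClusterPosterior",
    "ClusterSet",
    "trajectories_from_matrix",
    "select_noise_variance",
    "fit_dpgp_run",
    "fit_dpgp_schedule",
    "cluster_posterior",
    "vi_distance",
    "select_representative_run",
    "symmetric_kl_mvn",
    "order_clusters",
    "cluster_trajectories",
]

DEFAULT_ALPHAS = (1e-5, 1e-4, 1e-3, 1e-2, 1e-1)


@dataclass
class GPSpec:
    """Squared-exponential GP on the transformed time grid."""

    time_grid: np.ndarray            # transformed times, strictly increasing
    lengthscale: float = 6.0
    signal_variance: float = 1.0
    noise_variance: float = 0.25

    def __post_init__(self) -> None:
        self.time_grid = np.asarray(self.time_grid, dtype=float)
        if self.lengthscale <= 0 or self.signal_variance <= 0 or self.noise_variance <= 0:
            raise PipelineError("GP hyperparameters must be positive")
        if np.unique(self.time_grid).size != self.time_grid.size:
            raise PipelineError("duplicated grid points")

    def kernel(self) -> np.ndarray:
        d = self.time_grid[:, None] - self.time_grid[None, :]
        K = self.signal_variance * np.exp(-0.5 * (d / self.lengthscale) ** 2)
        return K + 1e-8 * np.eye(len(self.time_grid))


@dataclass
class ClusteringRun:
    alpha: float
    seed: int
    labels: pd.Series                 # lipid -> cluster id (MAP over sweeps)
    membership_prob: pd.DataFrame     # lipids x cluster ids, rows sum to 1
    n_sweeps: int
    log_likelihood: float = np.nan


@dataclass
class ClusterPosterior:
    mean: np.ndarray
    covariance: np.ndarray
    member_count: int


@dataclass
class ClusterSet:
    run: ClusteringRun
    posteriors: dict[int, ClusterPosterior]
    major_clusters: list[int]
    display_order: list[int]
    noise_clusters: list[int]
    labels: pd.Series = field(default_factory=pd.Series)


# ---------------------------------------------------------------------------
# data shaping
# ---------------------------------------------------------------------------

def trajectories_from_matrix(matrix: AbundanceMatrix):
    """Reshape a (residual/z-scored) matrix into per-donor trajectories.

    Returns (array of shape lipids x donors x timepoints, transformed
    grid, lipid ids, time points in hours).  Every donor must be
    observed at every time point.
    """
    bio = matrix.biological()
    samples = bio.samples
    times = np.array(sorted(samples["time_hours"].unique()), dtype=float)
    donors = sorted(samples["donor_id"].unique())
    lookup = {}
    for sid, row in samples.iterrows():
        lookup[(row["donor_id"], float(row["time_hours"]))] = sid
    cols = []
    for d in donors:
        for t in times:
            key = (d, t)
            if key not in lookup:
                raise PipelineError(f"donor {d!r} missing time point {t}")
            cols.append(lookup[key])
    arr = bio.values[cols].to_numpy(dtype=float)
    L = arr.shape[0]
    arr = arr.reshape(L, len(donors), len(times))
    if not np.isfinite(arr).all():
        raise PipelineError("non-finite values in trajectories")
    return arr, transform_time(times), list(bio.values.index), times


# ---------------------------------------------------------------------------
# marginal likelihood machinery
# ---------------------------------------------------------------------------

class _Evidence:
    """Closed-form log evidence of replicate trajectory sets under the GP.

    Works in the eigenbasis of the kernel so that per-set evidence is a
    few vector operations: with K = V diag(w) V', a set of m trajectories
    with projected sum s = V' sum_j y_j and sum of squares Q has

        log p = -(mT/2) log(2 pi sn2) - Q/(2 sn2)
                - 1/2 sum log w - 1/2 sum log(1/w + m/sn2)
                + 1/(2 sn2^2) sum s^2 / (1/w + m/sn2)
    """

    def __init__(self, spec: GPSpec):
        K = spec.kernel()
        w, V = np.linalg.eigh(K)
        self.w = np.maximum(w, 1e-12)
        self.V = V
        self.sn2 = spec.noise_variance
        self.T = K.shape[0]
        self.logdet_w = float(np.log(self.w).sum())

    def project(self, S: np.ndarray) -> np.ndarray:
        """Project trajectory sums onto the kernel eigenbasis."""
        return S @ self.V

    def logev(self, m, s_proj, Q):
        """Vectorized over leading axis: m (C,), s_proj (C,T), Q (C,)."""
        m = np.asarray(m, dtype=float)
        denom = 1.0 / self.w[None, :] + m[..., None] / self.sn2
        quad = (s_proj ** 2 / denom).sum(axis=-1) / self.sn2 ** 2
        return (
            -0.5 * m * self.T * np.log(2 * np.pi * self.sn2)
            - np.asarray(Q) / (2 * self.sn2)
            - 0.5 * self.logdet_w
            - 0.5 * np.log(denom).sum(axis=-1)
            + 0.5 * quad
        )


def select_noise_variance(arr: np.ndarray, spec: GPSpec | None = None) -> float:
    """Replicate-moment estimate of the trajectory noise variance.

    In the mixture model every donor trajectory of a lipid is the
    lipid's mean function plus iid noise, so the dispersion of the
    donor trajectories around each lipid's own mean trajectory is a
    direct estimate of sigma_n^2 that does not depend on the smoothness
    of the GP prior:  sum of squared deviations / (L * (D - 1) * T).
    """
    L, D, T = arr.shape
    if D < 2:
        raise PipelineError("need >=2 donors to estimate noise variance")
    resid = arr - arr.mean(axis=1, keepdims=True)
    sn2 = float((resid ** 2).sum() / (L * (D - 1) * T))
    return max(sn2, 1e-6)


# ---------------------------------------------------------------------------
# collapsed Gibbs sampler
# ---------------------------------------------------------------------------

def fit_dpgp_run(
    arr: np.ndarray,
    spec: GPSpec,
    alpha: float,
    seed: int,
    n_sweeps: int = 60,
    lipid_ids: list | None = None,
) -> ClusteringRun:
    """One collapsed Gibbs run of the DP-GP mixture.

    ``arr`` has shape (lipids, donors, timepoints) of donor-adjusted,
    z-scored trajectories.  Membership probabilities are assignment
    frequencies over the last half of sweeps; labels are the most
    frequent (MAP) cluster per lipid.  Fixed seeds give identical runs.
    """
    if n_sweeps < 10:
        raise PipelineError("n_sweeps must be >= 10")
    if not np.isfinite(arr).all():
        raise PipelineError("non-finite values")
    L, D, T = arr.shape
    if lipid_ids is None:
        lipid_ids = list(range(L))
    rng = np.random.default_rng(seed)
    ev = _Evidence(spec)

    d_i = np.full(L, float(D))
    S_i = ev.project(arr.sum(axis=1))           # (L, T)
    Q_i = (arr ** 2).sum(axis=(1, 2))           # (L,)
    self_ev = ev.logev(d_i, S_i, Q_i)           # evidence of each lipid alone

    # cluster state, persistent integer ids
    ids: list[int] = []
    m = np.zeros(0)          # replicate counts per cluster
    S = np.zeros((0, T))     # projected trajectory sums per cluster
    Q = np.zeros(0)
    n_lip = np.zeros(0)      # lipid counts per cluster
    base_ev = np.zeros(0)    # cached logev of each cluster's current members
    assign = np.full(L, -1)  # index into cluster arrays, per lipid
    next_id = 0
    log_alpha = np.log(alpha)

    def add_cluster(i: int) -> None:
        nonlocal m, S, Q, n_lip, base_ev, next_id
        ids.append(next_id)
        next_id += 1
        m = np.append(m, d_i[i])
        S = np.vstack([S, S_i[i][None, :]])
        Q = np.append(Q, Q_i[i])
        n_lip = np.append(n_lip, 1)
        base_ev = np.append(base_ev, self_ev[i])
        assign[i] = len(ids) - 1

    def join(i: int, c: int, joint_ev: float) -> None:
        m[c] += d_i[i]
        S[c] += S_i[i]
        Q[c] += Q_i[i]
        n_lip[c] += 1
        base_ev[c] = joint_ev
        assign[i] = c

    def remove(i: int) -> None:
        nonlocal m, S, Q, n_lip, base_ev, assign
        c = assign[i]
        n_lip[c] -= 1
        if n_lip[c] == 0:
            keep = np.arange(len(ids)) != c
            del ids[c]
            m, Q, n_lip, base_ev = m[keep], Q[keep], n_lip[keep], base_ev[keep]
            S = S[keep]
            assign[assign > c] -= 1
        else:
            m[c] -= d_i[i]
            S[c] -= S_i[i]
            Q[c] -= Q_i[i]
            base_ev[c] = float(ev.logev(m[c:c + 1], S[c:c + 1], Q[c:c + 1])[0])
        assign[i] = -1

    def gibbs_choice(i: int):
        """Sample a cluster index (or -1 for new) for lipid i."""
        if len(ids) == 0:
            return -1, None
        joint = ev.logev(m + d_i[i], S + S_i[i][None, :], Q + Q_i[i])
        logw = np.append(np.log(n_lip) + joint - base_ev,
                         log_alpha + self_ev[i])
        logw -= logw.max()
        wts = np.exp(logw)
        wts /= wts.sum()
        k = rng.choice(len(wts), p=wts)
        if k == len(ids):
            return -1, None
        return k, float(joint[k])

    # singleton initialisation: every lipid starts in its own cluster, so
    # structure emerges by merging; single-site Gibbs cannot split a
    # wrongly merged cluster, which makes rich starts safer than poor ones
    for i in range(L):
        add_cluster(i)

    burn = n_sweeps // 2
    counts: dict[tuple[int, int], int] = {}
    kept_sweeps = 0
    for sweep in range(n_sweeps):
        for i in rng.permutation(L):
            remove(i)
            k, joint = gibbs_choice(i)
            if k < 0:
                add_cluster(i)
            else:
                join(i, k, joint)
        if sweep >= burn:
            kept_sweeps += 1
            for i in range(L):
                key = (i, ids[assign[i]])
                counts[key] = counts.get(key, 0) + 1

    all_ids = sorted({cid for (_, cid) in counts})
    prob = np.zeros((L, len(all_ids)))
    col = {cid: j for j, cid in enumerate(all_ids)}
    for (i, cid), c in counts.items():
        prob[i, col[cid]] = c / kept_sweeps
    map_labels = np.array([all_ids[j] for j in prob.argmax(axis=1)])
    # relabel to dense ids ordered by cluster size (ties by first id)
    sizes = pd.Series(map_labels).value_counts()
    order = sorted(sizes.index, key=lambda cid: (-sizes[cid], cid))
    remap = {cid: r for r, cid in enumerate(order)}
    labels = pd.Series([remap[c] for c in map_labels], index=lipid_ids)
    # ids visited in kept sweeps but never MAP get codes after the dense ones
    remap_full = dict(remap)
    for cid in all_ids:
        if cid not in remap_full:
            remap_full[cid] = len(remap_full)
    prob_df = pd.DataFrame(prob, index=lipid_ids, columns=all_ids)
    prob_df = prob_df.rename(columns=remap_full)
    prob_df = prob_df.T.groupby(level=0).sum().T
    prob_df = prob_df[sorted(prob_df.columns)]
    total_ev = float(base_ev.sum() + len(ids) * log_alpha)
    return ClusteringRun(alpha, seed, labels, prob_df, n_sweeps, total_ev)


def fit_dpgp_schedule(
    arr: np.ndarray,
    spec: GPSpec,
    alphas=DEFAULT_ALPHAS,
    runs_per_alpha: int = 10,
    seed: int = 0,
    n_sweeps: int = 60,
    lipid_ids: list | None = None,
) -> list[ClusteringRun]:
    """Run the full seed x alpha schedule (default 10 runs per alpha)."""
    seeds = np.random.SeedSequence(seed).generate_state(len(alphas) * runs_per_alpha)
    runs = []
    k = 0
    for alpha in alphas:
        for _ in range(runs_per_alpha):
            runs.append(fit_dpgp_run(arr, spec, alpha, int(seeds[k] % (2 ** 31)),
                                     n_sweeps, lipid_ids))
            k += 1
    return runs


# ---------------------------------------------------------------------------
# cluster posterior and comparison
# ---------------------------------------------------------------------------

def cluster_posterior(members: np.ndarray, spec: GPSpec) -> ClusterPosterior:
    """Conjugate GP posterior of the cluster mean function.

    ``members`` is an (m, T) stack of trajectories on the shared grid;
    with ybar their pointwise mean,
    Sigma_post = (K^-1 + (m / sn2) I)^-1 and
    mu_post = Sigma_post (m / sn2) ybar.
    """
    members = np.atleast_2d(np.asarray(members, dtype=float))
    mtraj, T = members.shape
    if T != len(spec.time_grid):
        raise PipelineError("trajectory length does not match grid")
    K = spec.kernel()
    Kinv = np.linalg.inv(K)
    A = Kinv + (mtraj / spec.noise_variance) * np.eye(T)
    cov = np.linalg.inv(A)
    mu = cov @ (members.sum(axis=0) / spec.noise_variance)
    cov = 0.5 * (cov + cov.T)
    return ClusterPosterior(mu, cov, mtraj)


def vi_distance(labels_a, labels_b) -> float:
    """Variation of information between two partitions, in nats.

    VI = H(A) + H(B) - 2 I(A, B) with natural-log entropies of the
    empirical joint distribution over cluster pairs.
    """
    a = np.asarray(labels_a)
    b = np.asarray(labels_b)
    if a.shape != b.shape or a.size == 0:
        raise PipelineError("partitions must cover the same items")
    n = a.size
    joint = pd.crosstab(pd.Series(a), pd.Series(b)).to_numpy() / n
    pa = joint.sum(axis=1)
    pb = joint.sum(axis=0)
    nz = joint > 0
    h_joint = -float((joint[nz] * np.log(joint[nz])).sum())
    h_a = -float((pa[pa > 0] * np.log(pa[pa > 0])).sum())
    h_b = -float((pb[pb > 0] * np.log(pb[pb > 0])).sum())
    mi = h_a + h_b - h_joint
    return max(h_a + h_b - 2 * mi, 0.0)


def select_representative_run(runs: list[ClusteringRun]) -> ClusteringRun:
    """Pick the run with the smallest mean VI to the other runs of its
    alpha group; ties broken by (lower alpha, lower seed)."""
    if not runs:
        raise PipelineError("no runs")
    scored = []
    by_alpha: dict[float, list[ClusteringRun]] = {}
    for r in runs:
        by_alpha.setdefault(r.alpha, []).append(r)
    for alpha, group in by_alpha.items():
        if len(group) < 2:
            raise PipelineError(f"alpha {alpha} has fewer than 2 runs")
        labs = [g.labels.to_numpy() for g in group]
        k = len(group)
        dist = np.zeros((k, k))
        for i in range(k):
            for j in range(i + 1, k):
                dist[i, j] = dist[j, i] = vi_distance(labs[i], labs[j])
        for i, run in enumerate(group):
            mean_vi = dist[i].sum() / (k - 1)
            scored.append((mean_vi, run.alpha, run.seed, run))
    scored.sort(key=lambda t: (t[0], t[1], t[2]))
    return scored[0][3]


def symmetric_kl_mvn(a: ClusterPosterior, b: ClusterPosterior) -> float:
    """Symmetric KL divergence KL(a||b) + KL(b||a) between Gaussians."""
    mu_a, mu_b = np.asarray(a.mean, float), np.asarray(b.mean, float)
    if mu_a.shape != mu_b.shape:
        raise PipelineError("dimension mismatch")
    T = mu_a.size
    jit = 1e-8 * np.eye(T)
    Sa = np.asarray(a.covariance, float) + jit
    Sb = np.asarray(b.covariance, float) + jit
    Sa_inv = np.linalg.inv(Sa)
    Sb_inv = np.linalg.inv(Sb)
    d = mu_a - mu_b
    # the log-determinant terms cancel in the symmetric sum
    skl = 0.5 * (
        np.trace(Sb_inv @ Sa) + np.trace(Sa_inv @ Sb) - 2 * T
        + d @ Sb_inv @ d + d @ Sa_inv @ d
    )
    return float(max(skl, 0.0))


def order_clusters(
    posteriors: dict[int, ClusterPosterior], min_size: int = 10
) -> tuple[list[int], list[int], list[int]]:
    """Split clusters into major/noise and order the major ones.

    Major clusters (>= min_size member lipids) are ordered by the leaf
    order of a complete-linkage dendrogram on the symmetric-KL distance
    matrix; clusters below the size threshold are returned as noise.
    """
    if not posteriors:
        raise PipelineError("no clusters")
    major = sorted(c for c, p in posteriors.items() if p.member_count >= min_size)
    noise = sorted(c for c in posteriors if c not in major)
    if len(major) <= 1:
        return major, list(major), noise
    k = len(major)
    dist = np.zeros((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            dist[i, j] = dist[j, i] = symmetric_kl_mvn(
                posteriors[major[i]], posteriors[major[j]]
            )
    Z = hierarchy.complete(squareform(dist, checks=False))
    leaves = hierarchy.leaves_list(Z)
    return major, [major[i] for i in leaves], noise


def cluster_trajectories(
    matrix: AbundanceMatrix,
    lengthscale: float = 6.0,
    signal_variance: float = 1.0,
    noise_variance: float | None = None,
    alphas=DEFAULT_ALPHAS,
    runs_per_alpha: int = 10,
    seed: int = 0,
    n_sweeps: int = 60,
    min_size: int = 10,
) -> ClusterSet:
    """End-to-end clustering: schedule, run selection, posteriors, order.

    ``matrix`` holds donor-adjusted z-scored lipids.  The noise variance
    is chosen by marginal-likelihood grid search unless given.
    """
    arr, grid, lipid_ids, _ = trajectories_from_matrix(matrix)
    spec = GPSpec(grid, lengthscale, signal_variance, noise_variance or 0.25)
    if noise_variance is None:
        spec.noise_variance = select_noise_variance(arr, spec)
    runs = fit_dpgp_schedule(arr, spec, alphas, runs_per_alpha, seed, n_sweeps, lipid_ids)
    best = select_representative_run(runs)
    labels = best.labels
    posteriors = {}
    for cid in sorted(labels.unique()):
        members = arr[np.asarray(labels == cid)].reshape(-1, arr.shape[2])
        post = cluster_posterior(members, spec)
        post.member_count = int((labels == cid).sum())
        posteriors[cid] = post
    major, display_order, noise = order_clusters(posteriors, min_size)
    return ClusterSet(best, posteriors, major, display_order, noise, labels)
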