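"""Differential testing over time and trajectory clustering.

Quantile-normalizes and log-transforms the lipidome, tests each lipid
for change over time with a donor-adjusted moderated F-test, then
clusters the significant lipids' donor-adjusted z-scored trajectories
with the Dirichlet-process GP mixture and prints the selected
partition.
"""

from lipidyn.clustering import cluster_trajectories
from lipidyn.differential import run_differential
from lipidyn.preprocess import (
    adjust_donor_effects, log_transform, qc_filter, quantile_normalize, zscore_rows,
)
from lipidyn.simulate import SynthConfig, generate_dataset

lipidome, _, truth = generate_dataset(
    SynthConfig(n_clusters=6, lipids_per_cluster=25, seed=1)
)
kept, _ = qc_filter(lipidome)
pre = log_transform(quantile_normalize(kept).biological())

diff = run_differential(pre, fdr=0.05)
sig = diff.index[diff["significant"]]
print(f"differential: {len(sig)} / {len(diff)} lipids change over time (FDR < 0.05)")

z = zscore_rows(adjust_donor_effects(pre.subset_features(sig)))
clusters = cluster_trajectories(z, alphas=(1e-3, 1e-2), runs_per_alpha=5,
                                seed=1, n_sweeps=60)
print(f"clustering: {clusters.labels.nunique()} clusters, "
      f"{len(clusters.major_clusters)} with >= 10 lipids "
      f"(selected run: alpha={clusters.run.alpha:g})")
print(f"display order (complete-linkage on symmetric KL): "
      f"{[int(c) for c in clusters.display_order]}")
for cid in clusters.display_order:
    mu = clusters.posteriors[cid].mean
    trend = " rising into 16h" if mu[-1] == mu.max() and mu[-1] - mu[-2] > 0 else ""
    print(f"  cluster {int(cid)}: {clusters.posteriors[cid].member_count} lipids, "
          f"posterior mean at grid: {[round(float(v), 2) for v in mu]}{trend}")

# The cluster whose posterior mean is flat until 8 h and jumps at 16 h
# is the resolution-phase cluster; its members are the globosides and
# cholesteryl esters the generator planted there.
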