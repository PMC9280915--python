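"""Generate a synthetic LPS time-course study and look at its structure.

Builds a lipidome (8 temporal clusters, 11 donors, 5 time points, TQC
and blank injections) plus a transcriptome coupled to the
resolution-phase lipids through planted partial-correlation edges, and
prints what was planted.
"""

from lipidyn.simulate import SynthConfig, generate_dataset

config = SynthConfig(seed=1)
lipidome, expression, truth = generate_dataset(config)

n_bio = len(lipidome.sample_ids("biological"))
print(f"lipidome: {lipidome.values.shape[0]} lipids x "
      f"{lipidome.values.shape[1]} samples ({n_bio} biological, "
      f"{len(lipidome.sample_ids('tqc'))} TQC, {len(lipidome.sample_ids('blank'))} blank)")
print(f"lipid classes: {lipidome.features['lipid_class'].nunique()}")
print(f"expression: {expression.values.shape[0]} genes x {expression.values.shape[1]} samples")

sizes = truth.cluster_labels.value_counts().sort_index()
for cid, n in sizes.items():
    tag = " <- resolution phase" if cid in truth.resolution_clusters else ""
    print(f"  cluster {cid} ({truth.cluster_shapes[cid]}): {n} lipids{tag}")
print(f"planted lipid-gene edges: {sorted(truth.planted_lipid_gene_edges())[:3]} ...")

# The resolution cluster holds the globoside (Gb3/Gb4) and cholesteryl
# ester species whose abundance rises sharply between 8 h and 16 h; the
# planted edges tie ten of them to lipid-pathway genes, which is the
# signal the correlation and network stages are meant to recover.
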