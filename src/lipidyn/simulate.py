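"""Synthetic lipidomics and transcriptomics data with planted structure.

The generator emulates the statistical shape of an LPS time-course
experiment in primary human macrophages: ~260 lipid species in ~18
classes measured in 11 donors at 0, 0.5, 3, 8 and 16 hours, with
planted temporal clusters (including a resolution-phase cluster rising
between 8 h and 16 h populated by globosides and cholesteryl esters),
class-specific inter-individual variability (globoside classes get an
inflated donor-effect sd), pooled TQC and blank injections, and a
transcriptome coupled to the resolution lipids through a sparse planted
partial-correlation (precision-matrix) structure.

Abundances follow a lognormal model: on the log2 scale a lipid is
cluster mean + donor offset + iid noise, then exponentiated, which
guarantees positivity and matches the pipeline's log transform.  The
transcripts connected to lipids are drawn from the exact Gaussian
graphical model the network stage assumes, by conditional sampling of
the non-lipid block given the realized lipid values, so edge recovery
is a fair test.  Ground truth (labels, offsets, planted support) is
returned for recovery tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import AbundanceMatrix, ExpressionMatrix, GeneSetCollection, PipelineError

__all__ = [
    "SynthConfig",
    "SyntheticTruth",
    "CLUSTER_SHAPES",
    "DEFAULT_SHAPE_ORDER",
    "generate_lipidome",
    "generate_qc_samples",
    "generate_transcriptome",
    "synthetic_gene_sets",
    "generate_dataset",
]

# Piecewise-linear cluster mean shapes on the log2 scale (unit amplitude),
# defined at the measured time points and interpolated in between.  The
# "resolution" shape is flat until 8 h and rises sharply by 16 h.
_SHAPE_KNOTS = {
    "early_down": [0.0, -1.0, -1.0, -0.95, -0.9],
    "peak_3h": [0.0, 0.5, 1.0, 0.0, -0.6],
    "down_recover": [0.0, -1.0, -0.7, -0.35, -0.15],
    "gradual_up": [0.0, 0.45, 0.7, 0.9, 1.0],
    "peak_8h": [0.0, 0.1, 0.6, 1.0, -0.2],
    "resolution": [0.0, 0.0, 0.05, 0.25, 1.0],
    "late_down": [0.0, -0.05, -0.3, -0.7, -1.0],
    "early_up": [0.0, 1.0, 0.95, 0.9, 0.85],
}
_SHAPE_TIMES = np.array([0.0, 0.5, 3.0, 8.0, 16.0])

CLUSTER_SHAPES = {
    name: (lambda t, k=np.array(knots): np.interp(t, _SHAPE_TIMES, k))
    for name, knots in _SHAPE_KNOTS.items()
}
DEFAULT_SHAPE_ORDER = tuple(_SHAPE_KNOTS)

RESOLUTION_CLASSES = ("Gb3", "Gb4", "CE")
OTHER_CLASSES = (
    "PC", "PE", "PI", "PG", "PS", "LPC", "Cer", "SM", "HexCer",
    "Hex2Cer", "Ganglio", "SPB", "TG", "DG", "FA",
)


@dataclass
class SynthConfig:
    """Parameters of the synthetic study.

    Defaults mirror the emulated experiment: 11 donors, five time
    points, eight temporal clusters of 32 lipids (~260 species, 18
    classes) with globoside classes at a 4x inflated donor-effect sd,
    and a transcriptome of 60 lipid-pathway genes plus 300 genome-wide
    transcripts with 10 planted lipid-gene partial-correlation edges.
    """

    n_donors: int = 11
    time_points: tuple = (0.0, 0.5, 3.0, 8.0, 16.0)
    n_clusters: int = 8
    lipids_per_cluster: int = 32
    cluster_shapes: tuple = DEFAULT_SHAPE_ORDER
    amplitude: float = 1.5            # log2 units of temporal swing
    baseline_log2: float = 6.0        # mean baseline abundance, log2
    baseline_sd: float = 2.0          # lipid concentrations span orders of magnitude
    donor_effect_sd: float = 0.4      # log2 units
    noise_sd: float = 0.25            # log2 units
    high_cv_classes: tuple = ("Gb3", "Gb4")
    high_cv_factor: float = 4.0
    n_pathway_genes: int = 60
    n_transcripts: int = 300
    n_planted_edges: int = 10
    planted_strength: float = 0.9     # lipid-gene edge correlation
    transcripts_per_gene: int = 2     # coupled transcripts per planted gene
    transcript_strength: float = 0.9  # gene-transcript edge correlation
    planted_edges: list | None = None # explicit (a, b, strength) triples
    n_tqc: int = 5
    n_blank: int = 2
    tqc_cv: float = 0.05              # lognormal sd of TQC technical error
    n_contaminants: int = 4
    blank_contaminant_fraction: float = 0.15
    n_tqc_noisy: int = 4              # lipids with inflated TQC noise
    tqc_noisy_cv: float = 0.5
    expression_baseline: float = 5.0  # log2 TPM
    seed: int = 0

    def __post_init__(self) -> None:
        if self.lipids_per_cluster < 1:
            raise PipelineError("lipids_per_cluster must be >= 1")
        if self.donor_effect_sd < 0 or self.noise_sd < 0 or self.tqc_cv < 0:
            raise PipelineError("standard deviations must be >= 0")
        t = np.asarray(self.time_points, dtype=float)
        if not (np.diff(t) > 0).all():
            raise PipelineError("time points must be strictly increasing")
        if self.n_clusters > len(self.cluster_shapes):
            raise PipelineError("more clusters than available shapes")
        for tr in self.planted_edges or []:
            if not (-1.0 < tr[2] < 1.0):
                raise PipelineError("planted strengths must lie in (-1, 1)")


@dataclass
class SyntheticTruth:
    """Planted ground truth for recovery tests."""

    cluster_labels: pd.Series = field(default_factory=pd.Series)
    cluster_shapes: dict = field(default_factory=dict)
    resolution_clusters: list = field(default_factory=list)
    resolution_lipids: list = field(default_factory=list)
    donor_offsets: pd.DataFrame = field(default_factory=pd.DataFrame)
    per_class_donor_sd: dict = field(default_factory=dict)
    planted_edges: list = field(default_factory=list)
    adjacency: set = field(default_factory=set)      # frozenset pairs
    precision: pd.DataFrame = field(default_factory=pd.DataFrame)
    contaminant_lipids: list = field(default_factory=list)
    tqc_noisy_lipids: list = field(default_factory=list)
    pathway_genes: list = field(default_factory=list)

    def planted_lipid_gene_edges(self) -> set:
        return {
            frozenset((a, b)) for a, b, _ in self.planted_edges
            if a in set(self.resolution_lipids) or b in set(self.resolution_lipids)
        }


def _sample_table(config: SynthConfig) -> pd.DataFrame:
    rows = []
    for d in range(config.n_donors):
        donor = f"D{d + 1:02d}"
        for t in config.time_points:
            rows.append((f"{donor}_T{t:g}", donor, float(t), "biological"))
    df = pd.DataFrame(rows, columns=["sample_id", "donor_id", "time_hours", "sample_type"])
    return df.set_index("sample_id")


def _assign_classes(config: SynthConfig) -> tuple[list[str], list[str], list[int], dict]:
    """Lipid ids, classes and cluster labels; resolution clusters carry
    globoside/CE classes, the rest cycle through the other classes."""
    shapes = {c: config.cluster_shapes[c] for c in range(config.n_clusters)}
    lipid_ids, classes, labels = [], [], []
    counters: dict[str, int] = {}
    for c in range(config.n_clusters):
        pool = RESOLUTION_CLASSES if shapes[c] == "resolution" else OTHER_CLASSES
        for j in range(config.lipids_per_cluster):
            cls = pool[j % len(pool)]
            counters[cls] = counters.get(cls, 0) + 1
            lipid_ids.append(f"{cls}_{counters[cls]:03d}")
            classes.append(cls)
            labels.append(c)
    return lipid_ids, classes, labels, shapes


def generate_lipidome(config: SynthConfig) -> tuple[AbundanceMatrix, SyntheticTruth]:
    """Generate the biological-sample lipid abundance matrix and truth.

    abundance(lipid, donor, t) = 2 ** (baseline + amplitude * shape_c(t)
    + donor offset + noise), with the donor-offset sd inflated by
    ``high_cv_factor`` for lipids in ``high_cv_classes``.
    """
    rng = np.random.default_rng(config.seed)
    samples = _sample_table(config)
    lipid_ids, classes, labels, shapes = _assign_classes(config)
    L = len(lipid_ids)
    times = np.array([samples.loc[s, "time_hours"] for s in samples.index])
    donor_codes = pd.Categorical(samples["donor_id"]).codes
    donors = sorted(samples["donor_id"].unique())

    per_class_sd = {
        cls: config.donor_effect_sd
        * (config.high_cv_factor if cls in config.high_cv_classes else 1.0)
        for cls in set(classes)
    }
    base = config.baseline_log2 + config.baseline_sd * rng.standard_normal(L)
    offsets = np.empty((L, config.n_donors))
    for i, cls in enumerate(classes):
        offsets[i] = per_class_sd[cls] * rng.standard_normal(config.n_donors)

    log2_vals = np.empty((L, len(samples)))
    for i in range(L):
        shape = CLUSTER_SHAPES[shapes[labels[i]]](times)
        log2_vals[i] = (
            base[i] + config.amplitude * shape + offsets[i, donor_codes]
            + config.noise_sd * rng.standard_normal(len(samples))
        )

    values = pd.DataFrame(2.0 ** log2_vals, index=lipid_ids, columns=samples.index)
    features = pd.DataFrame({"lipid_class": classes}, index=lipid_ids)
    features.index.name = "feature_id"
    matrix = AbundanceMatrix(values, features, samples, "raw")

    resolution = [c for c, s in shapes.items() if s == "resolution"]
    truth = SyntheticTruth(
        cluster_labels=pd.Series(labels, index=lipid_ids),
        cluster_shapes=shapes,
        resolution_clusters=resolution,
        resolution_lipids=[lip for lip, lab in zip(lipid_ids, labels) if lab in resolution],
        donor_offsets=pd.DataFrame(offsets, index=lipid_ids, columns=donors),
        per_class_donor_sd=per_class_sd,
    )
    return matrix, truth


def generate_qc_samples(
    config: SynthConfig, base: AbundanceMatrix, truth: SyntheticTruth | None = None
) -> AbundanceMatrix:
    """Append TQC and blank columns to a biological abundance matrix.

    TQC columns are the pooled biological mean per lipid times a small
    lognormal technical error; lipids marked as TQC-noisy get an
    inflated error.  Blank columns are zero except for designated
    contaminant lipids, which are set to a fixed fraction of the TQC
    mean.  Contaminants and noisy lipids are drawn from outside the
    resolution clusters so technical failures do not collide with the
    planted biology.
    """
    if config.n_tqc < 2:
        raise PipelineError("need n_tqc >= 2 (TQC CV undefined otherwise)")
    rng = np.random.default_rng(np.random.SeedSequence((config.seed, 7)).generate_state(1)[0])
    bio_ids = base.sample_ids("biological")
    pooled = base.values[bio_ids].mean(axis=1)
    lipids = list(base.values.index)
    res_set = set(truth.resolution_lipids) if truth is not None else set()
    eligible = [lip for lip in lipids if lip not in res_set]
    noisy = eligible[: config.n_tqc_noisy]
    contaminants = eligible[config.n_tqc_noisy: config.n_tqc_noisy + config.n_contaminants]

    sigma = np.full(len(lipids), config.tqc_cv)
    sigma[[lipids.index(lip) for lip in noisy]] = config.tqc_noisy_cv
    tqc_cols = {}
    for j in range(config.n_tqc):
        err = np.exp(sigma * rng.standard_normal(len(lipids)) - sigma ** 2 / 2)
        tqc_cols[f"TQC{j + 1:02d}"] = pooled.to_numpy() * err
    blank = np.zeros(len(lipids))
    idx = [lipids.index(lip) for lip in contaminants]
    blank[idx] = config.blank_contaminant_fraction * pooled.to_numpy()[idx]
    blank_cols = {f"BLANK{j + 1:02d}": blank.copy() for j in range(config.n_blank)}

    values = base.values.copy()
    for name, col in {**tqc_cols, **blank_cols}.items():
        values[name] = col
    extra = pd.DataFrame(
        {
            "donor_id": [None] * (config.n_tqc + config.n_blank),
            "time_hours": [np.nan] * (config.n_tqc + config.n_blank),
            "sample_type": ["tqc"] * config.n_tqc + ["blank"] * config.n_blank,
        },
        index=list(tqc_cols) + list(blank_cols),
    )
    samples = pd.concat([base.samples, extra])
    if truth is not None:
        truth.contaminant_lipids = contaminants
        truth.tqc_noisy_lipids = noisy
    return AbundanceMatrix(values, base.features.copy(), samples, "raw")


def _planted_forest(config: SynthConfig, truth: SyntheticTruth) -> list[tuple]:
    """Planted (parent, child, edge correlation) triples forming a forest
    rooted at resolution lipids: lipid -> pathway gene -> transcripts."""
    if config.planted_edges is not None:
        edges = [tuple(e) for e in config.planted_edges]
    else:
        res = truth.resolution_lipids
        if len(res) < config.n_planted_edges:
            raise PipelineError("not enough resolution lipids for planted edges")
        edges = [
            (res[i], f"LPG{i + 1:03d}", config.planted_strength)
            for i in range(config.n_planted_edges)
        ]
        for i in range(config.n_planted_edges):
            gene = f"LPG{i + 1:03d}"
            for k in range(config.transcripts_per_gene):
                edges.append(
                    (gene, f"TX{i * config.transcripts_per_gene + k + 1:04d}",
                     config.transcript_strength)
                )
    children = [b for _, b, _ in edges]
    if len(set(children)) != len(children):
        raise PipelineError("planted edges must form a forest (one parent per node)")
    truth.planted_edges = edges
    truth.adjacency = {frozenset((a, b)) for a, b, _ in edges}
    return edges


def _forest_precision(edges: list[tuple], nodes: list[str]) -> pd.DataFrame:
    """Implied precision matrix of the unit-variance tree Gaussian
    (covariance between two nodes = product of edge correlations along
    the connecting path; zero across trees)."""
    idx = {v: i for i, v in enumerate(nodes)}
    sigma = np.eye(len(nodes))
    adj: dict[str, list[tuple[str, float]]] = {v: [] for v in nodes}
    for a, b, r in edges:
        adj[a].append((b, r))
        adj[b].append((a, r))
    for root in nodes:
        stack = [(root, 1.0, None)]
        while stack:
            node, corr, prev = stack.pop()
            if node != root:
                sigma[idx[root], idx[node]] = corr
            for nxt, r in adj[node]:
                if nxt != prev:
                    stack.append((nxt, corr * r, node))
    omega = np.linalg.inv(sigma)
    omega[np.abs(omega) < 1e-10] = 0.0
    return pd.DataFrame(omega, index=nodes, columns=nodes)


def generate_transcriptome(
    config: SynthConfig, truth: SyntheticTruth, lipidome: AbundanceMatrix
) -> tuple[ExpressionMatrix, SyntheticTruth]:
    """Generate log2 TPM expression jointly consistent with the lipidome.

    Coupled pathway genes and transcripts are sampled along the planted
    forest: each child is (edge r) x standardized parent + sqrt(1 - r^2)
    x fresh noise.  A Gaussian cascade on a tree is exactly a Gaussian
    graphical model whose precision support is the tree, so the planted
    adjacency is the true partial-correlation support and edge recovery
    is a fair test; the edge correlations are strong enough that planted
    associations clear the staged R^2 filters, as the emulated study's
    retained associations did.  Pathway genes without planted edges, and
    uncoupled transcripts, are independent noise with mild
    non-resolution temporal trends.
    """
    rng = np.random.default_rng(np.random.SeedSequence((config.seed, 11)).generate_state(1)[0])
    edges = _planted_forest(config, truth)
    bio = lipidome.biological()
    sample_ids = list(bio.samples.index)
    times = bio.samples["time_hours"].to_numpy(dtype=float)
    n = len(sample_ids)

    lipid_set = set(bio.values.index)
    node_values: dict[str, np.ndarray] = {}
    for lip in {a for a, _, _ in edges} & lipid_set:
        x = np.log2(bio.values.loc[lip].to_numpy(dtype=float) + 1.0)
        node_values[lip] = (x - x.mean()) / x.std(ddof=1)
    remaining = list(edges)
    while remaining:
        progressed = False
        for a, b, r in list(remaining):
            if a in node_values:
                parent = node_values[a]
                node_values[b] = r * parent + np.sqrt(1 - r ** 2) * rng.standard_normal(n)
                remaining.remove((a, b, r))
                progressed = True
        if not progressed:
            bad = sorted({a for a, _, _ in remaining})
            raise PipelineError(f"planted edges with unknown parents: {bad}")
    ordered = [v for v in node_values if v not in lipid_set]
    coupled_df = pd.DataFrame(
        np.array([node_values[v] for v in ordered]) if ordered else np.empty((0, n)),
        index=ordered, columns=sample_ids,
    )
    truth.precision = _forest_precision(edges, sorted(node_values))

    genes = [f"LPG{i + 1:03d}" for i in range(config.n_pathway_genes)]
    transcripts = [f"TX{i + 1:04d}" for i in range(config.n_transcripts)]
    all_ids = genes + transcripts
    expr = pd.DataFrame(0.0, index=all_ids, columns=sample_ids)
    trend_shapes = [s for s in DEFAULT_SHAPE_ORDER if s != "resolution"]
    for gid in all_ids:
        if gid in coupled_df.index:
            expr.loc[gid] = coupled_df.loc[gid]
        else:
            shape = CLUSTER_SHAPES[trend_shapes[rng.integers(len(trend_shapes))]](times)
            expr.loc[gid] = 0.3 * shape + rng.standard_normal(n)
    expr = config.expression_baseline + expr
    truth.pathway_genes = genes
    return ExpressionMatrix(expr, bio.samples.copy()), truth


def synthetic_gene_sets(
    config: SynthConfig, truth: SyntheticTruth, n_random_sets: int = 8
) -> GeneSetCollection:
    """A small gene-set collection for enrichment tests: one term holding
    the planted resolution-coupled genes plus random decoy terms."""
    rng = np.random.default_rng(np.random.SeedSequence((config.seed, 13)).generate_state(1)[0])
    genes = [f"LPG{i + 1:03d}" for i in range(config.n_pathway_genes)]
    transcripts = [f"TX{i + 1:04d}" for i in range(config.n_transcripts)]
    universe = genes + transcripts
    coupled = sorted({v for pair in truth.adjacency for v in pair if v in set(universe)})
    sets = {"RESOLUTION_COUPLED": ("planted resolution-phase program", coupled)}
    for k in range(n_random_sets):
        hi = max(6, min(40, len(universe)))
        size = int(rng.integers(5, hi))
        members = list(rng.choice(universe, size=size, replace=False))
        sets[f"DECOY_{k + 1:02d}"] = ("random decoy set", sorted(members))
    return GeneSetCollection(sets)


def generate_dataset(
    config: SynthConfig,
) -> tuple[AbundanceMatrix, ExpressionMatrix, SyntheticTruth]:
    """Full synthetic study: lipidome with QC columns, transcriptome, truth."""
    lipidome, truth = generate_lipidome(config)
    expression, truth = generate_transcriptome(config, truth, lipidome)
    lipidome = generate_qc_samples(config, lipidome, truth)
    return lipidome, expression, truth
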