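"""Data model and file I/O for the pipeline.

The central carriers are :class:`AbundanceMatrix` (lipid species x samples,
with lipid-class and sample annotations) and :class:`ExpressionMatrix`
(genes x samples, log2 TPM).  Matrices are plain TSV files; sample
metadata lives in a separate sample-sheet TSV so the matrix stays a plain
table.  Gene sets are read from GMT files; networks are written as
GraphML, SIF or an edge TSV.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import networkx as nx
import numpy as np
import pandas as pd

SAMPLE_TYPES = ("biological", "tqc", "blank")
TRANSFORM_STATES = ("raw", "log", "residual", "zscore")

SAMPLE_SHEET_COLUMNS = ["sample_id", "donor_id", "time_hours", "sample_type"]


class PipelineError(RuntimeError):
    """Raised for contract violations in pipeline inputs."""


def _check_sample_table(samples: pd.DataFrame) -> pd.DataFrame:
    samples = samples.copy()
    if samples.index.duplicated().any():
        dup = samples.index[samples.index.duplicated()][0]
        raise PipelineError(f"duplicate sample_id {dup!r}")
    bad = set(samples["sample_type"]) - set(SAMPLE_TYPES)
    if bad:
        raise PipelineError(f"unknown sample_type(s): {sorted(bad)}")
    bio = samples["sample_type"] == "biological"
    if samples.loc[bio, "donor_id"].isna().any():
        raise PipelineError("biological sample without donor_id")
    if samples.loc[bio, "time_hours"].isna().any():
        raise PipelineError("biological sample without time_hours")
    t = samples.loc[bio, "time_hours"].astype(float)
    if (t < 0).any():
        raise PipelineError("negative time_hours")
    return samples


@dataclass
class AbundanceMatrix:
    """Lipid species x samples abundance table with annotations.

    Attributes
    ----------
    values : DataFrame indexed by feature_id with sample_id columns.
    features : DataFrame indexed by feature_id, with a ``lipid_class`` column.
    samples : DataFrame indexed by sample_id, columns donor_id, time_hours,
        sample_type.
    transform_state : one of raw | log | residual | zscore.
    """

    values: pd.DataFrame
    features: pd.DataFrame
    samples: pd.DataFrame
    transform_state: str = "raw"

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.transform_state not in TRANSFORM_STATES:
            raise PipelineError(f"unknown transform_state {self.transform_state!r}")
        if self.values.index.duplicated().any():
            dup = self.values.index[self.values.index.duplicated()][0]
            raise PipelineError(f"duplicate feature_id {dup!r}")
        if not self.values.index.equals(self.features.index):
            raise PipelineError("values rows do not match feature table")
        if list(self.values.columns) != list(self.samples.index):
            raise PipelineError("values columns do not match sample table")
        self.samples = _check_sample_table(self.samples)
        vals = self.values.to_numpy()
        if np.isnan(vals).any():
            raise PipelineError("missing values are not allowed (no imputation)")
        if self.transform_state == "raw" and (vals < 0).any():
            i, j = np.argwhere(vals < 0)[0]
            raise PipelineError(
                f"negative raw abundance at feature {self.values.index[i]!r}, "
                f"sample {self.values.columns[j]!r}"
            )

    # -- convenient slices -------------------------------------------------
    def sample_ids(self, sample_type: str) -> list[str]:
        return list(self.samples.index[self.samples["sample_type"] == sample_type])

    def biological(self) -> "AbundanceMatrix":
        """Restrict to biological samples."""
        ids = self.sample_ids("biological")
        return AbundanceMatrix(
            self.values[ids], self.features.copy(), self.samples.loc[ids],
            self.transform_state,
        )

    def subset_features(self, feature_ids: Iterable[str]) -> "AbundanceMatrix":
        ids = list(feature_ids)
        return AbundanceMatrix(
            self.values.loc[ids], self.features.loc[ids], self.samples.copy(),
            self.transform_state,
        )

    def copy_with(self, values: pd.DataFrame, transform_state: str | None = None) -> "AbundanceMatrix":
        return AbundanceMatrix(
            values, self.features.loc[values.index].copy(),
            self.samples.loc[values.columns].copy(),
            transform_state or self.transform_state,
        )


@dataclass
class ExpressionMatrix:
    """Genes x samples log2 TPM matrix with sample annotations."""

    values: pd.DataFrame
    samples: pd.DataFrame

    def __post_init__(self) -> None:
        if self.values.index.duplicated().any():
            dup = self.values.index[self.values.index.duplicated()][0]
            raise PipelineError(f"duplicate gene symbol {dup!r}")
        if list(self.values.columns) != list(self.samples.index):
            raise PipelineError("values columns do not match sample table")
        self.samples = _check_sample_table(self.samples)
        if np.isnan(self.values.to_numpy()).any():
            raise PipelineError("missing expression values are not allowed")

    def sample_ids(self, sample_type: str) -> list[str]:
        return list(self.samples.index[self.samples["sample_type"] == sample_type])


@dataclass
class GeneSetCollection:
    """Named gene sets (term -> description + member symbols, uppercased)."""

    sets: dict[str, tuple[str, list[str]]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, (_, genes) in self.sets.items():
            if not genes:
                raise PipelineError(f"gene set {name!r} is empty")

    def genes(self, name: str) -> list[str]:
        return self.sets[name][1]

    def __len__(self) -> int:
        return len(self.sets)


@dataclass
class RunManifest:
    """Record of one pipeline run: config, seeds and per-stage counts."""

    config: dict
    seeds: dict[str, int] = field(default_factory=dict)
    version: str = ""
    stage_counts: dict[str, int] = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "config": self.config,
            "seeds": self.seeds,
            "version": self.version,
            "stage_counts": self.stage_counts,
        }
        Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "RunManifest":
        d = json.loads(Path(path).read_text())
        return cls(d["config"], d["seeds"], d["version"], d["stage_counts"])


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def read_sample_sheet(path: str | Path) -> pd.DataFrame:
    """Read a sample sheet TSV: sample_id, donor_id, time_hours, sample_type."""
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "donor_id": str})
    missing = set(SAMPLE_SHEET_COLUMNS) - set(df.columns)
    if missing:
        raise PipelineError(f"sample sheet missing column(s): {sorted(missing)}")
    df = df.set_index("sample_id")
    df["time_hours"] = pd.to_numeric(df["time_hours"], errors="coerce")
    return _check_sample_table(df[["donor_id", "time_hours", "sample_type"]])


def write_sample_sheet(samples: pd.DataFrame, path: str | Path) -> None:
    out = samples.reset_index()
    out.columns = SAMPLE_SHEET_COLUMNS
    out.to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_abundance_table(path: str | Path, sample_sheet: str | Path) -> AbundanceMatrix:
    """Read a lipid abundance TSV (feature_id, lipid_class, sample columns).

    Sample columns are matched against the sample sheet by sample_id;
    unknown columns, negative raw values and missing cells are hard errors.
    """
    sheet = read_sample_sheet(sample_sheet)
    df = pd.read_csv(path, sep="\t", dtype={0: str, 1: str})
    if df.columns[0] != "feature_id" or df.columns[1] != "lipid_class":
        raise PipelineError(
            "abundance table must start with columns feature_id, lipid_class"
        )
    df = df.set_index("feature_id")
    features = df[["lipid_class"]].copy()
    values = df.drop(columns="lipid_class")
    unknown = [c for c in values.columns if c not in sheet.index]
    if unknown:
        raise PipelineError(f"sample {unknown[0]!r} not in sample sheet")
    values = values.apply(pd.to_numeric).astype(float)
    return AbundanceMatrix(values, features, sheet.loc[list(values.columns)], "raw")


def write_abundance_table(
    matrix: AbundanceMatrix, path: str | Path, sample_sheet: str | Path | None = None
) -> None:
    out = matrix.values.copy()
    out.insert(0, "lipid_class", matrix.features["lipid_class"])
    out.index.name = "feature_id"
    out.to_csv(path, sep="\t", float_format="%.10g")
    if sample_sheet is not None:
        write_sample_sheet(matrix.samples, sample_sheet)


def read_expression_table(path: str | Path, sample_sheet: str | Path) -> ExpressionMatrix:
    """Read a genes x samples log2 TPM TSV (first column gene symbol)."""
    sheet = read_sample_sheet(sample_sheet)
    df = pd.read_csv(path, sep="\t", dtype={0: str})
    df = df.set_index(df.columns[0])
    df.index = df.index.str.upper()
    df.index.name = "gene"
    unknown = [c for c in df.columns if c not in sheet.index]
    if unknown:
        raise PipelineError(f"sample {unknown[0]!r} not in sample sheet")
    df = df.apply(pd.to_numeric).astype(float)
    return ExpressionMatrix(df, sheet.loc[list(df.columns)])


def write_expression_table(
    matrix: ExpressionMatrix, path: str | Path, sample_sheet: str | Path | None = None
) -> None:
    out = matrix.values.copy()
    out.index.name = "gene"
    out.to_csv(path, sep="\t", float_format="%.10g")
    if sample_sheet is not None:
        write_sample_sheet(matrix.samples, sample_sheet)


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Read a GMT file: name <tab> description <tab> gene [<tab> gene ...].

    Gene symbols are uppercased; duplicates within a line are dropped
    (first occurrence kept); empty lines are skipped.
    """
    sets: dict[str, tuple[str, list[str]]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise PipelineError(f"GMT line {lineno}: fewer than 3 fields")
            name, desc = parts[0], parts[1]
            genes = list(dict.fromkeys(g.strip().upper() for g in parts[2:] if g.strip()))
            if not genes:
                raise PipelineError(f"GMT line {lineno}: no gene symbols")
            sets[name] = (desc, genes)
    return GeneSetCollection(sets)


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, (desc, genes) in collection.sets.items():
            fh.write("\t".join([name, desc, *genes]) + "\n")


def read_gene_list(path: str | Path) -> list[str]:
    """Read a plain gene list (one symbol per line), uppercased, deduplicated."""
    out: list[str] = []
    for line in Path(path).read_text().splitlines():
        g = line.strip().upper()
        if g and g not in out:
            out.append(g)
    return out


# ---------------------------------------------------------------------------
# network export
# ---------------------------------------------------------------------------

EDGE_TSV_COLUMNS = ["source", "target", "source_type", "target_type", "pcor", "p", "q"]


def _sorted_edges(network: nx.Graph):
    for u, v in sorted((sorted((str(a), str(b))) for a, b in network.edges())):
        yield u, v, network.edges[u, v]


def write_network(network: nx.Graph, path: str | Path, format: str = "edge_tsv") -> None:
    """Write a network as graphml, sif or edge_tsv, with deterministic order."""
    path = Path(path)
    if format == "sif":
        with open(path, "w") as fh:
            for u, v, _ in _sorted_edges(network):
                fh.write(f"{u}\tpcor\t{v}\n")
    elif format == "edge_tsv":
        rows = []
        for u, v, data in _sorted_edges(network):
            rows.append({
                "source": u, "target": v,
                "source_type": network.nodes[u].get("node_type", ""),
                "target_type": network.nodes[v].get("node_type", ""),
                "pcor": data.get("pcor", np.nan),
                "p": data.get("p", np.nan),
                "q": data.get("q", np.nan),
            })
        pd.DataFrame(rows, columns=EDGE_TSV_COLUMNS).to_csv(
            path, sep="\t", index=False, float_format="%.10g"
        )
    elif format == "graphml":
        g = nx.Graph()
        for n in sorted(network.nodes, key=str):
            g.add_node(n, **network.nodes[n])
        for u, v, data in _sorted_edges(network):
            g.add_edge(u, v, **data)
        nx.write_graphml(g, path)
    else:
        raise PipelineError(f"unknown network format {format!r}")


def read_network_edge_tsv(path: str | Path) -> nx.Graph:
    df = pd.read_csv(path, sep="\t")
    g = nx.Graph()
    for row in df.itertuples(index=False):
        g.add_node(row.source, node_type=row.source_type)
        g.add_node(row.target, node_type=row.target_type)
        g.add_edge(row.source, row.target, pcor=row.pcor, p=row.p, q=row.q)
    return g
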