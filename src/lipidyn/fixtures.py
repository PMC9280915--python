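"""Packaged desk-scale synthetic study used by tests and examples.

The fixture is generated at run time from a seeded configuration: six
temporal clusters of 25 lipids (one of them the resolution-phase
cluster of globosides and cholesteryl esters) across 11 donors and five
time points, 40 lipid-pathway genes and 200 genome-wide transcripts
with 10 planted lipid-gene partial-correlation edges.  The clustering
schedule and the network q threshold are scaled to the fixture size
(ten runs over two concentration values, q < 0.05); the thresholds of
the full-scale analysis remain the package defaults.
"""

from __future__ import annotations

from .pipeline import PipelineConfig
from .simulate import SynthConfig

__all__ = ["fixture_synth_config", "fixture_pipeline_config"]


def fixture_synth_config(seed: int = 0) -> SynthConfig:
    return SynthConfig(
        n_clusters=6,
        lipids_per_cluster=25,
        n_pathway_genes=40,
        n_transcripts=200,
        seed=seed,
    )


def fixture_pipeline_config(seed: int = 0) -> PipelineConfig:
    return PipelineConfig(
        simulate=fixture_synth_config(seed),
        alphas=(1e-3, 1e-2),
        runs_per_alpha=5,
        n_sweeps=60,
        association_pairing="matched_samples",
        network_pairing="matched_samples",
        q_max=0.05,
        seed=seed,
    )
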