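"""Staged Pearson correlation between lipids and transcripts.

Stage 1 links resolution-phase lipids to lipid-pathway transcripts;
stage 2 links the surviving pathway transcripts to genome-wide
transcripts.  Each stage computes all pairwise Pearson correlations,
adjusts the p-values jointly with Benjamini-Hochberg, and filters on
R^2 and adjusted p (defaults R^2 > 0.6 / p-adj < 0.05 for stage 1 and
R^2 > 0.7 / p-adj < 0.01 for stage 2).  Both correlation signs pass the
filters.

Because lipidomics donors and RNA-seq samples need not be matched
one-to-one, the default pairing averages each feature across donors
within each time point (``timepoint_means``); ``matched_samples`` pairs
shared sample ids directly.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .differential import bh_adjust
from .io import AbundanceMatrix, ExpressionMatrix, PipelineError

__all__ = ["feature_table", "correlate_features", "filter_stage"]


def _timepoint_means(values: pd.DataFrame, samples: pd.DataFrame) -> pd.DataFrame:
    bio = samples.index[samples["sample_type"] == "biological"]
    sub = values[list(bio)]
    times = samples.loc[bio, "time_hours"].astype(float)
    out = sub.T.groupby(times.to_numpy()).mean().T
    return out[sorted(out.columns)]


def feature_table(
    data: AbundanceMatrix | ExpressionMatrix, pairing: str = "timepoint_means"
) -> pd.DataFrame:
    """Features x observations table under the requested pairing."""
    if isinstance(data, AbundanceMatrix):
        values, samples = data.values, data.samples
    else:
        values, samples = data.values, data.samples
    if pairing == "timepoint_means":
        return _timepoint_means(values, samples)
    if pairing == "matched_samples":
        bio = samples.index[samples["sample_type"] == "biological"]
        return values[list(bio)]
    raise PipelineError(f"unknown pairing {pairing!r}")


def correlate_features(
    a: pd.DataFrame, b: pd.DataFrame, pairing_check: bool = True
) -> pd.DataFrame:
    """All-pairs Pearson correlation between rows of ``a`` and rows of ``b``.

    ``a`` and ``b`` are feature x observation tables on a shared
    observation set (build them with :func:`feature_table`).  Returns a
    CorrelationTable with r, r_squared, two-sided p (t transform with
    n - 2 df) and BH-adjusted p over all pairs jointly.  Pairs with
    fewer than 3 observations or zero variance are skipped with a
    warning.
    """
    if pairing_check:
        shared = [c for c in a.columns if c in set(b.columns)]
        if len(shared) < 3:
            raise PipelineError("fewer than 3 paired observations")
        a, b = a[shared], b[shared]
    n = a.shape[1]
    if n < 3:
        raise PipelineError("fewer than 3 paired observations")

    A = a.to_numpy(dtype=float)
    B = b.to_numpy(dtype=float)
    sd_a = A.std(axis=1, ddof=1)
    sd_b = B.std(axis=1, ddof=1)
    ok_a, ok_b = sd_a > 0, sd_b > 0
    if (~ok_a).any() or (~ok_b).any():
        warnings.warn(
            f"skipping {int((~ok_a).sum())} + {int((~ok_b).sum())} zero-variance features"
        )
    Za = (A[ok_a] - A[ok_a].mean(axis=1, keepdims=True)) / sd_a[ok_a, None]
    Zb = (B[ok_b] - B[ok_b].mean(axis=1, keepdims=True)) / sd_b[ok_b, None]
    r = np.clip(Za @ Zb.T / (n - 1), -1.0, 1.0)

    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt((n - 2) / (1.0 - r ** 2))
    p = 2 * stats.t.sf(np.abs(t), n - 2)
    p[np.abs(r) >= 1.0] = 0.0

    ia = np.asarray(a.index)[ok_a]
    ib = np.asarray(b.index)[ok_b]
    fa, fb = np.meshgrid(np.arange(len(ia)), np.arange(len(ib)), indexing="ij")
    table = pd.DataFrame({
        "feature_a": ia[fa.ravel()],
        "feature_b": ib[fb.ravel()],
        "r": r.ravel(),
        "r_squared": (r ** 2).ravel(),
        "p_value": p.ravel(),
        "n_obs": n,
    })
    table["p_adjusted"] = bh_adjust(table["p_value"].to_numpy())
    return table[["feature_a", "feature_b", "r", "r_squared", "p_value", "p_adjusted", "n_obs"]]


def filter_stage(table: pd.DataFrame, r2_min: float, padj_max: float) -> pd.DataFrame:
    """Keep records with r^2 > r2_min and adjusted p < padj_max.

    Both correlation signs are retained.  The surviving distinct feature
    counts per side are stored in ``attrs``.
    """
    kept = table[(table["r_squared"] > r2_min) & (table["p_adjusted"] < padj_max)].copy()
    kept.attrs["n_feature_a"] = int(kept["feature_a"].nunique())
    kept.attrs["n_feature_b"] = int(kept["feature_b"].nunique())
    return kept
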