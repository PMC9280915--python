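"""Quality control, variability profiling and normalization.

Implements the pre-analysis steps for LC-MS lipid abundance tables:

* technical QC against pooled technical quality-control (TQC) injections
  (CV% < 30) and solvent blanks (mean blank signal < 10% of mean TQC);
* coefficient-of-variation profiling of biological (inter-donor)
  variability at baseline;
* quantile normalization across biological samples, log2(x + offset)
  transform, donor-effect removal by per-donor mean subtraction, row
  z-scoring, and the sqrt(t) + 2 time transform used downstream by the
  Gaussian-process clustering.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .io import AbundanceMatrix, PipelineError

__all__ = [
    "cv_percent",
    "compute_cv_table",
    "qc_filter",
    "quantile_normalize",
    "log_transform",
    "adjust_donor_effects",
    "zscore_rows",
    "transform_time",
]


def cv_percent(values) -> float:
    """Coefficient of variation in percent: 100 * sd / mean.

    Uses the n-1 sample standard deviation.  Requires at least two
    values and a non-zero mean.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise PipelineError("CV requires at least 2 values")
    m = x.mean()
    if m == 0:
        raise PipelineError("CV undefined: mean is zero")
    return float(100.0 * x.std(ddof=1) / m)


def _row_cv(values: pd.DataFrame) -> pd.Series:
    """Per-row CV%; rows with zero mean yield NaN (flagged, not dropped)."""
    m = values.mean(axis=1)
    sd = values.std(axis=1, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        cv = 100.0 * sd / m
    cv[m == 0] = np.nan
    return cv


def compute_cv_table(matrix: AbundanceMatrix, baseline_time: float = 0.0) -> pd.DataFrame:
    """Per-lipid biological CV% (untreated samples across donors) and TQC CV%.

    Rows with zero mean carry NaN CV and a ``cv_defined`` flag of False.
    """
    bio = matrix.samples.index[
        (matrix.samples["sample_type"] == "biological")
        & (matrix.samples["time_hours"] == baseline_time)
    ]
    tqc = matrix.sample_ids("tqc")
    out = pd.DataFrame(index=matrix.values.index)
    out["lipid_class"] = matrix.features["lipid_class"]
    out["biological_cv_percent"] = _row_cv(matrix.values[list(bio)]) if len(bio) >= 2 else np.nan
    out["tqc_cv_percent"] = _row_cv(matrix.values[tqc]) if len(tqc) >= 2 else np.nan
    out["cv_defined"] = ~out["biological_cv_percent"].isna()
    return out


def qc_filter(
    matrix: AbundanceMatrix, cv_max: float = 30.0, blank_max: float = 0.10
) -> tuple[AbundanceMatrix, pd.DataFrame]:
    """Drop lipids that fail technical QC.

    A lipid passes when its TQC CV% is below ``cv_max`` and its mean
    blank signal is below ``blank_max`` times its mean TQC signal.
    Returns the filtered matrix (all sample columns retained) and a
    report for every input lipid with columns tqc_cv_percent,
    blank_fraction_of_tqc, pass, reason.
    """
    tqc = matrix.sample_ids("tqc")
    blanks = matrix.sample_ids("blank")
    if len(tqc) < 2:
        raise PipelineError("qc_filter requires at least 2 TQC samples")

    tqc_vals = matrix.values[tqc]
    tqc_cv = _row_cv(tqc_vals)
    tqc_mean = tqc_vals.mean(axis=1)

    if blanks:
        blank_mean = matrix.values[blanks].mean(axis=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            blank_frac = (blank_mean / tqc_mean).where(tqc_mean > 0, np.inf)
        blank_frac = blank_frac.where(~((blank_mean == 0) & (tqc_mean == 0)), 0.0)
    else:
        warnings.warn("no blank samples: blank-contamination rule skipped")
        blank_frac = pd.Series(0.0, index=matrix.values.index)

    cv_ok = tqc_cv < cv_max
    blank_ok = blank_frac < blank_max
    passed = cv_ok & blank_ok
    reason = pd.Series("ok", index=matrix.values.index)
    reason[~cv_ok] = "high_tqc_cv"
    reason[cv_ok & ~blank_ok] = "present_in_blank"

    report = pd.DataFrame({
        "tqc_cv_percent": tqc_cv,
        "blank_fraction_of_tqc": blank_frac,
        "pass": passed,
        "reason": reason,
    })
    kept = matrix.subset_features(matrix.values.index[passed])
    return kept, report


def quantile_normalize(matrix: AbundanceMatrix) -> AbundanceMatrix:
    """Quantile-normalize the biological columns of a raw matrix.

    Each column's sorted values are replaced by the across-column means
    of the order statistics; tied values within a column receive the
    average of the reference values at their tied rank positions.
    Non-biological (TQC/blank) columns are left untouched.
    """
    bio = matrix.sample_ids("biological")
    if len(bio) < 2:
        raise PipelineError("quantile normalization requires >=2 biological samples")
    sub = matrix.values[bio].to_numpy(dtype=float)
    n, k = sub.shape
    order = np.argsort(sub, axis=0, kind="stable")
    reference = np.sort(sub, axis=0).mean(axis=1)

    out = np.empty_like(sub)
    for j in range(k):
        col = sub[:, j]
        idx = order[:, j]
        normed = np.empty(n)
        normed[idx] = reference
        # ties: average reference values over each run of equal inputs
        sorted_col = col[idx]
        start = 0
        for end in range(1, n + 1):
            if end == n or sorted_col[end] != sorted_col[start]:
                if end - start > 1:
                    normed[idx[start:end]] = reference[start:end].mean()
                start = end
        out[:, j] = normed

    values = matrix.values.copy()
    values[bio] = out
    return matrix.copy_with(values)


def log_transform(matrix: AbundanceMatrix, offset: float = 1.0) -> AbundanceMatrix:
    """log2(x + offset); marks the matrix as log-scale."""
    vals = matrix.values.to_numpy()
    if (vals < 0).any():
        raise PipelineError("log transform requires non-negative values")
    return matrix.copy_with(np.log2(matrix.values + offset), "log")


def adjust_donor_effects(matrix: AbundanceMatrix) -> AbundanceMatrix:
    """Remove inter-individual effects by taking residuals on donor.

    Per lipid, fits abundance ~ donor indicators by least squares and
    keeps the residuals, which equals subtracting each donor's mean.
    Operates on (and returns) biological samples only.
    """
    bio = matrix.biological()
    donors = bio.samples["donor_id"]
    if donors.isna().any():
        raise PipelineError("every biological sample needs a donor_id")
    centered = bio.values.sub(
        bio.values.T.groupby(donors).transform("mean").T
    )
    return bio.copy_with(centered, "residual")


def zscore_rows(matrix: AbundanceMatrix) -> AbundanceMatrix:
    """Per-lipid z-score: (x - mean) / sample sd; constant rows map to 0."""
    m = matrix.values.mean(axis=1)
    sd = matrix.values.std(axis=1, ddof=1)
    const = sd == 0
    if const.any():
        warnings.warn(f"{int(const.sum())} constant row(s) z-scored to 0")
        sd = sd.mask(const, 1.0)
    z = matrix.values.sub(m, axis=0).div(sd, axis=0)
    return matrix.copy_with(z, "zscore")


def transform_time(t):
    """Time transform used on the GP input grid: sqrt(t) + 2 (t in hours)."""
    t = np.asarray(t, dtype=float)
    if (t < 0).any():
        raise PipelineError("negative time")
    out = np.sqrt(t) + 2.0
    return float(out) if out.ndim == 0 else out
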