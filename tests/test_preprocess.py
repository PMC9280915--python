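"""QC filtering, CV computation, normalization and transforms."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lipidyn.io import PipelineError
from lipidyn.preprocess import (
    adjust_donor_effects,
    compute_cv_table,
    cv_percent,
    log_transform,
    qc_filter,
    quantile_normalize,
    transform_time,
    zscore_rows,
)

from conftest import make_matrix


# --- cv_percent ------------------------------------------------------------

@pytest.mark.parametrize("values,expected", [
    ([5, 5, 5], 0.0),
    ([2, 4], 100 * np.sqrt(2) / 3),     # 47.1405%
    ([98, 102, 100], 2.0),
])
def test_cv_percent_worked_examples(values, expected):
    assert cv_percent(values) == pytest.approx(expected, abs=1e-10)


def test_cv_percent_contracts():
    with pytest.raises(PipelineError):
        cv_percent([1.0])
    with pytest.raises(PipelineError, match="mean"):
        cv_percent([-1.0, 1.0])


# --- qc_filter -------------------------------------------------------------

def _qc_matrix(tqc_rows, blank_rows):
    """3 lipids x (2 bio + 3 tqc + 1 blank)."""
    bio = np.full((len(tqc_rows), 2), 100.0)
    vals = np.hstack([bio, np.asarray(tqc_rows, float), np.asarray(blank_rows, float)])
    return make_matrix(
        vals, donors=("A",), times=(0.0, 1.0),
        extra=[("Q1", "tqc"), ("Q2", "tqc"), ("Q3", "tqc"), ("B1", "blank")],
    )


def test_qc_filter_rules():
    # L0: TQC CV ~35% -> dropped; L1: blank at 15% of TQC -> dropped; L2: clean
    m = _qc_matrix(
        tqc_rows=[[65, 100, 135], [100, 100, 100], [99, 100, 101]],
        blank_rows=[[0], [15], [0]],
    )
    kept, report = qc_filter(m, cv_max=30.0, blank_max=0.10)
    assert list(kept.values.index) == ["L2"]
    assert report.loc["L0", "reason"] == "high_tqc_cv"
    assert report.loc["L1", "reason"] == "present_in_blank"
    assert report.loc["L2", "reason"] == "ok"
    assert report.loc["L1", "blank_fraction_of_tqc"] == pytest.approx(0.15)


def test_qc_filter_idempotent():
    m = _qc_matrix(
        tqc_rows=[[65, 100, 135], [100, 100, 100], [99, 100, 101]],
        blank_rows=[[0], [15], [0]],
    )
    once, _ = qc_filter(m)
    twice, rep = qc_filter(once)
    pd.testing.assert_frame_equal(once.values, twice.values)
    assert rep["pass"].all()


def test_qc_filter_requires_tqc():
    m = make_matrix([[1, 2, 3, 4]])
    with pytest.raises(PipelineError, match="TQC"):
        qc_filter(m)


def test_cv_table_flags_zero_mean():
    m = make_matrix([[0, 5, 0, 5], [1, 2, 3, 4]], donors=("A", "B"), times=(0.0, 3.0),
                    extra=[("Q1", "tqc"), ("Q2", "tqc")])
    m.values[["Q1", "Q2"]] = 1.0
    tab = compute_cv_table(m)
    assert not tab.loc["L0", "cv_defined"]
    assert tab.loc["L1", "cv_defined"]


# --- quantile normalization ------------------------------------------------

def test_quantile_normalize_worked_example():
    m = make_matrix(np.array([[1, 4], [2, 5], [3, 6]]), donors=("A",), times=(0.0, 1.0))
    out = quantile_normalize(m)
    expected = np.array([[2.5, 2.5], [3.5, 3.5], [4.5, 4.5]])
    np.testing.assert_allclose(out.values.to_numpy(), expected)


def test_quantile_normalize_identical_columns_unchanged():
    m = make_matrix(np.array([[1, 1], [5, 5], [3, 3]]), donors=("A",), times=(0.0, 1.0))
    out = quantile_normalize(m)
    np.testing.assert_allclose(out.values.to_numpy(), m.values.to_numpy())


def test_quantile_normalize_tie_handling():
    # ties get the mean of the reference values at the tied ranks
    m = make_matrix(np.array([[1, 1], [1, 2], [2, 3]]), donors=("A",), times=(0.0, 1.0))
    out = quantile_normalize(m)
    ref = np.array([1.0, 1.5, 2.5])
    col1 = out.values.iloc[:, 0].to_numpy()
    np.testing.assert_allclose(sorted(col1), [1.25, 1.25, 2.5])
    np.testing.assert_allclose(out.values.iloc[:, 1].to_numpy(), ref)


@settings(max_examples=25, deadline=None, derandomize=True)
@given(st.integers(0, 2 ** 31 - 1))
def test_quantile_normalize_equalises_sorted_columns(seed):
    rng = np.random.default_rng(seed)
    vals = rng.uniform(0, 100, size=(8, 4))
    m = make_matrix(vals, donors=("A", "B"), times=(0.0, 1.0))
    out = quantile_normalize(m).values.to_numpy()
    ref = np.sort(out[:, 0])
    for j in range(1, out.shape[1]):
        np.testing.assert_allclose(np.sort(out[:, j]), ref, atol=1e-12)
    # rank order within columns preserved
    for j in range(out.shape[1]):
        assert (np.argsort(vals[:, j], kind="stable")
                == np.argsort(out[:, j], kind="stable")).all()


# --- log / donor / z-score / time -----------------------------------------

def test_log_transform_values():
    m = make_matrix([[0, 1, 7, 3]])
    out = log_transform(m)
    np.testing.assert_allclose(out.values.to_numpy(), [[0, 1, 3, 2]])
    assert out.transform_state == "log"


def test_adjust_donor_effects_examples():
    m = make_matrix([[1, 2, 3, 4]], donors=("A", "B"), times=(0.0, 1.0),
                    transform_state="log")
    out = adjust_donor_effects(m)
    np.testing.assert_allclose(out.values.to_numpy(), [[-0.5, 0.5, -0.5, 0.5]])
    assert out.transform_state == "residual"

    single = make_matrix([[1, 5]], donors=("A",), times=(0.0, 1.0), transform_state="log")
    np.testing.assert_allclose(
        adjust_donor_effects(single).values.to_numpy(), [[-2, 2]]
    )
    const = make_matrix([[3, 3, 3, 3]], donors=("A", "B"), times=(0.0, 1.0),
                        transform_state="log")
    np.testing.assert_allclose(adjust_donor_effects(const).values.to_numpy(), 0.0)


def test_adjust_donor_effects_sums_to_zero_per_donor(rng):
    m = make_matrix(rng.normal(5, 1, size=(6, 10)), donors=("A", "B"),
                    times=(0, 0.5, 3, 8, 16), transform_state="log")
    out = adjust_donor_effects(m)
    donors = out.samples["donor_id"]
    for d in donors.unique():
        cols = donors.index[donors == d]
        np.testing.assert_allclose(out.values[cols].sum(axis=1), 0.0, atol=1e-10)


def test_zscore_rows():
    m = make_matrix([[1, 2, 3], [7, 7, 7]], donors=("A",), times=(0, 1, 2),
                    transform_state="residual")
    with pytest.warns(UserWarning, match="constant"):
        out = zscore_rows(m)
    np.testing.assert_allclose(out.values.to_numpy()[0], [-1, 0, 1])
    np.testing.assert_allclose(out.values.to_numpy()[1], 0.0)


def test_transform_time():
    assert transform_time(0.0) == 2.0
    assert transform_time(16.0) == 6.0
    np.testing.assert_allclose(transform_time([0, 4]), [2, 4])
    with pytest.raises(PipelineError):
        transform_time(-1.0)
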