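import numpy as np
import pandas as pd
import pytest

from lipidyn.io import AbundanceMatrix


def make_samples(donors, times, extra=None):
    """Sample table for a full donors x times biological design."""
    rows = []
    for d in donors:
        for t in times:
            rows.append((f"{d}_T{t:g}", d, float(t), "biological"))
    for sid, stype in extra or []:
        rows.append((sid, None, np.nan, stype))
    df = pd.DataFrame(rows, columns=["sample_id", "donor_id", "time_hours", "sample_type"])
    return df.set_index("sample_id")


def make_matrix(values, lipid_classes=None, donors=("A", "B"), times=(0.0, 1.0),
                extra=None, transform_state="raw"):
    """AbundanceMatrix from a 2-D array; columns follow make_samples order."""
    values = np.atleast_2d(np.asarray(values, dtype=float))
    samples = make_samples(donors, times, extra)
    if values.shape[1] < len(samples):  # pad QC columns with ones
        pad = np.ones((values.shape[0], len(samples) - values.shape[1]))
        values = np.hstack([values, pad])
    fids = [f"L{i}" for i in range(values.shape[0])]
    features = pd.DataFrame(
        {"lipid_class": lipid_classes or ["PC"] * len(fids)}, index=fids
    )
    vals = pd.DataFrame(values, index=fids, columns=samples.index)
    return AbundanceMatrix(vals, features, samples, transform_state)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
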