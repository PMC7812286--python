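import numpy as np
import pandas as pd
import pytest

from dnbtip.datamodel import ExpressionDataset, SampleSheet
from dnbtip.dnb import AdjustedMatrix


@pytest.fixture
def tiny_dataset():
    """3 genes x 4 samples, log2 scale, with a minimal valid sheet."""
    values = pd.DataFrame(
        [[1.0, 2.0, 3.0, 4.0], [2.0, 4.0, 6.0, 8.0], [1.0, 1.0, 2.0, 1.5]],
        index=["g1", "g2", "g3"],
        columns=["s1", "s2", "s3", "s4"],
    )
    return ExpressionDataset(values, scale="log2")


def make_sheet(treated_times, reps_treated, control_times=(), reps_control=3):
    rows = []
    for t in treated_times:
        for r in range(reps_treated):
            rows.append((f"T{t:02d}_r{r + 1}", "treated", t))
    for t in control_times:
        for r in range(reps_control):
            rows.append((f"C{t:02d}_r{r + 1}", "control", t))
    return SampleSheet(pd.DataFrame(rows, columns=["sample_id", "group", "time"]))


@pytest.fixture
def sheet_factory():
    return make_sheet


def adjusted_from_array(values, treated_times, reps):
    """Wrap a raw genes x (times*reps) array as an AdjustedMatrix whose
    sheet has the given balanced treated design (no controls needed)."""
    sheet = make_sheet(treated_times, reps, control_times=())
    cols = [f"T{t:02d}_r{r + 1}" for t in treated_times for r in range(reps)]
    values = np.asarray(values, dtype=float)
    genes = [f"g{i + 1:03d}" for i in range(values.shape[0])]
    df = pd.DataFrame(values, index=genes, columns=cols)
    return AdjustedMatrix(df, pd.Series(0.0, index=genes), sheet)


@pytest.fixture
def adjusted_factory():
    return adjusted_from_array
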