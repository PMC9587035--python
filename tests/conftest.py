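import numpy as np
import pandas as pd
import pytest

from refstab.data_io import CqTable


def make_cq(values, genes=None, samples=None, meta=None, **meta_cols):
    """Small CqTable from a 2-D array with sensible default metadata."""
    values = np.asarray(values, dtype=float)
    genes = genes or [f"G{i + 1}" for i in range(values.shape[0])]
    samples = samples or [f"S{j + 1}" for j in range(values.shape[1])]
    if meta is None:
        meta = pd.DataFrame({"plate": ["P1"] * len(samples)}, index=samples)
        for col, vals in meta_cols.items():
            meta[col] = list(vals)
    return CqTable(pd.DataFrame(values, index=genes, columns=samples), meta)


@pytest.fixture
def rng():
    return np.random.default_rng(20231005)


@pytest.fixture
def toy_table(rng):
    """5 genes x 8 samples, mild noise, two plates."""
    cq = 20 + np.arange(5)[:, None] + rng.normal(0, 0.2, (5, 8))
    samples = [f"S{j + 1}" for j in range(8)]
    meta = pd.DataFrame(
        {
            "plate": ["P1"] * 4 + ["P2"] * 4,
            "fio2": [0.21] * 8,
            "rin": [7.0] * 8,
            "pnd": [2.5, 2.5, 5.5, 5.5, 5.5, 21.0, 21.0, 21.0],
            "stage": ["PND2.5"] * 2 + ["PND5.5"] * 3 + ["PND14.5-28.5"] * 3,
            "sex": ["M", "F"] * 4,
        },
        index=samples,
    )
    return CqTable(
        pd.DataFrame(cq, index=[f"G{i + 1}" for i in range(5)], columns=samples),
        meta,
    )
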