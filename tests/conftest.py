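import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

settings.register_profile("repro", derandomize=True, deadline=None)
settings.load_profile("repro")

from vivoplan.data_model import CovariateTable
from vivoplan.dissimilarity import DissimilarityMatrix


def random_dissimilarity(rng: np.random.Generator, n: int) -> DissimilarityMatrix:
    """Symmetric zero-diagonal matrix of uniform(0,1) distances."""
    A = rng.random((n, n))
    D = (A + A.T) / 2.0
    np.fill_diagonal(D, 0.0)
    return DissimilarityMatrix(D)


@pytest.fixture
def rng():
    return np.random.default_rng(20160802)


@pytest.fixture
def small_covariates():
    """Six units, two numeric covariates and one categorical, two batches."""
    data = pd.DataFrame(
        {
            "weight": [24.0, 25.5, 23.8, 26.1, 24.9, 25.2],
            "psa": [10.0, 14.0, 11.5, 18.0, 12.2, 15.5],
            "sex": ["m", "m", "f", "f", "m", "f"],
        },
        index=pd.Index([f"m{i:02d}" for i in range(1, 7)], name="unit_id"),
    )
    batch = pd.Series(["A", "A", "A", "B", "B", "B"], index=data.index)
    return CovariateTable(data, {"weight": "numeric", "psa": "numeric", "sex": "categorical"}, batch)


@pytest.fixture
def long_rows():
    """Two units, three time points each, two arms, linear responses."""
    rows = []
    for uid, arm, slope in [("m01", "Vehicle", 2.0), ("m02", "Treat", 1.0)]:
        for t in range(3):
            rows.append((uid, t, 10.0 + slope * t, arm))
    return pd.DataFrame(rows, columns=["unit_id", "time", "response", "arm"])
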