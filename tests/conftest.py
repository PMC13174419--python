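import numpy as np
import pandas as pd
import pytest

from ccmetab.datamodel import IntensityMatrix


def make_matrix(values, conditions, metabolites=None, samples=None,
                scale="raw", kegg_ids=None):
    """Build an IntensityMatrix from a 2-D array and condition labels."""
    values = np.asarray(values, dtype=float)
    n_met, n_samp = values.shape
    metabolites = metabolites or [f"m{i + 1}" for i in range(n_met)]
    samples = samples or [f"s{j + 1}" for j in range(n_samp)]
    cond = pd.Series(list(conditions), index=samples, name="condition")
    kegg = None
    if kegg_ids is not None:
        kegg = pd.Series(list(kegg_ids), index=metabolites, name="kegg_id")
    return IntensityMatrix(
        values=pd.DataFrame(values, index=metabolites, columns=samples),
        condition=cond, kegg_ids=kegg, scale=scale,
    )


@pytest.fixture
def tiny_matrix():
    """4 metabolites x 6 samples, two conditions, one missing cell."""
    vals = [
        [10.0, 11.0, 12.0, 20.0, 21.0, 22.0],
        [5.0, 6.0, np.nan, 5.5, 6.5, 7.5],
        [100.0, 110.0, 90.0, 30.0, 35.0, 25.0],
        [1.0, 1.0, 1.0, 1.0, 1.0, 1.0],
    ]
    return make_matrix(vals, ["ctrl"] * 3 + ["tumor"] * 3)
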