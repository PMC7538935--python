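import numpy as np
import pandas as pd
import pytest

from oxiseq import CountMatrix, SampleTable


@pytest.fixture
def design8() -> SampleTable:
    """The standard 2 condition x 2 fraction x 2 replicate layout."""
    rows = []
    for cond in ("CA", "FA"):
        for frac, tag in (("input", "IN"), ("IP", "IP")):
            for rep in (1, 2):
                rows.append(
                    {
                        "sample_id": f"{cond}_{tag}_{rep}",
                        "condition": cond,
                        "fraction": frac,
                        "replicate": rep,
                    }
                )
    return SampleTable(pd.DataFrame(rows))


@pytest.fixture
def make_counts(design8):
    """Factory: wrap an (n x 8) array into a CountMatrix on the 2x2x2 design."""

    def _make(values, ids=None) -> CountMatrix:
        arr = np.asarray(values, float)
        if ids is None:
            ids = [f"T{i}" for i in range(arr.shape[0])]
        df = pd.DataFrame(arr, index=pd.Index(ids, name="transcript_id"),
                          columns=design8.sample_ids)
        return CountMatrix(df, design8)

    return _make


@pytest.fixture
def random_counts(make_counts):
    """A moderately sized random count matrix (no planted structure)."""
    rng = np.random.default_rng(42)
    return make_counts(rng.poisson(100, size=(50, 8)).astype(float))
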