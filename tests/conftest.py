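import numpy as np
import pandas as pd
import pytest

from surftarget.proteomics import NSAFMatrix, SpectralCountMatrix


@pytest.fixture
def toy_counts() -> SpectralCountMatrix:
    """Two proteins x two samples with unequal lengths."""
    counts = pd.DataFrame(
        {"s1": [10, 10], "s2": [4, 6]}, index=["P1", "P2"]
    )
    return SpectralCountMatrix(
        counts=counts,
        lengths=pd.Series([100, 300], index=["P1", "P2"]),
        gene_symbols=pd.Series(["GA", "GB"], index=["P1", "P2"]),
        sample_groups={"s1": "tumor", "s2": "tumor"},
    )


def make_nsaf(values: pd.DataFrame, groups: dict[str, str]) -> NSAFMatrix:
    """Build a valid NSAFMatrix from raw positive weights (normalized here)."""
    detected = values > 0
    norm = values.div(values.sum(axis=0).where(values.sum(axis=0) > 0, 1.0), axis=1)
    symbols = pd.Series(values.index.astype(str), index=values.index)
    return NSAFMatrix(values=norm, detected_mask=detected, gene_symbols=symbols, sample_groups=groups)
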