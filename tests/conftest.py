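import numpy as np
import pandas as pd
import pytest

from tohscan.core import GenotypeMatrix


def make_markers(n, chrom="chr1", spacing=10):
    return pd.DataFrame(
        {
            "chrom": [chrom] * n,
            "snp_id": [f"{chrom}_s{i}" for i in range(n)],
            "bp": np.arange(1, n + 1) * spacing,
        }
    )


def make_matrix(calls, chrom="chr1"):
    """Wrap a raw call array into a GenotypeMatrix with generic metadata."""
    calls = np.asarray(calls, dtype=np.int8)
    n, m = calls.shape
    samples = pd.DataFrame(
        {
            "sample_id": [f"ind_{i}" for i in range(n)],
            "sex": [i % 2 for i in range(n)],
            "phenotype": [1 if i < n // 2 else 0 for i in range(n)],
        }
    )
    return GenotypeMatrix(calls=calls, samples=samples, markers=make_markers(m, chrom))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_markers():
    return make_markers(300)
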