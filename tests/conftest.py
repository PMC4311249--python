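import numpy as np
import pytest

from ncmce import GenotypeMatrix


@pytest.fixture
def tiny_genotypes() -> GenotypeMatrix:
    """2 x 2 integer-coded matrix with one missing cell."""
    return GenotypeMatrix(
        np.array([[0.0, 3.0], [1.0, 2.0]]), ["s1", "s2"], ["snpA", "snpB"]
    )


@pytest.fixture
def labelled_genotypes() -> GenotypeMatrix:
    """4 samples in two populations, 3 SNPs, no missing data."""
    values = np.array(
        [[0.0, 2.0, 1.0], [2.0, 0.0, 1.0], [2.0, 2.0, 0.0], [0.0, 0.0, 2.0]]
    )
    ids = ["a1", "a2", "b1", "b2"]
    labels = {"a1": "P1", "a2": "P1", "b1": "P2", "b2": "P2"}
    return GenotypeMatrix(values, ids, ["s1", "s2", "s3"], labels=labels)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
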