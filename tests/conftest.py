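import numpy as np
import pandas as pd
import pytest

from longreml.genotype import GenotypeMatrix


def make_genotypes(dosages, chrom=None):
    """GenotypeMatrix from a raw array, with minimal metadata."""
    dosages = np.asarray(dosages, dtype=float)
    n, m = dosages.shape
    snp_meta = pd.DataFrame(
        {
            "chrom": chrom if chrom is not None else np.ones(m, dtype=int),
            "snp_id": [f"snp{j + 1}" for j in range(m)],
            "cm": 0.0,
            "pos": np.arange(1, m + 1) * 1000,
            "a1": "A",
            "a2": "G",
        }
    )
    sample_meta = pd.DataFrame(
        {
            "fid": [f"f{i + 1}" for i in range(n)],
            "iid": [f"s{i + 1}" for i in range(n)],
            "father": 0,
            "mother": 0,
            "sex": 1 + (np.arange(n) % 2),
            "phenotype": -9,
        }
    )
    return GenotypeMatrix(dosages, snp_meta, sample_meta)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def tiny_genotypes():
    """3 subjects x 4 SNPs with one missing call."""
    d = np.array(
        [
            [0.0, 1.0, 2.0, 1.0],
            [2.0, np.nan, 0.0, 0.0],
            [1.0, 1.0, 2.0, 2.0],
        ]
    )
    return make_genotypes(d)
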