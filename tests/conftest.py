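import numpy as np
import pandas as pd
import pytest

from genesetgxe.datasets import GenotypeDataset


def make_dataset(genotypes, chrom=None, pos=None, ids=None) -> GenotypeDataset:
    """Wrap a raw dosage matrix in a GenotypeDataset with a simple map."""
    genotypes = np.asarray(genotypes, dtype=float)
    n, m = genotypes.shape
    variants = pd.DataFrame(
        {
            "variant_id": ids if ids is not None else [f"v{j + 1}" for j in range(m)],
            "chrom": chrom if chrom is not None else np.ones(m, dtype=int),
            "pos": pos if pos is not None else 1000 * (np.arange(m) + 1),
            "a1": "A",
            "a2": "G",
        }
    )
    samples = pd.DataFrame(
        {"fid": [f"f{i}" for i in range(n)], "iid": [f"s{i}" for i in range(n)]}
    )
    return GenotypeDataset(genotypes, variants, samples)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
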