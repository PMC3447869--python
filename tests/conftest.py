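import numpy as np
import pytest

from founderdrift.datasets import load_locus_summaries
from founderdrift.popgen import GenotypeTable


@pytest.fixture(scope="session")
def locus_table():
    """Packaged per-locus diversity values for Finland and Oklahoma."""
    return load_locus_summaries()


@pytest.fixture()
def rng():
    return np.random.default_rng(20260921)


@pytest.fixture()
def small_table():
    """4 individuals x 2 loci; one heterozygote pattern and one missing slot."""
    alleles = np.array([
        [[1, 2], [1, 1]],
        [[1, 2], [1, 2]],
        [[2, 2], [0, 0]],  # missing at locus B
        [[1, 2], [2, 2]],
    ])
    return GenotypeTable(loci=["A", "B"], alleles=alleles, population="toy")
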