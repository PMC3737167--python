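import numpy as np
import pandas as pd
import pytest

from radpopgen import simdata
from radpopgen.genotyping import call_matrix


@pytest.fixture(scope="session")
def small_config():
    return simdata.SimConfig(
        n_loci=400, n_divergent=20, n_psv=15, seed=101,
        n_per_pop=30,
    )


@pytest.fixture(scope="session")
def small_dataset(small_config):
    return simdata.simulate_dataset(small_config)


@pytest.fixture(scope="session")
def small_called(small_dataset):
    return call_matrix(small_dataset.read_counts, small_dataset.genotypes.metadata)


def make_matrix(calls, populations=None, dh_flags=None,
                loci=None, individuals=None):
    """Hand-build a GenotypeMatrix from an int array of codes."""
    from radpopgen.core import GenotypeMatrix

    calls = np.asarray(calls, dtype=np.int8)
    n_loci, n_ind = calls.shape
    individuals = individuals or [f"i{k}" for k in range(n_ind)]
    loci = loci or [f"L{k}" for k in range(n_loci)]
    populations = populations or ["pop1"] * n_ind
    dh_flags = dh_flags or [False] * n_ind
    meta = pd.DataFrame(
        {"population": populations,
         "phenotype": populations,
         "doubled_haploid": dh_flags},
        index=pd.Index(individuals, name="individual"),
    )
    return GenotypeMatrix(loci=pd.Index(loci), individuals=meta.index,
                          calls=calls, metadata=meta)
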