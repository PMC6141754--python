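import numpy as np
import pandas as pd
import pytest

import plustree as pt


@pytest.fixture(scope="session")
def small_cohort() -> pt.CohortData:
    """Three small admixed populations with a few unmapped SNPs."""
    spec = pt.CohortSpec(
        n_populations=3,
        n_genotypes_per_pop=(45, 40, 35),
        n_ancestral_clusters=4,
        n_snps_mapped=400,
        n_snps_unmapped=8,
        n_linkage_groups=4,
        map_length_cM=100.0,
        missing_rate=0.02,
        seed=101,
    )
    return pt.simulate_cohort(spec)


@pytest.fixture(scope="session")
def unstructured_cohort() -> pt.CohortData:
    """One population, negligible structure, fast LD decay."""
    spec = pt.CohortSpec(
        n_populations=1,
        n_genotypes_per_pop=200,
        n_ancestral_clusters=2,
        admixture_concentration=[[5.0, 5.0]],
        divergence=0.05,
        recombination_block_cM=0.5,
        n_snps_mapped=500,
        n_snps_unmapped=0,
        n_linkage_groups=5,
        map_length_cM=100.0,
        missing_rate=0.0,
        seed=202,
    )
    return pt.simulate_cohort(spec)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(0)


def random_scores(rng: np.random.Generator, n: int, m: int) -> np.ndarray:
    return rng.choice([-1.0, 0.0, 1.0], size=(n, m))
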