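import numpy as np
import pandas as pd
import pytest

from mmpassoc import (
    Cohort,
    GenotypeTable,
    PhenotypeTable,
    SimulationConfig,
    SNPDef,
    simulate_cohort,
)
from mmpassoc import study


@pytest.fixture(scope="session")
def panel():
    return list(study.SNPS)


@pytest.fixture
def rng():
    return np.random.default_rng(20240915)


@pytest.fixture(scope="session")
def null_cohort():
    """Study-shaped cohort with no planted genetic effects."""
    return simulate_cohort(SimulationConfig(seed=42))


def cohort_from_counts(counts_level0, counts_level1, snp=None, outcome="status"):
    """Build a one-SNP cohort realising a 2x3 genotype count table exactly."""
    snp = snp or SNPDef("snp1", "A", "a")
    codes, status = [], []
    for level, triple in ((0, counts_level0), (1, counts_level1)):
        for code, k in zip((1, 2, 3), triple):
            codes.extend([code] * k)
            status.extend([level] * k)
    samples = [f"s{i}" for i in range(len(codes))]
    g = GenotypeTable(samples, [snp], np.array(codes, float).reshape(-1, 1))
    data = {"status": status}
    if outcome != "status":
        # everyone is a case; the stratum is the sub-phenotype
        data = {"status": [1] * len(codes), outcome: status}
    p = PhenotypeTable(pd.DataFrame(data, index=samples))
    return Cohort(g, p)
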