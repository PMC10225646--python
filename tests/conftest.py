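import numpy as np
import pandas as pd
import pytest

from gestmr.cohort import (
    CohortConfig,
    GenotypeMatrix,
    MetaboliteArchitecture,
    Relatedness,
    simulate_cohort,
    snp_ids,
)


@pytest.fixture()
def rng():
    # fresh, fixed-seed generator per test: results never depend on test order
    return np.random.default_rng(20230515)


def make_genotypes(X, chrom=None, stratum="SA"):
    """Wrap a plain dosage array into a GenotypeMatrix for unit tests."""
    X = np.asarray(X)
    n, m = X.shape
    if chrom is None:
        chrom = (np.arange(m) % 3) + 1
    snps = pd.DataFrame(
        {"chrom": chrom, "pos": np.arange(m) * 1000, "a1": "A", "a2": "G",
         "maf_target": np.nan},
        index=pd.Index(snp_ids(m), name="snp_id"),
    )
    return GenotypeMatrix(
        stratum=stratum,
        sample_ids=np.array([f"{stratum}_{i:05d}" for i in range(n)]),
        family_ids=np.array([f"F{i:05d}" for i in range(n)]),
        dosages=X.astype(np.int8),
        snps=snps,
    )


@pytest.fixture(scope="session")
def small_cohort():
    """Two-stratum cohort with one genetically driven metabolite."""
    arch = MetaboliteArchitecture(
        name="met", class_label="cls",
        causal_snps=tuple((s, 0.25) for s in snp_ids(30)[:6]),
        residual_sd=0.9,
    )
    config = CohortConfig(
        n_per_stratum=400, m_snps=30, n_chromosomes=3,
        strata=("SA", "WE"),
        maf_range_per_stratum={"SA": (0.2, 0.4), "WE": (0.25, 0.45)},
        relatedness=Relatedness(100, 0.25),
        metabolites=(arch,),
        causal_effects={"met": (0.1, 0.05)},
        confounder_loadings={"metabolites": 0.4, "fasting": 0.1, "two_hour": 0.1, "bmi": 1.5},
        seed=42,
    )
    return config, simulate_cohort(config)
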