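import numpy as np
import pytest
from hypothesis import settings

import tnmpls

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_regions():
    """Tiny TNM region table: 3 SN, 4 FPN, 4 DMN regions."""
    return tnmpls.synthetic_region_table((3, 4, 4))


@pytest.fixture(scope="session")
def small_edges(small_regions):
    return tnmpls.build_edge_index(small_regions)


@pytest.fixture(scope="session")
def cohort_1factor():
    """A 55-subject single-factor cohort at the default study conditions."""
    cfg = tnmpls.GeneratorConfig(
        n_subjects=55,
        network_sizes=(10, 15, 15),
        n_factors=1,
        phenotype_supports=[("Drinking", "Age")],
        seed=7,
    )
    return tnmpls.simulate_cohort(cfg)


@pytest.fixture(scope="session")
def cohort_domains(cohort_1factor):
    pheno, _ = tnmpls.assemble_phenotype_table(
        cohort_1factor.raw_phenotypes, cohort_1factor.pedigree
    )
    return cohort_1factor.connectivity.to_numpy(), pheno.to_numpy(), pheno
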