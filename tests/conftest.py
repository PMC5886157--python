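import numpy as np
import pytest

from dnmburden.synthetic import (CohortSimConfig, TrioSimConfig, default_gene_panel,
                                 simulate_cohort, simulate_trios)


@pytest.fixture(scope="session")
def small_trio_sim():
    """A modest noisy trio simulation shared across read-only tests."""
    cfg = TrioSimConfig(n_trios=12, n_background_sites=300, mosaic_prob=0.2,
                        sibling_prob=0.6, seed=42)
    return simulate_trios(cfg)


@pytest.fixture(scope="session")
def noiseless_trio_sim():
    """Deep, error-free trio simulation: every true DNM is recoverable."""
    cfg = TrioSimConfig(n_trios=30, dnm_rate=1.0, mean_depth=50.0, seq_error=0.0,
                        n_background_sites=400, mosaic_prob=0.15, sibling_prob=0.5,
                        seed=7)
    return simulate_trios(cfg)


@pytest.fixture(scope="session")
def small_cohort_sim():
    """Case-control cohort with a causal first gene (odds ratio 3)."""
    cfg = CohortSimConfig(n_cases=500, n_controls=800, genes=default_gene_panel(5),
                          carrier_or=3.0, n_rare_per_gene=12, n_common_per_gene=6,
                          seed=11)
    return simulate_cohort(cfg)


def trio_observations(sim, tmp_path):
    """Round-trip a simulation through VCF/PED files into observations."""
    from dnmburden import io as dio

    paths = sim.write(tmp_path)
    ped = dio.read_ped(paths["ped"])
    return dio.read_trio_vcf(paths["vcf"], ped)


@pytest.fixture(scope="session")
def noiseless_observations(noiseless_trio_sim, tmp_path_factory):
    return trio_observations(noiseless_trio_sim, tmp_path_factory.mktemp("noiseless"))


@pytest.fixture(scope="session")
def small_observations(small_trio_sim, tmp_path_factory):
    return trio_observations(small_trio_sim, tmp_path_factory.mktemp("small"))
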