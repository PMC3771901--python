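import pytest

from mitoquant import SimulationConfig, generate_psm_table


@pytest.fixture(scope="session")
def small_cfg():
    return SimulationConfig(n_proteins=60, seed=7,
                            psms_per_protein_mean=6.0,
                            psms_per_protein_min=3)


@pytest.fixture(scope="session")
def small_tables(small_cfg):
    return generate_psm_table(small_cfg)


@pytest.fixture(scope="session")
def noise_free_cfg():
    """All stochastic terms off: the forward-model limit in which the
    pipeline must recover truth exactly."""
    return SimulationConfig(n_proteins=80, seed=11,
                            noise_sigma=0.0, psm_baseline_sigma=0.0,
                            psms_per_protein_mean=6.0,
                            psms_per_protein_min=4,
                            decoy_fraction=0.0, frac_unlabeled=0.0,
                            frac_contaminant=0.0)


@pytest.fixture(scope="session")
def noise_free_tables(noise_free_cfg):
    return generate_psm_table(noise_free_cfg)
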