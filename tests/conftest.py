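import numpy as np
import pytest

from triomr import ScenarioConfig, replicate_panel, simulate_cohort, synthetic_panel


@pytest.fixture(scope="session")
def small_panel():
    """12-SNP panel for fast unit tests."""
    return replicate_panel(n_snps=12, seed=3)


@pytest.fixture(scope="session")
def mc_panel():
    """50-SNP panel used by the Monte-Carlo replicate studies."""
    return replicate_panel(n_snps=50, seed=7)


@pytest.fixture(scope="session")
def full_panel():
    """Full synthetic panel with the nested set structure (205 variants)."""
    return synthetic_panel(seed=0)


@pytest.fixture(scope="session")
def null_cohort(small_panel):
    """Small null-scenario cohort with items, dyads and a sibling block."""
    cfg = ScenarioConfig.null(n_families=300, seed=11, sib_fraction=0.1,
                              missing_father_fraction=0.2,
                              missing_mother_fraction=0.1,
                              n_outcomes=3, item_missing_rate=0.1)
    return simulate_cohort(small_panel, cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
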