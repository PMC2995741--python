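import numpy as np
import pytest

from ersig import (
    SimulationConfig,
    derive_signature,
    simulate_cohort,
    simulate_compartment_data,
)


@pytest.fixture(scope="session")
def ref_cohort():
    """Full-size reference cohort (curated labels) used for derivation tests."""
    cfg = SimulationConfig.reference_cohort(seed=11)
    matrix, clinical, truth = simulate_cohort(cfg)
    return matrix, clinical, truth


@pytest.fixture(scope="session")
def ref_compartments():
    cfg = SimulationConfig.reference_cohort(seed=11)
    comp, stromal_ids = simulate_compartment_data(cfg)
    return comp, stromal_ids


@pytest.fixture(scope="session")
def derived_signature(ref_cohort, ref_compartments):
    """Signature derived once from the reference cohort; reused across tests."""
    matrix, clinical, _ = ref_cohort
    comp, _ = ref_compartments
    return derive_signature(matrix, clinical.df["ihc_er"], comp, seed=3)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def small_config(seed: int, **overrides) -> SimulationConfig:
    """Lean cohort: few genes, full clinical structure (for survival tests)."""
    defaults = dict(n_genes=60, n_stromal_genes=5)
    defaults.update(overrides)
    return SimulationConfig(seed=seed, **defaults)
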