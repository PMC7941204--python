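import numpy as np
import pytest

from filakit.sim_core import SimConfig, simulate_assembly


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def seeded_filament_log():
    """One large filament, default growth/burst rates, no nucleation."""
    cfg = SimConfig(
        lattice_length_nt=30_000,
        nucleation_rate_const_J=0.0,
        duration_min=5.0,
        seed=7,
        initial_filaments=((12_000, 600),),
    )
    return simulate_assembly(cfg)


@pytest.fixture(scope="session")
def nucleation_only_config():
    return SimConfig(
        lattice_length_nt=10_000,
        rad51_conc=200.0,
        nucleation_rate_const_J=4.0e-7,
        add_rate_5p=0.0,
        add_rate_3p=0.0,
        off_attempt_rate=0.0,
        duration_min=1.0,
    )
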