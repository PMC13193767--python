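import pytest

from seedassay import FACILITY_MEAN_RATES, SimulationConfig


@pytest.fixture(scope="session")
def facility_means() -> dict[int, float]:
    return dict(FACILITY_MEAN_RATES)


@pytest.fixture(scope="session")
def small_pack_points(facility_means):
    """(n, mean rate) pairs for the 1-5 seed regime."""
    return [(n, m) for n, m in sorted(facility_means.items()) if n <= 5]


@pytest.fixture(scope="session")
def all_pack_points(facility_means):
    """(n, mean rate) pairs including the 20-seed packs."""
    return sorted(facility_means.items())


@pytest.fixture
def default_config() -> SimulationConfig:
    return SimulationConfig()


@pytest.fixture
def quiet_config() -> SimulationConfig:
    """No per-seed spread and no reading noise: rates are deterministic."""
    return SimulationConfig(activity_tolerance_frac=0.0, noise_rel_sd=0.0)
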