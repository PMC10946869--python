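import numpy as np
import pytest

from tptcr import simulate as sim


@pytest.fixture(scope="session")
def target_table():
    return sim.default_target_table()


@pytest.fixture(scope="session")
def complex_entry(target_table):
    return next(e for e in target_table.entries
                if e.species_name == "FABP1+bezafibrate")


@pytest.fixture(scope="session")
def globin_entry(target_table):
    return next(e for e in target_table.entries
                if e.species_name == "heme-alpha-globin")


@pytest.fixture(scope="session")
def model():
    return sim.SpectralModel()


@pytest.fixture(scope="session")
def quiet_model():
    """Noise-free spectral model for deterministic signal checks."""
    return sim.SpectralModel(noise_floor=1e-12, shot_noise_scale=0.0)


@pytest.fixture(scope="session")
def dosed_dataset(target_table, model):
    """A small dosed-2h tPTCR line-scan acquisition plus its phantom."""
    scen = sim.ScenarioConfig(scenario="dosed_2h", seed=11)
    phantom = sim.make_phantom(12, 12, scenario=scen)
    dataset = sim.acquire_line_scans(phantom, model, target_table=target_table,
                                     seed=11)
    return phantom, dataset


def assert_population_close(a, b, tol=1e-9):
    keys = set(a) | set(b)
    for k in keys:
        assert abs(a.get(k, 0.0) - b.get(k, 0.0)) <= tol, k
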