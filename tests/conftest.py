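import pytest

from nestmux import ReadLayout, SimulationConfig, analyze, simulate_run
from nestmux.examples import example_i5_set, example_i7_set, plate_sheet


@pytest.fixture(scope="session")
def i5_set():
    return example_i5_set()


@pytest.fixture(scope="session")
def i7_set():
    return example_i7_set()


@pytest.fixture(scope="session")
def i5_rules(i5_set):
    return analyze(i5_set)


@pytest.fixture(scope="session")
def i7_rules(i7_set):
    return analyze(i7_set)


@pytest.fixture(scope="session")
def layout():
    return ReadLayout()


@pytest.fixture(scope="session")
def sheet():
    """96-well sheet: 90 samples + 6 control combinations."""
    return plate_sheet(n_controls=6)


@pytest.fixture(scope="session")
def small_run(sheet, layout, i5_set, i7_set):
    """A 20k-read simulated run with 2% hopping, shared across tests."""
    config = SimulationConfig(seed=20240521, n_reads=20_000, hopping_rate=0.02)
    return config, simulate_run(config, sheet, layout, i5_set, i7_set)


@pytest.fixture(scope="session")
def clean_run(sheet, layout, i5_set, i7_set):
    """A small error-free, hop-free run: every read should decode exactly."""
    config = SimulationConfig(
        seed=7, n_reads=3_000, hopping_rate=0.0,
        index_error_rate_5p=0.0, index_error_rate_3p=0.0, body_error_rate=0.0,
    )
    return config, simulate_run(config, sheet, layout, i5_set, i7_set)
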