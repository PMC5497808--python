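import pytest

import segwave as sw


@pytest.fixture(scope="session")
def zebrafish():
    return sw.ModelParameters.zebrafish()


@pytest.fixture(scope="session")
def table1_field(zebrafish):
    """The full shortening-PSM run with the published parameter set:
    phi == 0 at t0 = -256 min, integrated to t = 500 min at dx = 1 um."""
    sc = sw.SimulationConfig(t_end=500.0, dx=1.0, L=900.0, output_stride=8)
    return sw.simulate(zebrafish, sc)


@pytest.fixture(scope="session")
def table1_obs(table1_field):
    return sw.compute_observables(table1_field)


@pytest.fixture(scope="session")
def table1_segments(table1_field):
    return sw.extract_segments(table1_field)


@pytest.fixture(scope="session")
def periodic_state(zebrafish):
    """Constant-length periodic state at xbar0 = 417 um."""
    from segwave.periodic import find_periodic_state

    return find_periodic_state(zebrafish, 417.0)
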