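import numpy as np
import pytest

from vmstrack.cleaning import Harbour
from vmstrack.synthetic import FleetScenario, ErrorRates, simulate
from vmstrack.vms_io import VmsPing, utc


def make_ping(vessel="V001", ts=None, lon=9.0, lat=43.0, speed=5.0, heading=90.0, **kw):
    return VmsPing(vessel_id=vessel, timestamp=ts or utc(2012, 6, 1, 12),
                   lon=lon, lat=lat, speed=speed, heading=heading, **kw)


@pytest.fixture
def harbours():
    return [Harbour("H1", "one", 9.99, 42.4),
            Harbour("H2", "two", 9.99, 43.0),
            Harbour("H3", "three", 9.99, 43.6)]


@pytest.fixture(scope="session")
def clean_sim():
    """Small noise-free, error-free fleet with ground truth."""
    scenario = FleetScenario(n_vessels=6, n_days=14, seed=11,
                             error_rates=ErrorRates(),
                             position_noise_deg=0.0, speed_noise_kn=0.0,
                             logbook_jitter_h=0.0)
    return simulate(scenario)


@pytest.fixture(scope="session")
def noisy_sim():
    """Default-conditions fleet (noise + injected errors), moderate size."""
    return simulate(FleetScenario(n_vessels=8, n_days=20, seed=23))


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
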