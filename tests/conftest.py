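import numpy as np
import pytest

from spiralspread.geometry import build_spiral
from spiralspread.simulate import SimConfig, simulate_replicate, simulate_experiment, thin_detections


@pytest.fixture(scope="session")
def skeleton():
    """Default 630-cm double spiral in the 60x40 box."""
    return build_spiral()


@pytest.fixture(scope="session")
def diffuse_run():
    """A small high-density run with diffuse hosts, truth plus thinned tables."""
    truth, hosts = simulate_experiment("high+diffuse", 4, seed=5)
    det = thin_detections(truth, 0.33, seed=6)
    return truth, det, hosts


@pytest.fixture(scope="session")
def homogeneous_run():
    """All-explorer walk with frozen modes: a plain Gaussian random walk."""
    cfg = SimConfig(
        n_agents=1000,
        sigma_explorer=2.0,
        initial_explorer_fraction=1.0,
        switch_re_base=0.0,
        switch_re_density_coef=0.0,
        switch_re_host_boost=0.0,
        switch_er_hazard=0.0,
        seed=3,
    )
    det, hosts = simulate_replicate(cfg)
    return cfg, det
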