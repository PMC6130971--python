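import numpy as np
import pytest

from snarefret import AnalysisConfig, SimulationConfig


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def clean_config():
    """Noise-free, leakage-free, bleach-free two-state configuration —
    the analytically transparent limit."""
    return SimulationConfig(
        noise_sigma=0.0,
        leakage={"l_da": 0.0, "l_ad": 0.0},
        donor_bleach_rate=0.0,
        acceptor_bleach_rate=0.0,
        label_efficiency=1.0,
        n_molecules_per_field=5,
        n_fields=1,
        seed=11,
    )


@pytest.fixture
def reference_config():
    """Reference assay conditions at a small molecule count: 10 Hz,
    200 s, relative noise 0.08, stochastic labeling, photobleaching."""
    return SimulationConfig(n_molecules_per_field=40, n_fields=2, seed=202)


@pytest.fixture
def analysis_config():
    return AnalysisConfig()
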