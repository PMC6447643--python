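import numpy as np
import pytest

from fpaperf.gamma_model import GammaParams
from fpaperf.synthetic import (
    build_curve_model,
    generate_dynamic_phantom,
    make_acquisition_spec,
    make_phantom,
    sample_curve,
)


@pytest.fixture
def spec45():
    """45-kg rest acquisition: 9-s injection."""
    return make_acquisition_spec(45.0, condition="rest", heart_rate=84.86, seed=7)


@pytest.fixture
def noiseless_model(spec45):
    """Noise-free b=3 curve model with 2.3-s dispersion delay."""
    return build_curve_model(
        spec45, peak_hu=640.07, b=3.0, baseline_hu=40.0, t0=8.0,
        dispersion_delay=2.3, noise_sd=0.0,
    )


@pytest.fixture
def noiseless_curve(spec45, noiseless_model):
    times = spec45.gate_times(noiseless_model.t_peak + 8.0)
    return sample_curve(noiseless_model, times)


@pytest.fixture
def exact_params():
    """Reference parameter set used across landmark/derivative tests."""
    return GammaParams(A=300.0, tau=12.0, b=3.0, C=50.0, t0=6.0)


@pytest.fixture
def small_phantom():
    return make_phantom(grid_shape=(16, 16, 8), perfusion=1.5)


@pytest.fixture
def noiseless_series(spec45, noiseless_model, small_phantom):
    return generate_dynamic_phantom(
        spec45, small_phantom, noiseless_model,
        rng=np.random.default_rng(0),
    )
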