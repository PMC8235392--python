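import numpy as np
import pytest

import thawspec as ts


@pytest.fixture(scope="session")
def default_grid():
    return ts.FrequencyGrid.default()


@pytest.fixture(scope="session")
def base_params():
    return ts.ColeParameters(r0_ohm=100.0, rinf_ohm=50.0, tau_s=1e-5, alpha=1.0)


def make_sample(params, grid, sample_id="s1", treatment="fast_thaw", time_s=0.0,
                temperature_C=4.0, noise_sd=0.0, rng=None):
    """Noiseless (or noisy) forward spectrum as an ImpedanceSample."""
    rng = rng or np.random.default_rng(0)
    return ts.synthesize_spectrum(
        params, grid, noise_sd, rng,
        sample_id=sample_id, treatment=treatment, time_s=time_s,
        temperature_C=temperature_C,
    )


@pytest.fixture(scope="session")
def small_cohort():
    """2+2 samples, default grid — cheap input for I/O and pipeline tests."""
    return ts.generate_cohort(ts.SimulatorConfig(n_fast=2, n_slow=2, seed=11))


@pytest.fixture(scope="session")
def default_cohort():
    """The full 10+10 study-design cohort (shared; treat as read-only)."""
    return ts.generate_cohort(ts.SimulatorConfig(seed=0))
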