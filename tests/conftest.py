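import numpy as np
import pytest

from thetaburst import SessionParams, generate_lfp_session

FS = 1017.0


@pytest.fixture(scope="session")
def fs():
    return FS


@pytest.fixture(scope="session")
def coupled_session():
    """One 600-s two-region session with strong MS->CA1 coupling (cached)."""
    params = SessionParams(
        duration_s=600.0,
        regions=("MS", "CA1"),
        coupling_probability=0.9,
        ms_to_ca1_delay_mean_s=0.12,
        ms_to_ca1_delay_sd_s=0.04,
        seed=8,
    )
    rec, truth = generate_lfp_session(params)
    return params, rec, truth


@pytest.fixture(scope="session")
def ca1_only_session():
    """A 300-s CA1-only session with uncoupled bursts at the default SNR."""
    params = SessionParams(
        duration_s=300.0,
        regions=("CA1",),
        burst_rate_per_min={"CA1": 6.0},
        coupling_probability=0.0,
        seed=11,
    )
    rec, truth = generate_lfp_session(params)
    return params, rec, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
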