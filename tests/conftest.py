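import pytest

from chemoscale import RunConfig, run_pipeline, simulate_cultivation


@pytest.fixture(scope="session")
def sim2l():
    """Noiseless benchtop-scale (2 L) cultivation with default kinetics."""
    return simulate_cultivation()


@pytest.fixture(scope="session")
def report2l():
    """Pipeline report for the noiseless 2 L scenario."""
    return run_pipeline(RunConfig())
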