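import time

import pytest

from tamsig import PipelineConfig, SimulationConfig, generate_cohort, run_all


@pytest.fixture(scope="session")
def default_cohort():
    """The default synthetic cohort (17 TAM / 4 pMPH / 3 MDM + refs)."""
    return generate_cohort(SimulationConfig(seed=0))


@pytest.fixture(scope="session")
def clean_cohort():
    """Default cohort without batch effects or contamination — for checks
    of the biological signal itself."""
    return generate_cohort(SimulationConfig(
        seed=0, batch_shift_sd=0.0, batch_scale_sd=0.0, contamination={}))


@pytest.fixture(scope="session")
def default_run(tmp_path_factory):
    """One full pipeline run on the default cohort, shared across tests.

    Returns (results, run directory, wall time in seconds).
    """
    out = tmp_path_factory.mktemp("default_run")
    t0 = time.perf_counter()
    results = run_all(PipelineConfig(seed=0), out)
    elapsed = time.perf_counter() - t0
    return results, out, elapsed
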