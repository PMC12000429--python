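import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from plangait.config import params_for_mode, validate_morphology
from plangait.pipeline import run_experiment
from plangait.synth import SyntheticScenario

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")

PIPELINE_SEED = 7
N_CYCLES = 120


@pytest.fixture(scope="session")
def morphology():
    return validate_morphology()


def _run(mode: str, noiseless: bool):
    scenario = SyntheticScenario(
        control=params_for_mode(mode), n_cycles=N_CYCLES, seed=PIPELINE_SEED
    )
    return run_experiment(scenario, noiseless=noiseless)


@pytest.fixture(scope="session")
def akfi_noiseless():
    return _run("AKFI", noiseless=True)


@pytest.fixture(scope="session")
def pkfi_noiseless():
    return _run("PKFI", noiseless=True)


@pytest.fixture(scope="session")
def akfi_noisy():
    return _run("AKFI", noiseless=False)


@pytest.fixture(scope="session")
def pkfi_noisy():
    return _run("PKFI", noiseless=False)


def event_errors(result, truth):
    """Per-event arrays of (detected - scheduled) %GC, aligned by cycle."""
    table = result.events.per_cycle
    idx = table["cycle"].to_numpy()
    return {
        name: table[name].to_numpy() - np.asarray(truth["events_gc"][name])[idx]
        for name in ("t_SKF", "t_SHF", "t_SAPF", "t_LLTD", "t_TO")
    }
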