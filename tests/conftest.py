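import pytest

from vasoloop import ControllerConfig, PatientParams, run_experiment

N_COHORT_SEEDS = 20
N_PAIRED_SEEDS = 5


@pytest.fixture(scope="session")
def config70() -> ControllerConfig:
    return ControllerConfig(weight_kg=70.0)


@pytest.fixture(scope="session")
def cohort_runs():
    """Closed-loop runs of the default synthetic patient over many seeds."""
    return [run_experiment(seed=s) for s in range(N_COHORT_SEEDS)]


@pytest.fixture(scope="session")
def untreated_runs():
    """Controller-disabled arms paired (by seed) with the first cohort runs."""
    return [
        run_experiment(seed=s, controller_enabled=False)
        for s in range(N_PAIRED_SEEDS)
    ]


@pytest.fixture(scope="session")
def default_run(cohort_runs):
    return cohort_runs[1]
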