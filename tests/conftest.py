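import pytest

from pgskit import SimulationConfig, run_pipeline, simulate_cohort

# Study conditions: the strong-signal cohort plants 20 genes among 2,000 in
# 400 samples with progression effect beta = 1.5; the null cohort shares the
# dimensions but has no planted signal and no progression effect.

STRONG = dict(n_samples=400, n_genes=2000, n_planted=20, progression_effect=1.5)
NULL = dict(n_samples=400, n_genes=2000, n_planted=0, progression_effect=0.0)


@pytest.fixture(scope="session")
def small_cohort():
    """A light cohort for unit-level checks."""
    return simulate_cohort(
        SimulationConfig(n_samples=120, n_genes=300, n_planted=10, seed=7)
    )


@pytest.fixture(scope="session")
def strong_cohort():
    return simulate_cohort(SimulationConfig(**STRONG, seed=1))


@pytest.fixture(scope="session")
def null_cohort():
    return simulate_cohort(SimulationConfig(**NULL, seed=1))


@pytest.fixture(scope="session")
def strong_pipeline(strong_cohort):
    c = strong_cohort
    return run_pipeline(c.expression, c.clinical, c.screen, seed=1)


@pytest.fixture(scope="session")
def null_pipeline(null_cohort):
    c = null_cohort
    return run_pipeline(c.expression, c.clinical, c.screen, seed=1)
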