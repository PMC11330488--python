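import numpy as np
import pytest

import fibrilkin as fk


@pytest.fixture(scope="session")
def study_rates() -> fk.RateConstants:
    """kappa = 0.4 1/h, lambda = 0.004 1/h at 100 uM (n2 = 0, nc = 1)."""
    return fk.default_rates()


@pytest.fixture(scope="session")
def study_traces():
    """Noisy (1%) study-condition traces: 100 uM, seeds 0 / 0.25 / 1%."""
    cfg = fk.GeneratorConfig(seed=11)
    traces, truth = fk.gen_kinetic_traces(cfg)
    return traces, truth


@pytest.fixture(scope="session")
def normalized_study_traces(study_traces):
    traces, truth = study_traces
    return [fk.normalize_trace(t) for t in traces], truth


@pytest.fixture(scope="session")
def unseeded_bulk(study_rates):
    times = np.arange(0.0, 60.25, 0.25)
    return fk.simulate_fibril_mass(study_rates, 100.0, 0.0, 0.0, times)


@pytest.fixture(scope="session")
def seeded_bulk(study_rates):
    times = np.arange(0.0, 60.25, 0.25)
    return fk.simulate_fibril_mass(study_rates, 100.0, 1.0, 1.0 / 5000.0, times)
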