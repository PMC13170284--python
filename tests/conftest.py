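import numpy as np
import pandas as pd
import pytest

import cogload as cl


@pytest.fixture(scope="session")
def small_config():
    return cl.SimulationConfig(
        n_patients=80, n_providers=10, event_vocabulary_size=40, seed=11
    )


@pytest.fixture(scope="session")
def small_study(small_config):
    return cl.simulate_study(small_config)


@pytest.fixture(scope="session")
def metrics_outcomes():
    """Provider-encounter metric rows with simulated outcomes (n=1,500)."""
    cfg = cl.SimulationConfig(n_patients=1500, n_providers=30, seed=21)
    df = cl.simulate_metrics(cfg, n_encounters=1500)
    return cl.simulate_outcomes(df, seed=22)


def make_audit_log(rows):
    """rows: (provider_id, csn, event_type, iso-timestamp) tuples."""
    return pd.DataFrame(
        {
            "provider_id": [r[0] for r in rows],
            "csn": [r[1] for r in rows],
            "event_type": [r[2] for r in rows],
            "timestamp": pd.to_datetime([r[3] for r in rows]),
        }
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
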