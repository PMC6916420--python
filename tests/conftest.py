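import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import trialsens as ts

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def table2():
    return ts.table2_fixture().table


def random_trial_tables(seed: int, count: int, max_n: int = 300):
    """Random valid tables with non-degenerate complete-case margins."""
    rng = np.random.default_rng(seed)
    tables = []
    while len(tables) < count:
        n_c, n_t = rng.integers(10, max_n, size=2)
        m_c = rng.integers(2, n_c + 1)
        m_t = rng.integers(2, n_t + 1)
        y_c = rng.integers(0, m_c + 1)
        y_t = rng.integers(0, m_t + 1)
        y_tot = y_c + y_t
        if y_tot == 0 or y_tot == m_c + m_t:
            continue
        tables.append(
            ts.TrialTable(
                y_c=int(y_c), m_c=int(m_c), n_c=int(n_c),
                y_t=int(y_t), m_t=int(m_t), n_t=int(n_t),
            )
        )
    return tables
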