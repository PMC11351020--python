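import numpy as np
import pytest

from leveltrf import stimuli, synthetic


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_session():
    """One 8-min synthetic session (2 min per level) at default noise,
    shared across tests that only need a realistic session to exist."""
    schedule = stimuli.build_trial_schedule(4, 4, seed=7)
    session = synthetic.simulate_session(schedule, seed=7)
    return schedule, session


def dense_trf_oracle(xs, y, lags):
    """Independent brute-force least squares: explicitly build the dense
    lagged design matrix (zero-padded copies) and solve the normal equations
    directly."""
    n = len(y)
    cols = []
    for x in xs:
        for lag in lags:
            c = np.zeros(n)
            if lag > 0:
                c[lag:] = x[: n - lag]
            elif lag < 0:
                c[:lag] = x[-lag:]
            else:
                c = np.asarray(x, dtype=float).copy()
            cols.append(c)
    X = np.column_stack(cols)
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    return beta.reshape(len(xs), len(lags))
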