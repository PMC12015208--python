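import numpy as np
import pandas as pd
import pytest

from heatbirth.experiments import small_sim_config
from heatbirth.synthetic import simulate


@pytest.fixture
def rng():
    return np.random.default_rng(20260921)


def make_strata(rng, n_strata, beta=0.3, sizes=(4, 5), sparse=True):
    """Random 1-case-per-stratum data with case day drawn from the model."""
    rows = []
    for s in range(n_strata):
        n = int(rng.choice(sizes))
        x = rng.normal(size=n)
        if sparse:  # AAT-like: many zero days
            x = np.maximum(x, 0.0) * (rng.random(n) < 0.5)
        p = np.exp(beta * x)
        p /= p.sum()
        case = rng.choice(n, p=p)
        for j in range(n):
            rows.append({"birth_id": s, "is_case": j == case, "x": float(x[j])})
    return pd.DataFrame(rows)


@pytest.fixture(scope="session")
def small_sim():
    """One modest simulated study, shared read-only across tests."""
    cfg = small_sim_config(
        seed=20260921, effect_log_or=float(np.log(1.05)),
        n_states=2, zctas_per_state=5, pregnancies_per_zcta=800, years=2,
    )
    return simulate(cfg, emit_grid=False)
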