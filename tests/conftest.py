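import numpy as np
import pandas as pd
import pytest

import lcsmed as L


@pytest.fixture(scope="session")
def default_trial():
    """One default synthetic trial (n=103) with its ground truth."""
    return L.generate_trial(L.SimulationConfig(seed=11))


@pytest.fixture(scope="session")
def exact_mediation_table():
    """Hand-built zero-residual mediation table with a=2, b=-1, c'=-3.

    The mediator change is 2*T plus a disturbance orthogonalized against
    the a-equation design, so the a path is exactly 2; the outcome change
    is an exact linear function of mediator change and treatment, so b
    and c' are exact.
    """
    rng = np.random.default_rng(42)
    n = 40
    arm = np.tile([0, 1], n // 2)
    m0 = rng.integers(10, 30, n).astype(float)
    y0 = rng.integers(25, 45, n).astype(float)
    X = np.column_stack([np.ones(n), arm, m0, y0])
    e_raw = rng.normal(0, 3, n)
    e = e_raw - X @ np.linalg.lstsq(X, e_raw, rcond=None)[0]  # exact orthogonality
    dm = 2.0 * arm + e
    dy = -1.0 * dm - 3.0 * arm
    return pd.DataFrame(
        {
            "id": [f"P{i}" for i in range(n)],
            "arm": arm,
            "sex": np.where(np.arange(n) % 3 == 0, "male", "female"),
            "bads_0": m0,
            "bads_3": m0 + dm,
            "bdi_0": y0,
            "bdi_3": y0 + dy,
        }
    )
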