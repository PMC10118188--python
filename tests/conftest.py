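import numpy as np
import pandas as pd
import pytest

from streambaci import default_trask_design, simulate_study


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_xy():
    """n=12, p=3 regression fixture used by the LOO and DoF oracles."""
    r = np.random.default_rng(7)
    X = r.normal(size=(12, 3))
    beta = np.array([1.0, -0.5, 0.25])
    y = X @ beta + r.normal(scale=0.5, size=12)
    return X, y


@pytest.fixture(scope="session")
def null_table():
    """Default study design, no injected effects, seed 11."""
    cfg = default_trask_design(seed=11)
    return simulate_study(cfg)


@pytest.fixture(scope="session")
def din_effect_table():
    """Default design with a 6-fold DIN increase in both clearcut groups."""
    cfg = default_trask_design(seed=1).with_effects(
        {("clearcut variable", "DIN"): 6.0, ("clearcut uniform", "DIN"): 6.0}
    )
    return simulate_study(cfg)


@pytest.fixture()
def factorial_design():
    """Balanced 4-treatment x 2-period layout (one row per site-year)."""
    from streambaci import build_design

    groups = ["clearcut variable"] * 3 + ["clearcut uniform"] * 3 + ["thinned"] + ["reference"] * 5
    rows_t, rows_p = [], []
    for g in groups:
        for period in ["pre"] * 5 + ["post"] * 4:
            rows_t.append(g)
            rows_p.append(period)
    return build_design(
        [("treatment", np.array(rows_t, dtype=object),
          ["clearcut variable", "clearcut uniform", "thinned", "reference"]),
         ("period", np.array(rows_p, dtype=object), ["pre", "post"])],
        with_interactions=True,
    )
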