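import numpy as np
import pandas as pd
import pytest

from mse_select.data_model import Design


def design_from_arrays(X, y, columns, weights=None, family="logistic",
                       exposure="x", roster=frozenset()):
    """Build a Design directly from arrays (bypasses CSV plumbing)."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(y)
    w = np.ones(n) if weights is None else np.asarray(weights, dtype=float)
    return Design(
        X=X,
        columns=tuple(columns),
        y=y,
        weights=w,
        is_actual=np.ones(n, dtype=bool),
        family=family,
        exposure=exposure,
        roster=frozenset(roster),
    )


@pytest.fixture
def toy_frame():
    """Deterministic 300-row frame: binary outcome/exposure, one forced
    binary covariate, one binary and one continuous candidate."""
    rng = np.random.default_rng(42)
    n = 300
    w1 = rng.binomial(1, 0.5, n)
    u1 = rng.binomial(1, 0.4, n)
    u2 = rng.standard_normal(n)
    from scipy.special import expit

    x = rng.binomial(1, expit(-0.2 + 0.8 * u1 + 0.3 * u2))
    y = rng.binomial(1, expit(-1.5 + 0.6 * x + 0.4 * w1 + 0.9 * u1 + 0.3 * u2))
    return pd.DataFrame({"y": y, "x": x, "w1": w1, "u1": u1, "u2": u2})


@pytest.fixture
def toy_spec():
    from mse_select import AnalysisSpec

    return AnalysisSpec(
        outcome_name="y", exposure_name="x",
        forced=("w1",), candidates=("u1", "u2"),
    )


@pytest.fixture
def separated_design():
    """Perfectly separated logistic data: y == x."""
    x = np.r_[np.zeros(10), np.ones(10)]
    X = np.column_stack([np.ones(20), x])
    return design_from_arrays(X, x.copy(), ("(intercept)", "x"))
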