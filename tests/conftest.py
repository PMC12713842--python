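import numpy as np
import pandas as pd
import pytest

from ordmediate import Dataset


@pytest.fixture
def rng():
    return np.random.default_rng(20250929)


def make_dataset(columns: dict, roles: dict, standardized=()) -> Dataset:
    return Dataset(table=pd.DataFrame(columns), roles=roles,
                   standardized=set(standardized))


@pytest.fixture
def simple_xy():
    """Tiny exposure/mediator/outcome table for structural tests."""
    rng = np.random.default_rng(7)
    n = 400
    x = rng.standard_normal(n)
    m = 0.5 * x + rng.standard_normal(n)
    eta = 0.8 * m
    g = 1.0 / (1.0 + np.exp(-(np.array([1.0, -0.5, -1.5])[None, :] + eta[:, None])))
    cells = np.column_stack([np.ones(n), g, np.zeros(n)])
    p = cells[:, :-1] - cells[:, 1:]
    u = rng.random(n)
    y = (np.cumsum(p, axis=1) < u[:, None]).sum(axis=1)
    return make_dataset(
        {"x": x, "m": m, "y": y.astype(float)},
        {"x": "exposure", "m": "mediator1", "y": "outcome"},
    )
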