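import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

import deaequity as dq

settings.register_profile(
    "ci", derandomize=True, max_examples=25, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def default_panel():
    """One default-condition synthetic panel (14 cities x 7 years)."""
    panel, truth = dq.generate(dq.GeneratorConfig(seed=20240))
    return panel, truth


@pytest.fixture()
def tiny_panel():
    """Three DMUs, one input/output, constructed by hand."""
    specs = [dq.IndicatorSpec("x", "input"), dq.IndicatorSpec("y", "output")]
    long = pd.DataFrame({
        "dmu": ["A", "C", "B"] * 2,
        "period": ["p1"] * 3 + ["p2"] * 3,
        "indicator": ["x"] * 3 + ["x"] * 3,
        "value": [2.0, 3.0, 4.0, 2.0, 3.0, 4.0],
    })
    ys = long.copy()
    ys["indicator"] = "y"
    ys["value"] = [2.0, 3.0, 2.0] * 2
    return dq.PanelDataset.from_long(pd.concat([long, ys], ignore_index=True), specs)


def make_period_frames(x_rows, y_rows, dmus=None):
    """DMU-indexed input/output frames from raw row lists."""
    x = np.atleast_2d(np.asarray(x_rows, float))
    y = np.atleast_2d(np.asarray(y_rows, float))
    dmus = dmus or [f"D{i}" for i in range(x.shape[0])]
    X = pd.DataFrame(x, index=dmus, columns=[f"x{j}" for j in range(x.shape[1])])
    Y = pd.DataFrame(y, index=dmus, columns=[f"y{j}" for j in range(y.shape[1])])
    return X, Y
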