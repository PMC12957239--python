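import numpy as np
import pytest

from ctgvision.chart_synthesis import (ChartLayout, SignalParams,
                                       render_chart, simulate_fhr,
                                       simulate_uc)


@pytest.fixture(scope="session")
def default_layout():
    return ChartLayout()


@pytest.fixture(scope="session")
def constant_chart(default_layout):
    """A rendered chart of constant FHR 140 bpm / UC 10 mmHg."""
    params = SignalParams(baseline_bpm=140, variability_amp=0, seed=7)
    fhr = simulate_fhr(params)
    uc = simulate_uc(params)
    chart, truth = render_chart(fhr, uc, default_layout)
    return chart, truth


@pytest.fixture(scope="session")
def wiggly_chart(default_layout):
    """A chart with variability, an acceleration and a contraction."""
    params = SignalParams(
        baseline_bpm=140, variability_amp=8,
        accel_events=[(300.0, 30.0, 20.0)],
        uc_events=[(200.0, 80.0, 60.0), (700.0, 70.0, 50.0)],
        seed=11)
    fhr = simulate_fhr(params)
    uc = simulate_uc(params)
    chart, truth = render_chart(fhr, uc, default_layout)
    return chart, truth


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
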