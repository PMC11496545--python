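import matplotlib

matplotlib.use("Agg")

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from protoflux import fes
from protoflux import vesicle as vs

settings.register_profile(
    "suite",
    derandomize=True,
    deadline=None,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


# ---- simulated assays (session-cached; each run is deterministic) --------

@pytest.fixture(scope="session")
def wt_acetate():
    return vs.acetate_assay("WT-Nqo13")


@pytest.fixture(scope="session")
def control_acetate():
    return vs.acetate_assay("empty")


@pytest.fixture(scope="session")
def e123q_acetate():
    return vs.acetate_assay("E123Q-Nqo13")


@pytest.fixture(scope="session")
def f1fo_atp():
    return vs.atp_competition_assay("F1Fo-only")


@pytest.fixture(scope="session")
def wt_atp():
    return vs.atp_competition_assay("WT-Nqo13")


# ---- umbrella-sampling sets ---------------------------------------------

@pytest.fixture(scope="session")
def double_well():
    return fes.ModelPotential("double_well", barrier_height=5.0, well_separation=2.0)


@pytest.fixture(scope="session")
def double_well_samples(double_well):
    windows = fes.default_windows(-1.6, 1.6, n_windows=24, n_samples=1500, seed=11)
    samples = [fes.sample_window(double_well, w) for w in windows]
    return windows, samples


@pytest.fixture(scope="session")
def wham_estimate(double_well_samples):
    windows, samples = double_well_samples
    return fes.WHAMEstimator(windows, samples).fit()


@pytest.fixture(scope="session")
def mbar_estimate(double_well_samples):
    windows, samples = double_well_samples
    return fes.MBAREstimator(windows, samples).fit()
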