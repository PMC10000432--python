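import warnings

import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from caremod.features import Protocol, Trace
from caremod.simulate import (
    CalciumSimConfig,
    ExprSimConfig,
    simulate_calcium,
    simulate_expression_pair,
)


@pytest.fixture(autouse=True)
def _quiet_numeric_warnings():
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", category=RuntimeWarning)
        warnings.filterwarnings("ignore", message=".*underdispersed.*")
        yield


@pytest.fixture(scope="session")
def default_protocol() -> Protocol:
    return Protocol(baseline_end=180.0, readdition_start=600.0, recording_end=960.0)


def make_trace(times, ratios, **meta) -> Trace:
    defaults = dict(cell_id="c1", day="d1", coverslip="cv1", line="NCM460", treatment="control")
    defaults.update(meta)
    return Trace(times=np.asarray(times, float), ratios=np.asarray(ratios, float), **defaults)


@pytest.fixture(scope="session")
def small_calcium():
    """A small noiseless-ish calcium simulation shared across tests."""
    cfg = CalciumSimConfig(
        n_days=2,
        coverslips_per_condition_day=2,
        cells_per_coverslip=4,
        sigma_day=0.0,
        sigma_coverslip=0.0,
        sigma_cell=0.0,
        sigma_noise=0.0,
        seed=0,
    )
    traces, truth = simulate_calcium(cfg)
    return cfg, traces, truth


@pytest.fixture(scope="session")
def small_expression():
    cfg = ExprSimConfig(n_genes=400, seed=3)
    return cfg, simulate_expression_pair(cfg)
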