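import dataclasses

import numpy as np
import pytest

import hutchcast as hc
from hutchcast.experiments import prepare_windows


@pytest.fixture(scope="session")
def fujian_preset():
    return hc.make_region_preset("fujian")


@pytest.fixture(scope="session")
def raw_fujian_14d(fujian_preset):
    """14 days of noisy 1-min Fujian-preset data, no artifacts."""
    cfg = hc.SimulationConfig(n_days=14, step_minutes=1, seed=1)
    return hc.simulate_house(fujian_preset, cfg)


@pytest.fixture(scope="session")
def noiseless_preset(fujian_preset):
    return dataclasses.replace(
        fujian_preset, noise_sd=np.zeros(6), ar_coefficient=0.0
    )


@pytest.fixture(scope="session")
def artifact_fixture(fujian_preset):
    """7-day table with seeded spikes and two gaps, plus its artifact log."""
    cfg = hc.SimulationConfig(
        n_days=7, step_minutes=1, seed=2,
        outlier_rate=0.01, gap_spec=[(1000, 30), (3000, 90)],
    )
    clean = hc.simulate_house(fujian_preset, cfg)
    table, log = hc.inject_artifacts(clean, cfg)
    return clean, table, log, cfg


@pytest.fixture(scope="session")
def clean_down_14d(raw_fujian_14d):
    """Masked, imputed, 10-min down-sampled version of the 14-day table."""
    masked = hc.detect_outliers(raw_fujian_14d)
    return hc.downsample_mean(hc.fill_gaps(masked), 10)


@pytest.fixture(scope="session")
def clean_down_7d(fujian_preset):
    """Smaller 7-day dataset for the harness-shape tests."""
    cfg = hc.SimulationConfig(n_days=7, step_minutes=1, seed=3)
    table = hc.simulate_house(fujian_preset, cfg)
    return hc.downsample_mean(hc.fill_gaps(hc.detect_outliers(table)), 10)


@pytest.fixture(scope="session")
def prep_48_12(clean_down_14d):
    return prepare_windows(clean_down_14d, 48, 12)


@pytest.fixture()
def smoke_config():
    return hc.ModelConfig(N=48, H=12, seed=0, **hc.SMOKE_PROFILE)


@pytest.fixture()
def tiny_config():
    """Very small architecture for equation-level and shape tests."""
    return hc.ModelConfig(N=8, H=3, L=4, d=8, n_layers=1, ffn_hidden=16, seed=0)
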