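import pandas as pd
import pytest

from cropclim.design import build_design
from cropclim.synthetic import (
    SyntheticConfig,
    gen_region_anomalies,
    gen_truth,
    gen_yield_panel,
)


def model_panel(cfg: SyntheticConfig, noise: bool = True) -> pd.DataFrame:
    """Anomaly panel with detrended response taken from the generator's truth.

    Bypasses aggregation/detrending: the response is signal + eps directly,
    which is the regime for testing the modelling stack in isolation.
    """
    truth = gen_truth(cfg)
    anoms = gen_region_anomalies(cfg)
    _, tp = gen_yield_panel(truth, anoms, cfg, noise=noise)
    tp = tp.copy()
    tp["d_yield"] = tp["signal"] + tp["eps"]
    tp.attrs["truth"] = truth
    return tp


@pytest.fixture(scope="session")
def small_cfg() -> SyntheticConfig:
    """5 regions x 20 years: fast but non-trivial."""
    return SyntheticConfig(n_regions=5, year_start=1995, year_end=2014, seed=42)


@pytest.fixture(scope="session")
def small_panel(small_cfg):
    return model_panel(small_cfg)


@pytest.fixture(scope="session")
def small_design(small_panel):
    return build_design(small_panel)


@pytest.fixture(scope="session")
def study_panel():
    """Full study conditions (25 regions x 54 years), one draw."""
    return model_panel(SyntheticConfig(seed=7))


@pytest.fixture(scope="session")
def study_design(study_panel):
    return build_design(study_panel)
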