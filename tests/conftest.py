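import numpy as np
import pandas as pd
import pytest
from hypothesis import settings, HealthCheck

import chlfpred as cp

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_config():
    """A fast two-trial study: 30 lines, 100 obs/line/trial, planted violations."""
    return cp.SimulationConfig(
        n_lines=30,
        n_markers=120,
        n_environments=2,
        obs_per_line_per_env=100,
        violation_fractions=(0.05, 0.02, 0.01),
        seed=101,
    )


@pytest.fixture(scope="session")
def small_study(small_config):
    snp = cp.generate_population(small_config)
    truth = cp.generate_true_effects(snp, small_config)
    records, planted = cp.simulate_chlf_series(truth, small_config)
    traits = cp.simulate_yield(truth, small_config)
    return {
        "config": small_config,
        "snp": snp,
        "truth": truth,
        "records": records,
        "planted": planted,
        "traits": traits,
    }


@pytest.fixture(scope="session")
def noiseless_study():
    """Noise-free records: the fitted model can interpolate the truth exactly."""
    cfg = cp.SimulationConfig(
        n_lines=12,
        n_markers=60,
        n_environments=2,
        obs_per_line_per_env=40,
        noise_sd_fqfm=0.0,
        seed=7,
    )
    snp = cp.generate_population(cfg)
    truth = cp.generate_true_effects(snp, cfg)
    records, _ = cp.simulate_chlf_series(truth, cfg)
    return cfg, truth, records
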