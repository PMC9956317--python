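import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

import strokerecovery as sr

settings.register_profile(
    "ci", derandomize=True, max_examples=50,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


@pytest.fixture(scope="session")
def noiseless_config():
    cfg = sr.BehaviorSimConfig(seed=11)
    return cfg.with_(trial_noise_sd={k: 0.0 for k in cfg.trial_noise_sd},
                     missing_rate=0.0)


@pytest.fixture(scope="session")
def noiseless_cohort(noiseless_config):
    trials, truth = sr.gen_behavior_cohort(noiseless_config)
    return trials, truth


@pytest.fixture(scope="session")
def default_cohort():
    return sr.gen_behavior_cohort(sr.BehaviorSimConfig(seed=3))


@pytest.fixture(scope="session")
def default_readouts(default_cohort):
    trials, _ = default_cohort
    return sr.daily_readouts(trials)


@pytest.fixture(scope="session")
def small_qpcr():
    """Tiny noiseless qPCR design: one cell, fold change 4 for one gene."""
    cfg = sr.QpcrSimConfig(
        genes=("Adora2a",), regions=("MOp",), hemispheres=("cl",), endpoints=(14,),
        group_fold_change={("Adora2a", "MOp", "cl", 14, "poor"): 4.0},
        efficiency_true={"Adora2a": 2.0, "Gapdh": 2.0},
        replicate_sd=0.0, animal_sd=0.0,
        n_per_group={14: {"poor": 4, "sham": 4}}, seed=5)
    return sr.gen_qpcr_dataset(cfg)
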