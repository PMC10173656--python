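"""Shared fixtures: synthetic cohorts and (session-scoped) trained models.

Training fixtures are deliberately session-scoped so the expensive fits are
paid once and reused by the coverage, monotonicity, ablation and sanity
tests.
"""

import numpy as np
import pytest

from labreduce.encounters import apply_cohort_filters, encounters_to_tensors, split_cohort
from labreduce.losses import LossConfig
from labreduce.network import ModelConfig
from labreduce.synthetic import SimConfig, calibrate_prevalence, generate_cohort
from labreduce.training import TrainConfig, train_single


@pytest.fixture(scope="session")
def small_cohort():
    """Uncalibrated 300-encounter cohort for fast structural tests."""
    return generate_cohort(SimConfig(n_encounters=300, seed=7))


@pytest.fixture(scope="session")
def small_tensors(small_cohort):
    return encounters_to_tensors(apply_cohort_filters(small_cohort))


@pytest.fixture(scope="session")
def calibrated_config():
    """Generator configuration calibrated to the study label prevalences."""
    return calibrate_prevalence(SimConfig(n_encounters=2000, seed=11), n_pilot=600)


@pytest.fixture(scope="session")
def calibrated_split(calibrated_config):
    """2000-encounter calibrated cohort, 80/20 encounter-level split."""
    cohort = apply_cohort_filters(generate_cohort(calibrated_config))
    tr, te = split_cohort(cohort, 0.8, seed=11)
    return encounters_to_tensors(tr), encounters_to_tensors(te)


@pytest.fixture(scope="session")
def trained_grid(calibrated_split):
    """One trained checkpoint per target coverage in {0.75, 0.85, 0.95}."""
    dtr, _ = calibrated_split
    out = {}
    for c in (0.75, 0.85, 0.95):
        out[c] = train_single(dtr, ModelConfig(seed=11), LossConfig(target_coverage=c),
                              TrainConfig(seed=11))
    return out


@pytest.fixture(scope="session")
def vanilla_checkpoint(calibrated_split):
    """Vanilla-LSTM ablation trained on the same cohort as `trained_grid`."""
    dtr, _ = calibrated_split
    cfg = ModelConfig(seed=11, vanilla_lstm=True, use_attention=False, use_selection=False)
    return train_single(dtr, cfg, LossConfig(target_coverage=1.0), TrainConfig(seed=11))


@pytest.fixture(scope="session")
def stable_cohort_checkpoint():
    """Model trained on a transition-free, all-normal cohort, with its test half.

    A single stably-normal class (high start offset, zero drop hazard, zero
    drift) puts every Hgb above the LBNR with no normal-to-abnormal
    transitions.
    """
    cfg = SimConfig(n_encounters=500, seed=23, class_mix=(1.0, 0.0, 0.0, 0.0),
                    hgb_start_offset=0.8, hgb_between_sd=0.3, drop_event_prob=0.0)
    cohort = apply_cohort_filters(generate_cohort(cfg))
    tr, te = split_cohort(cohort, 0.8, seed=23)
    dtr, dte = encounters_to_tensors(tr), encounters_to_tensors(te)
    ck = train_single(dtr, ModelConfig(seed=23), LossConfig(target_coverage=0.85),
                      TrainConfig(epochs=15, seed=23, patience=15))
    return ck, dte


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
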