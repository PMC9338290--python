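"""Shared fixtures: small synthetic sessions generated at test time."""

import numpy as np
import pytest

import wearbp.preprocessing as pp
import wearbp.synthetic_data as sd
from wearbp.config import GeneratorConfig, PipelineConfig


@pytest.fixture(scope="session")
def clean_cohort():
    """Four subjects, one per JNC-7 class, deterministic."""
    return sd.generate_cohort(4, (0.25, 0.25, 0.25, 0.25), seed=11)


@pytest.fixture(scope="session")
def clean_session(clean_cohort):
    """One noise-free synthetic session (waveforms + observations + truth)."""
    subject = clean_cohort[1]
    protocol = sd.default_protocol(obs_per_condition=2)
    return sd.synthesize_recording(subject, protocol, seed=21)


@pytest.fixture(scope="session")
def clean_mask(clean_session):
    return pp.assess_quality(clean_session.recording)


@pytest.fixture(scope="session")
def movement_session(clean_cohort):
    """Session with an injected 20-s movement epoch at t = 200 s."""
    cfg = GeneratorConfig(movement_epochs=((200.0, 20.0),))
    subject = clean_cohort[2]
    protocol = sd.default_protocol(obs_per_condition=2)
    return sd.synthesize_recording(subject, protocol, seed=22, config=cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture()
def small_pipeline_config(tmp_path):
    cfg = PipelineConfig(seed=3, n_subjects=8, obs_per_subject=12)
    cfg.evaluation.n_bootstrap_rmse = 500
    cfg.evaluation.n_bootstrap_mad = 200
    return cfg
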