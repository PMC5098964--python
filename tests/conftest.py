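"""Shared fixtures: synthetic trials are expensive, so they are session-scoped."""

from __future__ import annotations

import dataclasses

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from elefoot.pressure_io import PlateSpec
from elefoot.segment import SegmentationConfig, assess_completeness, segment_steps
from elefoot.synthetic import default_foot_models, default_gait_plan, generate_trial

settings.register_profile(
    "ci",
    deadline=None,
    max_examples=25,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def plate() -> PlateSpec:
    return PlateSpec()


@pytest.fixture(scope="session")
def models():
    return default_foot_models()


@pytest.fixture(scope="session")
def quiet_trial(models):
    """Noise-free default trial: four well-separated footsteps with truth."""
    plan = dataclasses.replace(default_gait_plan(seed=11), noise_sd_kpa=0.0)
    return generate_trial(models, plan)


@pytest.fixture(scope="session")
def quiet_steps(quiet_trial):
    """Segmented, completeness-assessed steps of the noise-free trial."""
    record, truth = quiet_trial
    steps = segment_steps(record, SegmentationConfig())
    for s in steps:
        s.complete_spatial, s.complete_temporal = assess_completeness(s, record)
    return steps


@pytest.fixture(scope="session")
def noisy_trial(models):
    plan = default_gait_plan(seed=11, noise_sd_kpa=1.0)
    return generate_trial(models, plan)


@pytest.fixture(scope="session")
def pipeline_bundle(tmp_path_factory):
    """One full pipeline run on the default synthetic cohort."""
    from elefoot.pipeline import PipelineConfig, run_pipeline

    out = tmp_path_factory.mktemp("pipeline") / "run"
    config = PipelineConfig(out_dir=str(out), seed=1)
    return run_pipeline(config)
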