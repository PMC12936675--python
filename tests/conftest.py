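"""Shared fixtures: a default synthetic cohort and its analysis table."""

from __future__ import annotations

import numpy as np
import pytest

from kneeqmri.cohort import generate_cohort, truth_regional_measures
from kneeqmri.config import PipelineConfig, SimulationConfig
from kneeqmri.stats import (build_analysis_table, compute_change,
                            select_control_knee)


@pytest.fixture(scope="session")
def default_cohort():
    cfg = SimulationConfig(seed=42)
    participants, truths = generate_cohort(cfg)
    return cfg, participants, truths


@pytest.fixture(scope="session")
def analysis_table(default_cohort):
    cfg, participants, truths = default_cohort
    measures = truth_regional_measures(participants, truths)
    change = compute_change(measures)
    control = select_control_knee(participants, seed=42)
    return build_analysis_table(change, control)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture()
def tiny_pipeline_config():
    """A pipeline small enough for end-to-end runs in seconds."""
    cfg = PipelineConfig()
    cfg.simulation.n_per_group = {"ACL": {"20-30": 3, "40-60": 2},
                                  "HEA": {"20-30": 3, "40-60": 3}}
    cfg.simulation.seed = 11
    cfg.analysis.seed = 11
    cfg.analysis.bootstrap_reps = 25
    cfg.n_rendered_knees = 1
    cfg.render_spacing = (0.8, 0.8, 0.25)
    return cfg.validate()
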