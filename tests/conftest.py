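"""Shared fixtures: small simulated cohorts reused across test modules.

Simulation sizes are deliberately small (few participants, reduced rep counts,
500 Hz) so the whole suite stays fast; generator defaults themselves are
exercised in dedicated tests.
"""

import numpy as np
import pytest

from fearext.pipeline import AnalysisConfig, process_participant
from fearext.schedule import DesignConfig, generate_experiment
from fearext.synthgen import GeneratorConfig, simulate_cohort, simulate_participant


@pytest.fixture(scope="session")
def small_design():
    return DesignConfig(reps_per_cue_learning=12, reps_per_cue_test=8)


@pytest.fixture(scope="session")
def default_experiment():
    return generate_experiment(seed=7)


@pytest.fixture(scope="session")
def analysis_cfg():
    return AnalysisConfig(n_perm=300, detect_artifacts=False, seed=5)


@pytest.fixture(scope="session")
def ext_cohort(small_design, analysis_cfg):
    """6 processed participants, extinction only, with planted theta and
    pattern effects in AMY and a context effect in lPFC."""
    gen = GeneratorConfig(
        sampling_rate=500.0,
        rois={"AMY": 3, "lPFC": 3},
        theta_safety_effect=1.5,
        item_pattern_gain={"AMY": 1.5},
        item_pattern_roles=("CS++",),
        context_pattern_gain={"lPFC": 1.0},
    )
    parts = simulate_cohort(6, seed=11, design=small_design, config=gen,
                            phases=("extinction",))
    return [process_participant(p, analysis_cfg) for p in parts]


@pytest.fixture(scope="session")
def full_participant(small_design):
    """One three-phase participant with item and context signatures in two ROIs."""
    gen = GeneratorConfig(
        sampling_rate=500.0,
        rois={"TMP": 3, "lPFC": 3},
        item_pattern_gain=1.2,
        context_pattern_gain=0.8,
        shared_pattern_weight=0.5,
        phase_pattern_weight=1.0,
    )
    return simulate_participant(seed=13, design=small_design, config=gen)


@pytest.fixture(scope="session")
def full_data(full_participant):
    cfg = AnalysisConfig(epoch_window=(-2.5, 2.5), detect_artifacts=False)
    return process_participant(full_participant, cfg), cfg


@pytest.fixture(scope="session")
def ratings_cohort(small_design):
    """Ratings-only cohort (12 participants) with learning onset at trial 8."""
    gen = GeneratorConfig(sampling_rate=500.0, rois={"AMY": 2})

    class RatingsOnly:
        def __init__(self, ratings):
            self.ratings = ratings

    parts = simulate_cohort(
        12, seed=3, design=small_design, config=gen,
        ratings_kwargs={"learning_onset": 8, "noise_sd": 0.4, "miss_rate": 0.05},
        phases=("extinction",),
    )
    return [RatingsOnly(p.ratings) for p in parts]


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
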