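"""Shared fixtures: a seeded random-morphology sweep and a two-class cohort.

Both are expensive to build (each beat shape is numerically calibrated), so
they are session-scoped and shared by the unit and acceptance tests.
"""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

from pulsecontour import fiducials as fid
from pulsecontour import synthwave as syn
from pulsecontour.cli import RunConfig, subject_feature_table
from pulsecontour.features import compute_beat_features

settings.register_profile("ci", deadline=None, derandomize=True)
settings.load_profile("ci")

SWEEP_SEED = 20260929
SWEEP_SIZE = 200
COHORT_SEED = 42


@pytest.fixture(scope="session")
def beat_sweep():
    """200 random dicrotic beats: (params, beat, truth, detected, features)."""
    rng = np.random.default_rng(SWEEP_SEED)
    out = []
    for _ in range(SWEEP_SIZE):
        params = syn.sample_beat_params(rng)
        beat, truth = syn.generate_beat(params)
        derivs = fid.compute_derivatives(beat)
        points = fid.refine_with_spline(beat, fid.detect_fiducials(beat, derivs))
        feats = compute_beat_features(beat, points)
        out.append((params, beat, truth, points, feats))
    return out


@pytest.fixture(scope="session")
def two_class_cohort():
    """100 subjects split between the elastic-vessel (age20) and stiff-vessel
    (age60) morphologies, with their pipeline-extracted feature table."""
    cohort = syn.generate_cohort(
        100, {"young": "age20", "old": "age60"}, seed=COHORT_SEED, duration=12.0
    )
    table = subject_feature_table(cohort, RunConfig())
    return cohort, table


@pytest.fixture(scope="session")
def stiff_cohort_table():
    """Feature table of a 50-subject stiff-vessel (age60) cohort."""
    cohort = syn.generate_cohort(50, {"age60": "age60"}, seed=11, duration=12.0)
    return subject_feature_table(cohort, RunConfig())


@pytest.fixture(scope="session")
def young_normal_table():
    """Feature table of a 20-subject textbook elastic-vessel cohort."""
    cohort = syn.generate_cohort(
        20, {"young-normal": "young-normal"}, seed=13, duration=12.0
    )
    return subject_feature_table(cohort, RunConfig())
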