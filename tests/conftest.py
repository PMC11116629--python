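"""Shared fixtures: small fast cohorts for end-to-end tests.

The "small" scenario shrinks the heart, frame and acquisition so a full
simulate -> segment -> normalise run takes seconds while keeping the same
calibrated group structure (45/65/85% trajectory, 3% mCherry survival,
55% FHF share).
"""

import numpy as np
import pytest

from heartregen import load_plate, normalize_to_control, segment_plate
from heartregen.synth import HeartModel, ImagingParams, default_scenario, simulate_cohort

SMALL_HEART = HeartModel(
    center_xy=(32.0, 28.0),
    diastolic_semi_axes=(20.0, 15.0),
    bulbus_offset_xy=(0.0, -22.0),
    bulbus_radius=5.0,
)
SMALL_IMAGING = ImagingParams(duration_s=1.0, frame_shape=(64, 64))


def small_scenario(n_larvae=3, seed=11, **overrides):
    overrides.setdefault("heart", SMALL_HEART)
    overrides.setdefault("imaging", SMALL_IMAGING)
    return default_scenario(n_larvae=n_larvae, seed=seed, **overrides)


@pytest.fixture(scope="session")
def small_cohort(tmp_path_factory):
    """A simulated 3-larvae-per-group cohort with its ground truth."""
    out = tmp_path_factory.mktemp("small-cohort")
    return simulate_cohort(small_scenario(), out / "cohort")


@pytest.fixture(scope="session")
def small_records(small_cohort):
    return load_plate(small_cohort.metadata_csv)


@pytest.fixture(scope="session")
def small_bfp_areas(small_records):
    return segment_plate(small_records, "BFP", "negative_control")


@pytest.fixture(scope="session")
def small_kinetics(small_bfp_areas):
    return normalize_to_control(small_bfp_areas, "negative_control")


@pytest.fixture
def rng():
    return np.random.default_rng(20260930)
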