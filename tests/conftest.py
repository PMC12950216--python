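"""Shared fixtures: a printed hand grid and session-scoped phantom cohorts."""

from __future__ import annotations

import numpy as np
import pytest

from ctbodycomp.io_ct import CTSlice
from ctbodycomp.metrics import compute_record
from ctbodycomp.phantom import default_spec, generate_cohort
from ctbodycomp.segmentation import segment

COHORT_SEED = 11
COHORT_SIZE = 20


def build_hand_grid() -> tuple[CTSlice, dict]:
    """12x12 grid at 1 mm spacing: square muscle ring (50 HU) with a
    diamond-cornered hole, fat (-100 HU) inside and outside, air (-1000 HU)
    beyond the body.

    Geometry (rows = cols by symmetry): body spans rows 1-10; the muscle
    ring is the rows 3-8 square minus a hole of rows 4-7 without its four
    corners — rounding the hole corners keeps a radius-1 morphological
    closing an exact identity, so labeled counts equal naive enumeration.
    """
    hu = np.full((12, 12), -1000.0)
    hu[1:11, 1:11] = -100.0
    hu[3:9, 3:9] = 50.0
    hole = np.zeros((12, 12), dtype=bool)
    hole[4:8, 4:8] = True
    for r, c in ((4, 4), (4, 7), (7, 4), (7, 7)):
        hole[r, c] = False
    hu[hole] = -100.0
    ct = CTSlice(hu=hu, spacing_mm=(1.0, 1.0), level="L3", phase=0, subject_id="grid")
    expected = {
        "muscle_px": 36 - 12,  # rows 3-8 square minus 12-px hole
        "vat_px": 12,
        "sat_px": 100 - 36,  # body minus the ring's bounding square
        "body_px": 100,
    }
    return ct, expected


@pytest.fixture
def hand_grid():
    return build_hand_grid()


@pytest.fixture(scope="session")
def default_cohort():
    """20-subject default phantom (partial-volume blur on), fixed seed."""
    return generate_cohort(default_spec(subject_count=COHORT_SIZE, seed=COHORT_SEED))


@pytest.fixture(scope="session")
def blur_off_cohort():
    """Same cohort conditions with the point spread disabled."""
    return generate_cohort(
        default_spec(subject_count=COHORT_SIZE, seed=COHORT_SEED, blur_sigma=0.0)
    )


def measure_cohort(cohort) -> list:
    """Segment and measure every slice of a phantom cohort."""
    records = []
    for subj in cohort:
        for key in sorted(subj.slices):
            ct = subj.slices[key]
            records.append(compute_record(ct, segment(ct)))
    return records


@pytest.fixture(scope="session")
def measured_records(default_cohort):
    return measure_cohort(default_cohort)


@pytest.fixture(scope="session")
def blur_off_records(blur_off_cohort):
    return measure_cohort(blur_off_cohort)


def cohort_mean_trajectory(records, parameter: str, level: str) -> list[float]:
    """Cohort-mean value of one parameter per phase 0..4."""
    out = []
    for phase in range(5):
        vals = [
            r.value(parameter)
            for r in records
            if r.level == level and r.phase == phase and r.value(parameter) is not None
        ]
        out.append(float(np.mean(vals)))
    return out
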