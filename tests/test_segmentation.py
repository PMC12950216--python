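"""Threshold windows, compartment geometry, body mask and calibration."""

import numpy as np
import pytest

from ctbodycomp.io_ct import CTSlice
from ctbodycomp.phantom import default_spec, generate_cohort
from ctbodycomp.segmentation import (
    EmptyBodyError,
    SegmentationFailure,
    ThresholdSet,
    body_mask,
    segment,
)

from _oracles import fill_holes_by_flood, flood_fill


def _slice(hu, spacing=1.0):
    return CTSlice(hu=np.asarray(hu, float), spacing_mm=(spacing, spacing),
                   level="L3", phase=0, subject_id="t")


class TestBodyMask:
    def test_hand_grid_body(self, hand_grid):
        ct, expected = hand_grid
        mask = body_mask(ct)
        assert int(mask.sum()) == expected["body_px"]

    def test_all_air_raises(self):
        with pytest.raises(EmptyBodyError):
            body_mask(_slice(np.full((8, 8), -1000.0)))

    def test_interior_air_pocket_filled(self):
        """Holes are filled: result matches a border flood-fill oracle on a
        20x20 grid with a -1000 HU pocket inside the body."""
        hu = np.full((20, 20), -1000.0)
        hu[3:17, 3:17] = 40.0
        hu[8:12, 8:12] = -1000.0  # air pocket
        mask = body_mask(_slice(hu))
        oracle = fill_holes_by_flood(hu > -200.0)
        assert np.array_equal(mask, oracle)
        # simply connected: everything not in the mask is border-reachable
        outside = flood_fill(np.pad(~mask, 1, constant_values=True), [(0, 0)])[1:-1, 1:-1]
        assert np.array_equal(outside, ~mask)


class TestSegmentHandGrid:
    def test_counts_match_enumeration(self, hand_grid):
        ct, expected = hand_grid
        seg = segment(ct, closing_mm=1.0, min_muscle_mm2=1.0)
        assert int((seg.labels == 1).sum()) == expected["muscle_px"]
        assert int((seg.labels == 2).sum()) == expected["sat_px"]
        assert int((seg.labels == 3).sum()) == expected["vat_px"]

    def test_compartments_from_flood_fill(self, hand_grid):
        """SAT is exactly the fat reachable from the border without crossing
        muscle; VAT exactly the fat that is not."""
        ct, _ = hand_grid
        seg = segment(ct, closing_mm=1.0, min_muscle_mm2=1.0)
        fat = (ct.hu >= -190) & (ct.hu <= -30) & (ct.hu >= -1000 + 1)
        passable = np.pad(~(seg.labels == 1), 1, constant_values=True)
        border_reach = flood_fill(passable, [(0, 0)])[1:-1, 1:-1]
        assert np.array_equal(seg.labels == 2, fat & border_reach & (ct.hu > -200))
        assert np.array_equal(seg.labels == 3, fat & ~border_reach)

    def test_interior_fat_outside_vat_window_labeled_zero(self, hand_grid):
        """Fat at -40 HU inside the ring is in the SAT window but not the VAT
        window: compartment membership selects the window, so it gets 0."""
        ct, expected = hand_grid
        hu = ct.hu.copy()
        interior = np.zeros_like(hu, bool)
        interior[4:8, 4:8] = True
        for r, c in ((4, 4), (4, 7), (7, 4), (7, 7)):
            interior[r, c] = False
        hu[interior] = -40.0
        seg = segment(_slice(hu), closing_mm=1.0, min_muscle_mm2=1.0)
        assert int((seg.labels[interior] == 0).sum()) == expected["vat_px"]
        assert int((seg.labels == 2).sum()) == expected["sat_px"]

    def test_no_muscle_raises(self):
        hu = np.full((12, 12), -1000.0)
        hu[2:10, 2:10] = -100.0  # fat-only body
        with pytest.raises(SegmentationFailure):
            segment(_slice(hu), closing_mm=1.0, min_muscle_mm2=1.0)


class TestThresholdSet:
    def test_defaults_are_the_noncontrast_windows(self):
        t = ThresholdSet()
        assert t.muscle == (-29.0, 150.0)
        assert t.sat == (-190.0, -30.0)
        assert t.vat == (-150.0, -50.0)

    def test_inverted_window_rejected(self):
        with pytest.raises(ValueError):
            ThresholdSet(muscle=(150.0, -29.0))


@pytest.fixture(scope="module")
def sharp_subject():
    spec = default_spec(
        subject_count=1, seed=2, blur_sigma=0.0, noise_sd=0.0,
        subject_density_sd=0.0,
        tissue_baseline_hu={"muscle": (45.0, 0.0), "sat": (-100.0, 0.0), "vat": (-92.0, 0.0)},
    )
    return generate_cohort(spec)[0]


class TestPhantomSegmentation:
    def test_noise_free_segmentation_equals_truth(self, sharp_subject):
        for level in ("L3", "L1"):
            ct = sharp_subject.slices[(level, 0)]
            seg = segment(ct)
            truth = sharp_subject.truth[(level, 0)].labels
            for lab in (1, 2, 3):
                assert np.array_equal(seg.labels == lab, truth == lab)

    def test_body_mask_equals_truth_body(self, sharp_subject):
        ct = sharp_subject.slices[("L3", 0)]
        truth = sharp_subject.truth[("L3", 0)].labels
        assert np.array_equal(body_mask(ct), truth > 0)

    def test_labeled_means_inside_windows(self, default_cohort):
        windows = {1: (-29, 150), 2: (-190, -30), 3: (-150, -50)}
        s = default_cohort[0]
        for phase in (0, 4):
            ct = s.slices[("L3", phase)]
            seg = segment(ct)
            for lab, (lo, hi) in windows.items():
                vals = ct.hu[seg.labels == lab]
                assert lo <= vals.mean() <= hi

    def test_compartment_topology_on_phantom(self, default_cohort):
        """No SAT pixel is border-unreachable and no VAT pixel is
        border-reachable when the muscle wall blocks passage."""
        ct = default_cohort[1].slices[("L3", 2)]
        seg = segment(ct)
        passable = np.pad(seg.labels != 1, 1, constant_values=True)
        border_reach = flood_fill(passable, [(0, 0)])[1:-1, 1:-1]
        assert not (border_reach & (seg.labels == 3)).any()
        assert ((seg.labels == 2) & ~border_reach).sum() == 0

    def test_dice_against_truth_at_default_conditions(self, default_cohort):
        """Segmentation recovers the phantom truth with Dice >= 0.95 for each
        tissue under the default noise and partial-volume blur."""
        for subj in default_cohort[::5]:
            for level in ("L3", "L1"):
                for phase in (0, 2, 4):
                    ct = subj.slices[(level, phase)]
                    seg = segment(ct)
                    truth = subj.truth[(level, phase)].labels
                    for lab in (1, 2, 3):
                        a = truth == lab
                        b = seg.labels == lab
                        dice = 2 * (a & b).sum() / (a.sum() + b.sum())
                        assert dice >= 0.95, (subj.subject_id, level, phase, lab, dice)
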