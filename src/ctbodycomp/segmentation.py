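"""Threshold/compartment segmentation of one axial CT slice.

Partitions a slice into skeletal muscle, subcutaneous adipose tissue (SAT),
visceral adipose tissue (VAT) and other, using fixed HU windows
(muscle [-29, 150], SAT [-190, -30], VAT [-150, -50], bounds inclusive)
combined with compartment geometry: SAT is fat between the skin and the
outer contour of the muscle wall, VAT is fat inside the muscle wall. The SAT
and VAT windows overlap; compartment membership, not HU, decides which
window applies to a fat pixel.

The muscle compartment boundary is built classically: HU-window candidates
are cleaned of small speckles, morphologically closed to bridge gaps between
muscle groups, and the largest closed component is taken as the muscle wall.
Candidate components that are not connected to this wall (e.g. boundary
voxels of enhancing parenchymal organs whose partial-volume values pass
through the muscle window) are *not* muscle and are labeled 0 — parenchymal
organs never enter any region of interest.

Array convention: (row, col), 0-based, row 0 at the image top. Label
encoding: 0 background/other, 1 muscle, 2 SAT, 3 VAT.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.morphology import disk

from .io_ct import CTSlice

LABEL_BACKGROUND = 0
LABEL_MUSCLE = 1
LABEL_SAT = 2
LABEL_VAT = 3

DEFAULT_AIR_THRESHOLD_HU = -200.0
DEFAULT_CLOSING_MM = 3.0
DEFAULT_MIN_MUSCLE_MM2 = 20.0


class EmptyBodyError(ValueError):
    """No pixel above the air threshold: there is no patient in the image."""


class SegmentationFailure(RuntimeError):
    """No closed muscle wall could be formed; the slice must be flagged."""


@dataclass(frozen=True)
class ThresholdSet:
    """Inclusive HU windows for the three tissues.

    Defaults are the standard noncontrast thresholds: skeletal muscle
    [-29, 150] HU, SAT [-190, -30] HU, VAT [-150, -50] HU.
    """

    muscle: tuple[float, float] = (-29.0, 150.0)
    sat: tuple[float, float] = (-190.0, -30.0)
    vat: tuple[float, float] = (-150.0, -50.0)

    def __post_init__(self) -> None:
        for name in ("muscle", "sat", "vat"):
            lo, hi = getattr(self, name)
            if not lo < hi:
                raise ValueError(f"{name} window must satisfy lo < hi, got {(lo, hi)}")

    def window(self, tissue: str) -> tuple[float, float]:
        return getattr(self, tissue)


DEFAULT_THRESHOLDS = ThresholdSet()


@dataclass(frozen=True)
class TissueSegmentation:
    """Mutually exclusive tissue labels aligned to the source slice.

    ``segment`` emits labels 0-3 only; label 4 (organ/other structure) is
    reserved for ground-truth masks from the phantom generator.
    """

    labels: np.ndarray
    provenance: dict = field(default_factory=dict, compare=False)

    def __post_init__(self) -> None:
        labels = np.asarray(self.labels)
        if labels.ndim != 2:
            raise ValueError(f"labels must be 2D, got shape {labels.shape}")
        if not np.isin(labels, (0, 1, 2, 3, 4)).all():
            raise ValueError("labels must be in {0, 1, 2, 3, 4}")
        object.__setattr__(self, "labels", labels.astype(np.int16))

    def mask(self, label: int) -> np.ndarray:
        return self.labels == label


def _in_window(hu: np.ndarray, window: tuple[float, float]) -> np.ndarray:
    lo, hi = window
    return (hu >= lo) & (hu <= hi)


def _drop_small_components(mask: np.ndarray, min_px: int) -> np.ndarray:
    lab, n = ndimage.label(mask)
    if n == 0:
        return mask
    sizes = np.bincount(lab.ravel())
    keep = sizes >= min_px
    keep[0] = False
    return keep[lab]


def _largest_component(mask: np.ndarray) -> np.ndarray:
    lab, n = ndimage.label(mask)
    if n == 0:
        return np.zeros_like(mask, dtype=bool)
    sizes = np.bincount(lab.ravel())
    sizes[0] = 0
    return lab == sizes.argmax()


def body_mask(ct: CTSlice, air_threshold: float = DEFAULT_AIR_THRESHOLD_HU) -> np.ndarray:
    """Patient cross-section: largest connected component above the air
    threshold (default -200 HU), interior holes filled. Its boundary is the
    skin."""
    above = ct.hu > air_threshold
    if not above.any():
        raise EmptyBodyError("no pixel above the air threshold; empty field of view")
    body = _largest_component(above)
    return ndimage.binary_fill_holes(body)


def segment(
    ct: CTSlice,
    thresholds: ThresholdSet = DEFAULT_THRESHOLDS,
    closing_mm: float = DEFAULT_CLOSING_MM,
    min_muscle_mm2: float = DEFAULT_MIN_MUSCLE_MM2,
    air_threshold: float = DEFAULT_AIR_THRESHOLD_HU,
) -> TissueSegmentation:
    """Segment one slice into muscle / SAT / VAT / other.

    Steps: (1) muscle candidates = body pixels inside the muscle window,
    components below ``min_muscle_mm2`` dropped; (2) morphological closing
    (disk of ``closing_mm``) bridges muscle groups; the largest closed
    component is the muscle wall and its filled outline is the outer muscle
    contour; (3) SAT = SAT-window pixels inside the body and strictly outside
    that contour; (4) VAT = VAT-window pixels strictly inside the wall's
    interior cavity; (5) everything else is 0. Candidate components isolated
    from the wall (organ partial-volume halos) are labeled 0, not muscle.

    Raises :class:`SegmentationFailure` when no closed muscle wall with a
    nonempty interior exists, rather than returning fat-only labels.
    """
    body = body_mask(ct, air_threshold=air_threshold)
    px_area = ct.pixel_area_mm2

    cand = body & _in_window(ct.hu, thresholds.muscle)
    min_px = max(1, int(np.ceil(min_muscle_mm2 / px_area)))
    cand = _drop_small_components(cand, min_px)

    mean_spacing = float(np.mean(ct.spacing_mm))
    radius_px = max(1, int(round(closing_mm / mean_spacing)))
    closed = ndimage.binary_closing(cand, structure=disk(radius_px))

    wall = _largest_component(closed)
    if not wall.any():
        raise SegmentationFailure("no muscle detected in the muscle HU window")
    filled = ndimage.binary_fill_holes(wall)
    interior = filled & ~wall
    if not interior.any():
        raise SegmentationFailure("muscle wall has no interior cavity")

    # keep only candidate components connected to the muscle wall
    cand_lab, n_comp = ndimage.label(cand)
    if n_comp:
        touches = np.zeros(n_comp + 1, dtype=bool)
        touched = np.unique(cand_lab[wall])
        touches[touched] = True
        touches[0] = False
        muscle = touches[cand_lab]
    else:
        muscle = np.zeros_like(cand)

    # Closing artifacts: pixels the closing added along the cavity's
    # rasterized boundary belong to the cavity, not the wall. Added
    # components touching only the interior are reclaimed; genuine bridge
    # pixels (touching the outer region too) stay part of the boundary.
    extra = wall & ~cand
    if extra.any():
        extra_lab, n_extra = ndimage.label(extra)
        outer = ~filled
        near_cavity = np.unique(extra_lab[ndimage.binary_dilation(interior) & extra])
        near_outer = np.unique(extra_lab[ndimage.binary_dilation(outer) & extra])
        reclaim = np.setdiff1d(near_cavity, near_outer)
        reclaim = reclaim[reclaim != 0]
        if reclaim.size:
            interior |= np.isin(extra_lab, reclaim)

    sat = body & ~filled & _in_window(ct.hu, thresholds.sat) & ~muscle
    vat = interior & _in_window(ct.hu, thresholds.vat) & ~muscle

    labels = np.zeros(ct.hu.shape, dtype=np.int16)
    labels[sat] = LABEL_SAT
    labels[vat] = LABEL_VAT
    labels[muscle] = LABEL_MUSCLE  # muscle wins by assignment order
    return TissueSegmentation(
        labels=labels,
        provenance={
            "thresholds": {
                "muscle": thresholds.muscle,
                "sat": thresholds.sat,
                "vat": thresholds.vat,
            },
            "closing_mm": closing_mm,
            "min_muscle_mm2": min_muscle_mm2,
            "air_threshold": air_threshold,
        },
    )
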