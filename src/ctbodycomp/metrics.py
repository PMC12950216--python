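"""Body-composition parameters from one segmented slice.

Six parameters per image: skeletal muscle area (SMA), subcutaneous and
visceral adipose tissue areas (SATA, VATA) in cm^2, and the mean density of
each tissue (MSMD, MSATD, MVATD) in HU. Areas use pixel-center counting
(each labeled pixel contributes its full physical area); densities are
arithmetic means of the labeled pixels' HU values.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io_ct import CTSlice
from .segmentation import LABEL_MUSCLE, LABEL_SAT, LABEL_VAT, TissueSegmentation

_WINDOW_BY_FIELD = {
    "msmd_hu": (-29.0, 150.0),
    "msatd_hu": (-190.0, -30.0),
    "mvatd_hu": (-150.0, -50.0),
}


class AlignmentError(ValueError):
    """Segmentation and slice shapes disagree."""


@dataclass(frozen=True)
class CompositionRecord:
    """The six body-composition parameters for one (subject, level, phase).

    Densities are ``None`` when the corresponding tissue has zero area;
    0 HU is a legal density and never stands for "absent".
    """

    subject_id: str
    level: str
    phase: int
    sma_cm2: float
    sata_cm2: float
    vata_cm2: float
    msmd_hu: float | None
    msatd_hu: float | None
    mvatd_hu: float | None

    def __post_init__(self) -> None:
        for name in ("sma_cm2", "sata_cm2", "vata_cm2"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.phase not in (0, 1, 2, 3, 4):
            raise ValueError(f"phase must be 0..4, got {self.phase}")
        if self.level not in ("L3", "L1"):
            raise ValueError(f"level must be L3 or L1, got {self.level!r}")

    def value(self, parameter: str) -> float | None:
        """Look up a parameter by its field name ('SMA', 'MVATD', ...)."""
        return getattr(self, _FIELD_BY_PARAM[parameter])


#: canonical parameter names -> record fields
_FIELD_BY_PARAM = {
    "SMA": "sma_cm2",
    "SATA": "sata_cm2",
    "VATA": "vata_cm2",
    "MSMD": "msmd_hu",
    "MSATD": "msatd_hu",
    "MVATD": "mvatd_hu",
}

AREA_PARAMETERS = ("SMA", "SATA", "VATA")
DENSITY_PARAMETERS = ("MSMD", "MSATD", "MVATD")
ALL_PARAMETERS = AREA_PARAMETERS + DENSITY_PARAMETERS


def _area_cm2(mask: np.ndarray, ct: CTSlice) -> float:
    return float(mask.sum()) * ct.pixel_area_mm2 / 100.0


def _mean_hu(mask: np.ndarray, ct: CTSlice) -> float | None:
    n = int(mask.sum())
    if n == 0:
        return None
    return float(ct.hu[mask].mean())


def compute_record(ct: CTSlice, seg: TissueSegmentation) -> CompositionRecord:
    """Measure the six parameters from a slice and its tissue segmentation.

    area = pixel count x row_spacing x col_spacing / 100 (mm^2 -> cm^2);
    density = mean HU over the labeled pixels, ``None`` for empty tissues.
    """
    if seg.labels.shape != ct.hu.shape:
        raise AlignmentError(
            f"labels shape {seg.labels.shape} != slice shape {ct.hu.shape}"
        )
    muscle = seg.labels == LABEL_MUSCLE
    sat = seg.labels == LABEL_SAT
    vat = seg.labels == LABEL_VAT
    return CompositionRecord(
        subject_id=ct.subject_id,
        level=ct.level,
        phase=ct.phase,
        sma_cm2=_area_cm2(muscle, ct),
        sata_cm2=_area_cm2(sat, ct),
        vata_cm2=_area_cm2(vat, ct),
        msmd_hu=_mean_hu(muscle, ct),
        msatd_hu=_mean_hu(sat, ct),
        mvatd_hu=_mean_hu(vat, ct),
    )


def height_index(area_cm2: float, height_m: float) -> float:
    """Height-normalized index (cm^2/m^2): area divided by height squared.

    Applied to SMA this is the skeletal muscle index (SMI); the same
    normalization applies to the fat areas.
    """
    if height_m <= 0:
        raise ValueError(f"height must be positive, got {height_m}")
    return area_cm2 / height_m**2
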