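"""Imaging and tabular I/O.

All intensities are Hounsfield units (HU); all geometry is millimetres.
Areas appear in cm^2 only inside :class:`~ctbodycomp.metrics.CompositionRecord`.
Array convention: (row, col), 0-based, row 0 at the image top.

Images travel as single-slice NIfTI-1 (.nii / .nii.gz) with pixel spacing in
the header; single-frame DICOM is read-only with the standard rescale
slope/intercept applied. Measurement records are UTF-8 CSV with a header row
and '.' decimal, one row per (subject, level, phase), areas at 0.01 cm^2 and
densities at 0.01 HU precision.
"""

from __future__ import annotations

import io
import os
from dataclasses import dataclass
from typing import Sequence

import nibabel as nib
import numpy as np
import pandas as pd

LEVELS = ("L3", "L1")
PHASES = (0, 1, 2, 3, 4)

#: fixed CSV column order for measurement records
RECORD_COLUMNS = (
    "subject_id",
    "level",
    "phase",
    "sma_cm2",
    "sata_cm2",
    "vata_cm2",
    "msmd_hu",
    "msatd_hu",
    "mvatd_hu",
)


class MetadataError(ValueError):
    """A file lacks required, trustworthy geometry metadata (e.g. spacing)."""


class AmbiguityError(ValueError):
    """A multi-slice volume was given where a single slice is required."""


class RecordParseError(ValueError):
    """A measurement CSV row violates the record invariants."""


@dataclass(frozen=True)
class CTSlice:
    """One axial CT image in HU with physical pixel spacing and study labels.

    Parameters
    ----------
    hu : 2D float array of Hounsfield units.
    spacing_mm : (row spacing, col spacing) in mm, both strictly positive.
    level : vertebral level label, "L3" or "L1".
    phase : contrast phase, 0 (unenhanced) through 4 (equilibrium).
    subject_id : examination identifier.
    """

    hu: np.ndarray
    spacing_mm: tuple[float, float]
    level: str
    phase: int
    subject_id: str = ""

    def __post_init__(self) -> None:
        hu = np.asarray(self.hu, dtype=float)
        if hu.ndim != 2:
            raise ValueError(f"hu must be 2D, got shape {hu.shape}")
        object.__setattr__(self, "hu", hu)
        rs, cs = self.spacing_mm
        if not (rs > 0 and cs > 0):
            raise MetadataError(f"pixel spacing must be positive, got {self.spacing_mm}")
        object.__setattr__(self, "spacing_mm", (float(rs), float(cs)))
        if self.level not in LEVELS:
            raise ValueError(f"level must be one of {LEVELS}, got {self.level!r}")
        if self.phase not in PHASES:
            raise ValueError(f"phase must be in {PHASES}, got {self.phase!r}")

    @property
    def pixel_area_mm2(self) -> float:
        return self.spacing_mm[0] * self.spacing_mm[1]


def _nifti_affine(spacing_mm: tuple[float, float]) -> np.ndarray:
    return np.diag([spacing_mm[0], spacing_mm[1], 1.0, 1.0])


def write_slice(ct: CTSlice, path: str | os.PathLike) -> None:
    """Write one slice as single-slice NIfTI, spacing in the header zooms."""
    img = nib.Nifti1Image(ct.hu.astype(np.float32)[:, :, None], _nifti_affine(ct.spacing_mm))
    img.header.set_zooms((ct.spacing_mm[0], ct.spacing_mm[1], 1.0))
    nib.save(img, os.fspath(path))


def write_labels(labels: np.ndarray, spacing_mm: tuple[float, float], path: str | os.PathLike) -> None:
    """Write an integer label mask (0 bg, 1 muscle, 2 SAT, 3 VAT, 4 organ/other)."""
    img = nib.Nifti1Image(np.asarray(labels, dtype=np.int16)[:, :, None], _nifti_affine(spacing_mm))
    img.header.set_zooms((spacing_mm[0], spacing_mm[1], 1.0))
    nib.save(img, os.fspath(path))


def _read_nifti(path: str) -> tuple[np.ndarray, tuple[float, float]]:
    img = nib.load(path)
    data = np.asanyarray(img.dataobj)
    data = np.squeeze(data)
    if data.ndim != 2:
        raise AmbiguityError(
            f"{path}: expected a single slice, got data of shape {np.asanyarray(img.dataobj).shape}"
        )
    zooms = img.header.get_zooms()[:2]
    if len(zooms) < 2 or not all(np.isfinite(z) and z > 0 for z in zooms):
        raise MetadataError(f"{path}: missing or non-positive pixel spacing {zooms}")
    return np.asarray(data, dtype=float), (float(zooms[0]), float(zooms[1]))


def _read_dicom(path: str) -> tuple[np.ndarray, tuple[float, float]]:
    import pydicom

    ds = pydicom.dcmread(path)
    arr = ds.pixel_array
    if arr.ndim != 2:
        raise AmbiguityError(f"{path}: multi-frame DICOM requires an explicit slice index")
    slope = float(getattr(ds, "RescaleSlope", 1.0))
    intercept = float(getattr(ds, "RescaleIntercept", 0.0))
    hu = arr.astype(float) * slope + intercept
    spacing = getattr(ds, "PixelSpacing", None)
    if spacing is None:
        raise MetadataError(f"{path}: DICOM lacks PixelSpacing; refusing to guess")
    rs, cs = float(spacing[0]), float(spacing[1])
    if not (rs > 0 and cs > 0):
        raise MetadataError(f"{path}: non-positive PixelSpacing {spacing}")
    return hu, (rs, cs)


def read_slice(path: str | os.PathLike, level: str, phase: int, subject_id: str = "") -> CTSlice:
    """Read a single-slice NIfTI or single-frame DICOM image as a :class:`CTSlice`.

    DICOM stored values are converted to HU with RescaleSlope/RescaleIntercept.
    Fails with :class:`MetadataError` rather than guessing a missing spacing.
    """
    p = os.fspath(path)
    if p.endswith(".nii") or p.endswith(".nii.gz"):
        hu, spacing = _read_nifti(p)
    else:
        hu, spacing = _read_dicom(p)
    return CTSlice(hu=hu, spacing_mm=spacing, level=level, phase=phase, subject_id=subject_id)


def read_labels(path: str | os.PathLike) -> tuple[np.ndarray, tuple[float, float]]:
    """Read an integer label mask and its spacing from NIfTI."""
    data, spacing = _read_nifti(os.fspath(path))
    return data.astype(np.int64), spacing


# ---------------------------------------------------------------------------
# measurement record CSV
# ---------------------------------------------------------------------------

def _records_to_frame(records: Sequence) -> pd.DataFrame:
    rows = []
    for r in records:
        rows.append(
            {
                "subject_id": r.subject_id,
                "level": r.level,
                "phase": r.phase,
                "sma_cm2": r.sma_cm2,
                "sata_cm2": r.sata_cm2,
                "vata_cm2": r.vata_cm2,
                "msmd_hu": r.msmd_hu,
                "msatd_hu": r.msatd_hu,
                "mvatd_hu": r.mvatd_hu,
            }
        )
    return pd.DataFrame(rows, columns=list(RECORD_COLUMNS))


def write_records(records: Sequence, path: str | os.PathLike | io.TextIOBase) -> None:
    """Write composition records as CSV; an empty list yields a header-only file.

    Areas are serialized at 0.01 cm^2 and densities at 0.01 HU; undefined
    densities (empty tissue) become empty cells, never 0.
    """
    df = _records_to_frame(records)
    for col in RECORD_COLUMNS[3:]:
        df[col] = df[col].map(lambda v: "" if v is None or (isinstance(v, float) and np.isnan(v)) else f"{v:.2f}")
    df.to_csv(path, index=False)


def read_records(path: str | os.PathLike | io.TextIOBase) -> list:
    """Read composition records; raises :class:`RecordParseError` naming bad rows."""
    from .metrics import CompositionRecord

    df = pd.read_csv(path, dtype={"subject_id": str, "level": str})
    missing = [c for c in RECORD_COLUMNS if c not in df.columns]
    if missing:
        raise RecordParseError(f"missing columns: {missing}")
    out = []
    for i, row in df.iterrows():
        try:
            dens = {
                c: (None if pd.isna(row[c]) else float(row[c]))
                for c in ("msmd_hu", "msatd_hu", "mvatd_hu")
            }
            out.append(
                CompositionRecord(
                    subject_id=str(row["subject_id"]),
                    level=str(row["level"]),
                    phase=int(row["phase"]),
                    sma_cm2=float(row["sma_cm2"]),
                    sata_cm2=float(row["sata_cm2"]),
                    vata_cm2=float(row["vata_cm2"]),
                    msmd_hu=dens["msmd_hu"],
                    msatd_hu=dens["msatd_hu"],
                    mvatd_hu=dens["mvatd_hu"],
                )
            )
        except (ValueError, TypeError) as exc:
            raise RecordParseError(f"row {i}: {exc}") from exc
    return out
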