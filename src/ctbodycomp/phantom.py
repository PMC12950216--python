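"""Synthetic five-phase, two-level CT cohort with known ground truth.

Each subject is a 2D scene of concentric structures on an elliptical body:
an outer subcutaneous-fat ring, a muscle ring, and a visceral interior
holding visceral fat plus 2-4 elliptical "organs". Per contrast phase,
tissue HU = frozen per-pixel baseline texture + an additive phase offset +
per-phase noise, then a Gaussian blur models the scanner's partial-volume
point spread. Ground-truth masks are recorded before blur and are
geometrically identical across phases — anatomy does not move.

The default phase offsets are the published L3 density shifts for the five
dynamic phases (muscle +2.1/+5.8/+7.8/+9.6 HU, subcutaneous fat
+1.2/+3.7/+4.8/+6.2 HU, visceral fat +1.5/+4.1/+5.2/+6.1 HU for phases
1-4). Organ HU stays above the muscle window ceiling (150 HU) at every
phase, so threshold windows exclude parenchyma outright; only the organs'
blurred boundary interacts with the fat windows. That partial-volume halo
pushes boundary visceral-fat pixels above the -50 HU ceiling and is the
mechanism by which the measured visceral fat area shrinks as organs enhance
— area change is emergent, never injected.

L1 slices are geometrically scaled variants of the same subject's L3 scene,
with per-parameter multiplicative factors plus subject-level jitter, so
level-to-level regression is testable against a known slope.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .io_ct import CTSlice, write_labels, write_slice
from .segmentation import (
    LABEL_MUSCLE,
    LABEL_SAT,
    LABEL_VAT,
    TissueSegmentation,
)

LABEL_ORGAN = 4

TISSUES = ("muscle", "sat", "vat")
AIR_HU = -1000.0

# canonical scene areas (mm^2) before per-subject variation
_A_INTERIOR_MM2 = 21_000.0
_A_MUSCLE_MM2 = 8_000.0
_A_SAT_MM2 = 20_000.0
_ASPECT_MEAN, _ASPECT_SD = 0.72, 0.03
_ASPECT_RANGE = (0.65, 0.80)
_RADIUS_FACTOR_CLIP = 2.5  # truncate anatomy factors at +/- 2.5 sd
_ORGAN_SEMI_AXIS_MM = (16.0, 26.0)
_ORGAN_ASPECT_RANGE = (0.70, 0.95)
_ORGAN_MARGIN_MM = 10.0
_ORGAN_TEXTURE_SD_HU = 10.0
_AIR_TEXTURE_SD_HU = 0.0  # air is homogeneous; scanner noise enters via noise_sd

_WINDOWS = {"muscle": (-29.0, 150.0), "sat": (-190.0, -30.0), "vat": (-150.0, -50.0)}

#: published L3 density shifts from the unenhanced phase, used as injected offsets
REFERENCE_DENSITY_SHIFTS_L3 = {
    "muscle": (0.0, 2.1, 5.8, 7.8, 9.6),
    "sat": (0.0, 1.2, 3.7, 4.8, 6.2),
    "vat": (0.0, 1.5, 4.1, 5.2, 6.1),
}


class InvalidSpecError(ValueError):
    """The phantom specification violates its invariants."""


def _default_baselines() -> dict[str, tuple[float, float]]:
    # (mean, per-pixel texture sd) in HU at phase 0; means sit well inside
    # the segmentation windows
    return {"muscle": (45.0, 6.0), "sat": (-100.0, 8.0), "vat": (-92.0, 8.0)}


def _default_offsets() -> dict[tuple[str, int], float]:
    return {
        (t, p): REFERENCE_DENSITY_SHIFTS_L3[t][p] for t in TISSUES for p in range(5)
    }


def _default_organ_enhancement() -> dict[int, float]:
    # stays above the 150 HU muscle ceiling in every phase; portal-phase
    # organs enhance steeply
    return {0: 160.0, 1: 220.0, 2: 270.0, 3: 300.0, 4: 310.0}


def _default_level_scale() -> dict[str, float]:
    # multiplicative L1/L3 factors per parameter (areas geometric, densities
    # on the baseline mean)
    return {
        "SMA": 0.80,
        "SATA": 0.70,
        "VATA": 0.85,
        "MSMD": 1.05,
        "MSATD": 1.00,
        "MVATD": 1.00,
    }


@dataclass(frozen=True)
class PhantomSpec:
    """All knobs of the synthetic cohort; defaults are the study conditions.

    ``tissue_baseline_hu`` maps tissue -> (mean, per-pixel sd) at phase 0;
    ``phase_offsets`` maps (tissue, phase) -> additive HU shift (0 at phase
    0); ``organ_enhancement`` maps phase -> absolute organ HU;
    ``anatomy_variation`` is the fractional sd of ring radii across
    subjects; ``level_scale`` maps parameter -> multiplicative L1/L3 factor;
    ``level_jitter_sd`` is the subject-level lognormal sd around those
    factors; ``subject_density_sd`` spreads tissue baselines across subjects
    (shared between levels, constant across phases).
    """

    subject_count: int = 20
    image_size: int = 320
    pixel_spacing: float = 1.25
    seed: int = 0
    tissue_baseline_hu: dict[str, tuple[float, float]] = field(default_factory=_default_baselines)
    phase_offsets: dict[tuple[str, int], float] = field(default_factory=_default_offsets)
    organ_enhancement: dict[int, float] = field(default_factory=_default_organ_enhancement)
    blur_sigma: float = 1.0
    noise_sd: float = 5.0
    anatomy_variation: float = 0.06
    level_scale: dict[str, float] = field(default_factory=_default_level_scale)
    level_jitter_sd: float = 0.03
    subject_density_sd: float = 4.0

    def validate(self) -> None:
        if self.subject_count <= 0:
            raise InvalidSpecError(f"subject_count must be positive, got {self.subject_count}")
        if self.pixel_spacing <= 0:
            raise InvalidSpecError("pixel_spacing must be positive")
        if self.blur_sigma < 0 or self.noise_sd < 0:
            raise InvalidSpecError("blur_sigma and noise_sd must be >= 0")
        for t in TISSUES:
            mean, sd = self.tissue_baseline_hu[t]
            lo, hi = _WINDOWS[t]
            if not (lo <= mean <= hi):
                raise InvalidSpecError(
                    f"{t} baseline mean {mean} outside its window [{lo}, {hi}]"
                )
            if sd < 0:
                raise InvalidSpecError(f"{t} baseline sd must be >= 0")
            if self.phase_offsets.get((t, 0), 0.0) != 0.0:
                raise InvalidSpecError(f"phase_offsets[({t!r}, 0)] must be 0")
        # worst-case body semi-axis must fit with margin
        worst_area = _A_BODY_MM2 * (1 + _RADIUS_FACTOR_CLIP * self.anatomy_variation) ** 2
        a_max = np.sqrt(worst_area / (np.pi * _ASPECT_RANGE[0]))
        half_extent = self.image_size * self.pixel_spacing / 2.0
        if a_max + 3 * self.pixel_spacing > half_extent:
            raise InvalidSpecError(
                f"image too small: body semi-axis up to {a_max:.0f} mm does not fit "
                f"in half-extent {half_extent:.0f} mm"
            )


_A_BODY_MM2 = _A_INTERIOR_MM2 + _A_MUSCLE_MM2 + _A_SAT_MM2


def default_spec(subject_count: int = 20, seed: int = 0, **overrides) -> PhantomSpec:
    """The reference phantom: published L3 density shifts as injected
    offsets, steeply enhancing organs, and partial-volume blur on."""
    spec = PhantomSpec(subject_count=subject_count, seed=seed, **overrides)
    spec.validate()
    return spec


@dataclass(frozen=True)
class PhantomSubject:
    """One synthetic examination: 10 slices (2 levels x 5 phases) plus truth."""

    subject_id: str
    slices: dict[tuple[str, int], CTSlice]
    truth: dict[tuple[str, int], TissueSegmentation]

    def __post_init__(self) -> None:
        if len(self.slices) != 10:
            raise ValueError(f"expected 10 slices (2 levels x 5 phases), got {len(self.slices)}")


# ---------------------------------------------------------------------------
# scene construction
# ---------------------------------------------------------------------------

def _ellipse_mask(yy: np.ndarray, xx: np.ndarray, cy: float, cx: float, a: float, b: float) -> np.ndarray:
    """Pixels inside an axis-aligned ellipse; a = column (x) semi-axis,
    b = row (y) semi-axis, all in mm."""
    return ((xx - cx) / a) ** 2 + ((yy - cy) / b) ** 2 <= 1.0


def _axes_from_area(area_mm2: float, aspect: float) -> tuple[float, float]:
    a = float(np.sqrt(area_mm2 / (np.pi * aspect)))
    return a, aspect * a


def _place_organs(
    rng: np.random.Generator, a_in: float, b_in: float
) -> list[tuple[float, float, float, float]]:
    """Seeded rejection sampling of 2-4 non-overlapping organ ellipses
    (cy, cx, a, b) inside the visceral cavity with a safety margin."""
    n = int(rng.integers(2, 5))
    organs: list[tuple[float, float, float, float]] = []
    for _ in range(n):
        a_o = float(rng.uniform(*_ORGAN_SEMI_AXIS_MM))
        b_o = a_o * float(rng.uniform(*_ORGAN_ASPECT_RANGE))
        for attempt in range(200):
            shrink = 0.9 ** (attempt // 50)
            ao, bo = a_o * shrink, b_o * shrink
            ax = a_in - ao - _ORGAN_MARGIN_MM
            bx = b_in - bo - _ORGAN_MARGIN_MM
            if ax <= 0 or bx <= 0:
                continue
            cx = float(rng.uniform(-ax, ax))
            cy = float(rng.uniform(-bx, bx))
            if (cx / ax) ** 2 + (cy / bx) ** 2 > 1.0:
                continue
            ok = all(
                np.hypot(cx - ox, cy - oy) > max(ao, bo) + max(oa, ob) + 4.0
                for oy, ox, oa, ob in organs
            )
            if ok:
                organs.append((cy, cx, ao, bo))
                break
    return organs


_SUPERSAMPLE = 4  # subpixel sampling factor for partial-volume coverage


def _paint_labels(
    n: int,
    spacing: float,
    aspect: float,
    areas: tuple[float, float, float],
    organs: list[tuple[float, float, float, float]],
) -> np.ndarray:
    """Rasterize one scene at pixel-center sampling.
    ``areas`` = (interior, muscle ring, SAT ring) mm^2."""
    coords = (np.arange(n) - (n - 1) / 2.0) * spacing
    yy, xx = np.meshgrid(coords, coords, indexing="ij")
    a_int, a_mus, a_sat = areas
    a_in, b_in = _axes_from_area(a_int, aspect)
    a_out, b_out = _axes_from_area(a_int + a_mus, aspect)
    a_body, b_body = _axes_from_area(a_int + a_mus + a_sat, aspect)

    labels = np.zeros((n, n), dtype=np.int16)
    labels[_ellipse_mask(yy, xx, 0, 0, a_body, b_body)] = LABEL_SAT
    labels[_ellipse_mask(yy, xx, 0, 0, a_out, b_out)] = LABEL_MUSCLE
    labels[_ellipse_mask(yy, xx, 0, 0, a_in, b_in)] = LABEL_VAT
    for cy, cx, ao, bo in organs:
        labels[_ellipse_mask(yy, xx, cy, cx, ao, bo)] = LABEL_ORGAN
    return labels


def _coverage_maps(
    n: int,
    spacing: float,
    aspect: float,
    areas: tuple[float, float, float],
    organs: list[tuple[float, float, float, float]],
) -> np.ndarray:
    """Per-pixel area fraction of each label, from supersampled rasterization.

    Shape (5, n, n); fractions sum to 1. This models the subpixel partial
    volume a real detector integrates: boundary pixels mix the HU of the
    tissues they straddle instead of snapping to one of them.
    """
    f = _SUPERSAMPLE
    fine = _paint_labels(n * f, spacing / f, aspect, areas, organs)
    cov = np.empty((5, n, n))
    for lab in range(5):
        cov[lab] = (fine == lab).reshape(n, f, n, f).mean(axis=(1, 3))
    return cov


def _render_phase(
    labels: np.ndarray,
    coverage: np.ndarray | None,
    spec: PhantomSpec,
    phase: int,
    means: dict[str, float],
    z_texture: np.ndarray,
    z_noise: np.ndarray,
) -> np.ndarray:
    """HU image for one phase: mean + frozen texture + phase noise, blurred.

    With blur on, per-pixel means/sds are coverage-weighted mixtures
    (subpixel partial volume); with blur off they are sharp per-label values
    so that noise-free images are exactly piecewise constant.
    """
    label_mean = np.array(
        [
            AIR_HU,
            means["muscle"] + spec.phase_offsets[("muscle", phase)],
            means["sat"] + spec.phase_offsets[("sat", phase)],
            means["vat"] + spec.phase_offsets[("vat", phase)],
            spec.organ_enhancement[phase],
        ]
    )
    label_sd = np.array(
        [
            _AIR_TEXTURE_SD_HU,
            spec.tissue_baseline_hu["muscle"][1],
            spec.tissue_baseline_hu["sat"][1],
            spec.tissue_baseline_hu["vat"][1],
            _ORGAN_TEXTURE_SD_HU,
        ]
    )
    if coverage is None:
        mean_map = label_mean[labels]
        sd_map = label_sd[labels]
    else:
        mean_map = np.einsum("l,lij->ij", label_mean, coverage)
        sd_map = np.einsum("l,lij->ij", label_sd, coverage)

    img = mean_map + sd_map * z_texture + spec.noise_sd * z_noise
    if spec.blur_sigma > 0:
        img = ndimage.gaussian_filter(img, sigma=spec.blur_sigma / spec.pixel_spacing)
    return img


def generate_cohort(spec: PhantomSpec) -> list[PhantomSubject]:
    """Generate the synthetic cohort; deterministic for a fixed seed.

    All randomness flows through one seeded generator threaded explicitly;
    no global random state is touched.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    shape = (spec.image_size, spec.image_size)
    scale = spec.level_scale
    subjects = []
    for idx in range(spec.subject_count):
        subject_id = f"S{idx:03d}"
        aspect = float(
            np.clip(rng.normal(_ASPECT_MEAN, _ASPECT_SD), *_ASPECT_RANGE)
        )
        rf = rng.normal(1.0, spec.anatomy_variation, size=3)
        rf = np.clip(
            rf,
            1.0 - _RADIUS_FACTOR_CLIP * spec.anatomy_variation,
            1.0 + _RADIUS_FACTOR_CLIP * spec.anatomy_variation,
        )
        areas_l3 = (
            _A_INTERIOR_MM2 * rf[0] ** 2,
            _A_MUSCLE_MM2 * rf[1] ** 2,
            _A_SAT_MM2 * rf[2] ** 2,
        )
        dens_shift = {t: float(rng.normal(0.0, spec.subject_density_sd)) for t in TISSUES}
        jitter = {
            p: float(np.exp(rng.normal(0.0, spec.level_jitter_sd)))
            for p in ("SMA", "SATA", "VATA")
        }

        a_in3, b_in3 = _axes_from_area(areas_l3[0], aspect)
        organs_l3 = _place_organs(rng, a_in3, b_in3)

        s_vat = scale["VATA"] * jitter["VATA"]
        lin = np.sqrt(s_vat)
        organs_l1 = [(cy * lin, cx * lin, ao * lin, bo * lin) for cy, cx, ao, bo in organs_l3]
        areas_l1 = (
            areas_l3[0] * s_vat,
            areas_l3[1] * scale["SMA"] * jitter["SMA"],
            areas_l3[2] * scale["SATA"] * jitter["SATA"],
        )

        means = {
            "L3": {t: spec.tissue_baseline_hu[t][0] + dens_shift[t] for t in TISSUES},
            "L1": {
                t: (spec.tissue_baseline_hu[t][0] + dens_shift[t]) * scale[p]
                for t, p in (("muscle", "MSMD"), ("sat", "MSATD"), ("vat", "MVATD"))
            },
        }
        geom = {"L3": (areas_l3, organs_l3), "L1": (areas_l1, organs_l1)}

        slices: dict[tuple[str, int], CTSlice] = {}
        truth: dict[tuple[str, int], TissueSegmentation] = {}
        for level in ("L3", "L1"):
            areas, organs = geom[level]
            labels = _paint_labels(spec.image_size, spec.pixel_spacing, aspect, areas, organs)
            coverage = (
                _coverage_maps(spec.image_size, spec.pixel_spacing, aspect, areas, organs)
                if spec.blur_sigma > 0
                else None
            )
            seg = TissueSegmentation(labels=labels, provenance={"source": "phantom-truth"})
            z_tex = rng.standard_normal(shape)
            for phase in range(5):
                z_noise = rng.standard_normal(shape) if spec.noise_sd > 0 else np.zeros(shape)
                hu = _render_phase(labels, coverage, spec, phase, means[level], z_tex, z_noise)
                slices[(level, phase)] = CTSlice(
                    hu=hu,
                    spacing_mm=(spec.pixel_spacing, spec.pixel_spacing),
                    level=level,
                    phase=phase,
                    subject_id=subject_id,
                )
                truth[(level, phase)] = seg
        subjects.append(PhantomSubject(subject_id=subject_id, slices=slices, truth=truth))
    return subjects


def truth_record(subject: PhantomSubject, level: str, phase: int):
    """Ground-truth composition record computed from the truth masks."""
    from .metrics import compute_record

    return compute_record(subject.slices[(level, phase)], subject.truth[(level, phase)])


def write_cohort(
    subjects: list[PhantomSubject], out_dir: str | os.PathLike, compress: bool = True
) -> str:
    """Write slices and truth masks as NIfTI plus a manifest CSV.

    Returns the manifest path. Manifest columns: subject_id, level, phase,
    image, truth (paths relative to ``out_dir``).
    """
    out = os.fspath(out_dir)
    os.makedirs(out, exist_ok=True)
    ext = ".nii.gz" if compress else ".nii"
    rows = []
    for subj in subjects:
        for (level, phase), ct in sorted(subj.slices.items()):
            stem = f"{subj.subject_id}_{level}_p{phase}"
            img_rel = f"{stem}{ext}"
            lab_rel = f"{stem}_truth{ext}"
            write_slice(ct, os.path.join(out, img_rel))
            write_labels(
                subj.truth[(level, phase)].labels, ct.spacing_mm, os.path.join(out, lab_rel)
            )
            rows.append(
                {
                    "subject_id": subj.subject_id,
                    "level": level,
                    "phase": phase,
                    "image": img_rel,
                    "truth": lab_rel,
                }
            )
    manifest = os.path.join(out, "manifest.csv")
    pd.DataFrame(rows).to_csv(manifest, index=False)
    return manifest
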