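"""Harmonize body-composition measurements across contrast phases and
vertebral levels.

Two conversion families:

* **Phase conversion.** Area parameters carry a relative value per
  (level, parameter, phase) with the unenhanced phase fixed at 100; an
  enhanced measurement is brought to its unenhanced equivalent by
  ``value * 100 / relative``. Density parameters carry an additive HU
  offset per key (0 at phase 0); conversion subtracts the offset. The
  bundled default table stores the published values exactly as printed;
  it is data, not a fit of this package. Conversion between two enhanced
  phases composes through phase 0.

* **Level conversion.** L3 and L1 values of one parameter in one phase are
  linked by a one-parameter regression through the origin, y = beta x with
  x = L3 and y = L1. The slope is Σxy/Σx²; its 95% CI uses the
  through-origin standard error with n-1 degrees of freedom. R² is the
  *uncentered* coefficient of determination, 1 - RSS/Σy², the standard for
  no-intercept models — it is NOT comparable to the centered R² of a model
  with an intercept.

Worked conversions are reported to one decimal place at the display
surface; every chained computation keeps full precision.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
from scipy import stats as sps

AREA_PARAMETERS = ("SMA", "SATA", "VATA")
DENSITY_PARAMETERS = ("MSMD", "MSATD", "MVATD")
LEVELS = ("L3", "L1")
PHASES = (0, 1, 2, 3, 4)

#: relative tissue area by contrast phase (unenhanced = 100), as published
RELATIVE_AREA = {
    ("L3", "SMA"): (100.0, 101.1, 102.1, 102.8, 103.5),
    ("L1", "SMA"): (100.0, 102.0, 102.7, 103.0, 103.7),
    ("L3", "SATA"): (100.0, 99.6, 98.1, 97.1, 95.3),
    ("L1", "SATA"): (100.0, 99.7, 97.8, 96.5, 93.9),
    ("L3", "VATA"): (100.0, 92.5, 82.2, 80.0, 77.8),
    ("L1", "VATA"): (100.0, 91.5, 79.9, 77.4, 76.3),
}

#: change in mean tissue density from the unenhanced phase (HU), as published
DENSITY_OFFSET = {
    ("L3", "MSMD"): (0.0, 2.1, 5.8, 7.8, 9.6),
    ("L1", "MSMD"): (0.0, 2.9, 7.7, 9.1, 9.8),
    ("L3", "MSATD"): (0.0, 1.2, 3.7, 4.8, 6.2),
    ("L1", "MSATD"): (0.0, 1.2, 3.8, 4.7, 5.6),
    ("L3", "MVATD"): (0.0, 1.5, 4.1, 5.2, 6.1),
    ("L1", "MVATD"): (0.0, 1.9, 4.9, 5.8, 6.3),
}


class TableLookupError(KeyError):
    """No conversion entry for the requested (level, parameter, phase)."""


class FitError(ValueError):
    """Degenerate input for the through-origin regression."""


@dataclass(frozen=True)
class ConversionTable:
    """Phase-conversion data keyed by (level, parameter, phase).

    Invariants: every area key has relative value 100 at phase 0 and every
    density key has offset 0 at phase 0.
    """

    area_relative: dict[tuple[str, str, int], float]
    density_offset: dict[tuple[str, str, int], float]

    def __post_init__(self) -> None:
        for (level, param, phase), v in self.area_relative.items():
            if phase == 0 and v != 100.0:
                raise ValueError(f"area_relative[{(level, param, 0)}] must be 100, got {v}")
            if v <= 0:
                raise ValueError(f"area_relative[{(level, param, phase)}] must be > 0")
        for (level, param, phase), v in self.density_offset.items():
            if phase == 0 and v != 0.0:
                raise ValueError(f"density_offset[{(level, param, 0)}] must be 0, got {v}")

    def relative(self, level: str, parameter: str, phase: int) -> float:
        try:
            return self.area_relative[(level, parameter, phase)]
        except KeyError:
            raise TableLookupError(f"no area entry for {(level, parameter, phase)}") from None

    def offset(self, level: str, parameter: str, phase: int) -> float:
        try:
            return self.density_offset[(level, parameter, phase)]
        except KeyError:
            raise TableLookupError(f"no density entry for {(level, parameter, phase)}") from None


def default_table() -> ConversionTable:
    """The bundled table with the published values, verbatim."""
    return ConversionTable(
        area_relative={
            (level, param, p): RELATIVE_AREA[(level, param)][p]
            for (level, param) in RELATIVE_AREA
            for p in PHASES
        },
        density_offset={
            (level, param, p): DENSITY_OFFSET[(level, param)][p]
            for (level, param) in DENSITY_OFFSET
            for p in PHASES
        },
    )


def area_to_unenhanced(
    value: float, level: str, parameter: str, phase: int, table: ConversionTable | None = None
) -> float:
    """Estimate an area's unenhanced (phase 0) equivalent:
    ``value * 100 / relative(level, parameter, phase)``."""
    table = table or default_table()
    rel = table.relative(level, parameter, phase)
    return value if rel == 100.0 else value * 100.0 / rel


def area_from_unenhanced(
    value: float, level: str, parameter: str, phase: int, table: ConversionTable | None = None
) -> float:
    """Inverse of :func:`area_to_unenhanced`: project a phase-0 area to an
    enhanced phase."""
    table = table or default_table()
    rel = table.relative(level, parameter, phase)
    return value if rel == 100.0 else value * rel / 100.0


def density_to_unenhanced(
    value: float, level: str, parameter: str, phase: int, table: ConversionTable | None = None
) -> float:
    """Estimate a density's unenhanced equivalent:
    ``value - offset(level, parameter, phase)``."""
    table = table or default_table()
    return value - table.offset(level, parameter, phase)


def density_from_unenhanced(
    value: float, level: str, parameter: str, phase: int, table: ConversionTable | None = None
) -> float:
    table = table or default_table()
    return value + table.offset(level, parameter, phase)


def convert_phase(
    value: float,
    level: str,
    parameter: str,
    from_phase: int,
    to_phase: int,
    table: ConversionTable | None = None,
) -> float:
    """Convert between any two phases, composing through phase 0."""
    table = table or default_table()
    if parameter in AREA_PARAMETERS:
        p0 = area_to_unenhanced(value, level, parameter, from_phase, table)
        return area_from_unenhanced(p0, level, parameter, to_phase, table)
    p0 = density_to_unenhanced(value, level, parameter, from_phase, table)
    return density_from_unenhanced(p0, level, parameter, to_phase, table)


# ---------------------------------------------------------------------------
# level regression
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LevelRegression:
    """Through-origin link between L3 (x) and L1 (y) values of one parameter."""

    parameter: str
    phase: int
    slope: float
    slope_ci95: tuple[float, float]
    r2: float
    n: int

    def __post_init__(self) -> None:
        lo, hi = self.slope_ci95
        if not lo <= self.slope <= hi:
            raise ValueError("slope_ci95 must contain slope")


def fit_level_regression(
    pairs: Iterable[tuple[float, float]], parameter: str = "", phase: int = 0
) -> LevelRegression:
    """Least-squares line through the origin, y = beta x.

    slope = Σxy/Σx²; se(slope) = sqrt(RSS/(n-1)/Σx²); 95% CI via the t
    distribution with n-1 df; R² = 1 - RSS/Σy² (uncentered).
    """
    arr = np.asarray(list(pairs), dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2 or arr.shape[0] < 3:
        raise FitError(f"need >= 3 (L3, L1) pairs, got shape {arr.shape}")
    x, y = arr[:, 0], arr[:, 1]
    sxx = float(np.dot(x, x))
    if sxx == 0.0:
        raise FitError("all L3 values are zero; slope is undefined")
    slope = float(np.dot(x, y)) / sxx
    resid = y - slope * x
    rss = float(np.dot(resid, resid))
    n = len(x)
    se = np.sqrt(rss / (n - 1) / sxx)
    tcrit = float(sps.t.ppf(0.975, n - 1))
    syy = float(np.dot(y, y))
    r2 = 1.0 - rss / syy if syy > 0 else 0.0
    return LevelRegression(
        parameter=parameter,
        phase=phase,
        slope=slope,
        slope_ci95=(slope - tcrit * se, slope + tcrit * se),
        r2=float(np.clip(r2, 0.0, 1.0)),
        n=n,
    )


def convert_level(value: float, regression: LevelRegression, direction: str = "L3->L1") -> float:
    """Convert a value between levels with a fitted through-origin slope.

    L3->L1 multiplies by the slope, L1->L3 divides; the round trip is the
    identity.
    """
    if regression.slope == 0:
        raise ValueError("cannot convert with a zero slope")
    if direction == "L3->L1":
        return value * regression.slope
    if direction == "L1->L3":
        return value / regression.slope
    raise ValueError(f"direction must be 'L3->L1' or 'L1->L3', got {direction!r}")


# ---------------------------------------------------------------------------
# TOML serialization
# ---------------------------------------------------------------------------

def table_to_toml(table: ConversionTable) -> str:
    """Serialize a conversion table as TOML with per-key phase arrays."""
    lines = []
    for section, data in (("area", table.area_relative), ("density", table.density_offset)):
        keys = sorted({(lvl, par) for (lvl, par, _) in data})
        for lvl, par in keys:
            values = [data[(lvl, par, p)] for p in PHASES]
            lines.append(f"[{section}.{lvl}.{par}]")
            lines.append("phases = [" + ", ".join(repr(float(v)) for v in values) + "]")
            lines.append("")
    return "\n".join(lines)


def table_from_toml(text: str) -> ConversionTable:
    import tomllib

    doc = tomllib.loads(text)
    area = {
        (lvl, par, p): float(entry["phases"][p])
        for lvl, pars in doc.get("area", {}).items()
        for par, entry in pars.items()
        for p in PHASES
    }
    density = {
        (lvl, par, p): float(entry["phases"][p])
        for lvl, pars in doc.get("density", {}).items()
        for par, entry in pars.items()
        for p in PHASES
    }
    return ConversionTable(area_relative=area, density_offset=density)
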