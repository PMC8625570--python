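"""Analytical size-exclusion chromatography arithmetic.

Partition coefficients on a calibrated gel-filtration column
(``Kav = (Ve - V0) / (Vc - V0)``, linear in log10 of molecular mass),
apparent-mass inference from elution volumes, peak detection in elution
profiles, and integer stoichiometry inference for two-component complexes
(e.g. deciding whether an observed 228 kDa species is a 2:2
effector/GTPase heterotetramer).

Defaults describe a 24-mL analytical column with an 8-mL void volume.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product
from typing import Sequence

import numpy as np
from scipy.signal import find_peaks

from .errors import CalibrationError, ValidationError

#: added mass of a bound non-hydrolyzable GTP analog (GppNHp), kDa
GPPNHP_MASS_KDA = 0.52


@dataclass(frozen=True)
class ColumnGeometry:
    """Void volume and geometric column volume in mL."""

    V0: float = 8.0
    Vc: float = 24.0

    def __post_init__(self):
        if not 0 < self.V0 < self.Vc:
            raise ValidationError(
                f"need 0 < V0 < Vc (got V0={self.V0}, Vc={self.Vc})"
            )


@dataclass(frozen=True)
class CalibrationCurve:
    """Least-squares line Kav = slope * log10(mass_kDa) + intercept."""

    standards: tuple   # ((mass_kDa, Ve_mL), ...)
    slope: float
    intercept: float
    geometry: ColumnGeometry


@dataclass(frozen=True)
class SECPeak:
    elution_volume: float  # mL (apex)
    height: float
    width: float           # mL, half-prominence width


@dataclass(frozen=True)
class ElutionProfile:
    volumes: np.ndarray
    absorbance: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "volumes", np.asarray(self.volumes, float))
        object.__setattr__(self, "absorbance",
                           np.asarray(self.absorbance, float))
        if self.volumes.shape != self.absorbance.shape:
            raise ValidationError("volumes and absorbance lengths differ")
        if np.any(np.diff(self.volumes) <= 0):
            raise ValidationError("volumes must be strictly increasing")


@dataclass(frozen=True)
class StoichiometryResult:
    copies: tuple[int, int]
    predicted_mass: float  # kDa
    error: float           # |predicted - observed|, kDa


#: a typical gel-filtration calibration set (mass kDa); Ve values are
#: synthetic, produced by inverting a plausible calibration line — real
#: column standards must be supplied by the user for real data.
TYPICAL_STANDARD_MASSES = (13.7, 29.0, 43.0, 66.0, 158.0, 440.0, 669.0)


def synthetic_calibration_standards(
        geometry: ColumnGeometry | None = None,
        slope: float = -0.35, intercept: float = 1.05,
) -> list[tuple[float, float]]:
    """Synthetic standards on an ideal calibration line (for tests/demos)."""
    geometry = geometry or ColumnGeometry()
    out = []
    for mass in TYPICAL_STANDARD_MASSES:
        kav_val = slope * np.log10(mass) + intercept
        ve = geometry.V0 + kav_val * (geometry.Vc - geometry.V0)
        out.append((mass, float(ve)))
    return out


def kav(Ve: float, geometry: ColumnGeometry | None = None) -> float:
    """Partition coefficient (Ve - V0) / (Vc - V0); 0 at the void volume."""
    geometry = geometry or ColumnGeometry()
    if not geometry.V0 <= Ve <= geometry.Vc:
        raise ValidationError(
            f"Ve = {Ve} mL outside [{geometry.V0}, {geometry.Vc}] mL"
        )
    return (Ve - geometry.V0) / (geometry.Vc - geometry.V0)


def fit_calibration(standards: Sequence[tuple[float, float]],
                    geometry: ColumnGeometry | None = None
                    ) -> CalibrationCurve:
    """Fit Kav vs log10(mass) to the calibration standards (mass kDa, Ve mL)."""
    geometry = geometry or ColumnGeometry()
    masses = [m for m, _ in standards]
    if len(set(masses)) < 3:
        raise CalibrationError("need >= 3 standards with distinct masses")
    logm = np.log10(masses)
    kavs = np.array([kav(ve, geometry) for _, ve in standards])
    slope, intercept = np.polyfit(logm, kavs, 1)
    if slope >= 0:
        raise CalibrationError(
            f"calibration slope {slope:.3g} is not negative: larger species "
            "must elute earlier"
        )
    return CalibrationCurve(standards=tuple(tuple(s) for s in standards),
                            slope=float(slope), intercept=float(intercept),
                            geometry=geometry)


def infer_mass(Ve: float, calibration: CalibrationCurve,
               geometry: ColumnGeometry | None = None) -> float:
    """Apparent molecular mass (kDa) of a species eluting at Ve."""
    geometry = geometry or calibration.geometry
    k = kav(Ve, geometry)
    return float(10 ** ((k - calibration.intercept) / calibration.slope))


def elution_volume_for_mass(mass_kda: float, calibration: CalibrationCurve,
                            geometry: ColumnGeometry | None = None) -> float:
    """Invert the calibration line: predicted Ve (mL) for a mass (kDa)."""
    geometry = geometry or calibration.geometry
    k = calibration.slope * np.log10(mass_kda) + calibration.intercept
    return float(geometry.V0 + k * (geometry.Vc - geometry.V0))


def detect_peaks(profile: ElutionProfile, min_height: float = 0.0
                 ) -> list[SECPeak]:
    """Local maxima above min_height, apex refined by 3-point parabola."""
    v, a = profile.volumes, profile.absorbance
    if len(v) < 10:
        raise ValidationError("profile needs >= 10 samples")
    idx, props = find_peaks(a, height=min_height if min_height > 0 else None,
                            width=0)
    peaks = []
    for j, i in enumerate(idx):
        apex_v, apex_h = float(v[i]), float(a[i])
        if 0 < i < len(v) - 1:
            y0, y1, y2 = a[i - 1], a[i], a[i + 1]
            denom = y0 - 2 * y1 + y2
            if denom != 0:
                delta = 0.5 * (y0 - y2) / denom
                step = (v[i + 1] - v[i - 1]) / 2
                apex_v = float(v[i] + delta * step)
                apex_h = float(y1 - 0.25 * (y0 - y2) * delta)
        width = float(props["widths"][j] * np.mean(np.diff(v)))
        peaks.append(SECPeak(apex_v, apex_h, width))
    return peaks


def infer_stoichiometry(observed_kda: float, mass1_kda: float,
                        mass2_kda: float, max_copies: int = 4
                        ) -> StoichiometryResult:
    """Integer copy numbers (a, b) minimising |a*m1 + b*m2 - observed|.

    Both components must be present (a, b >= 1) — the use case is a complex
    whose gel bands show both partners.  Ties are broken by the smaller
    total copy number, then by the smaller first-component count.
    """
    if observed_kda <= 0 or mass1_kda <= 0 or mass2_kda <= 0:
        raise ValidationError("masses must be > 0")
    best = None
    for a, b in product(range(1, max_copies + 1), repeat=2):
        pred = a * mass1_kda + b * mass2_kda
        key = (abs(pred - observed_kda), a + b, a)
        if best is None or key < best[0]:
            best = (key, (a, b), pred)
    (_err, _, _), copies, pred = best
    return StoichiometryResult(copies=copies, predicted_mass=float(pred),
                               error=float(abs(pred - observed_kda)))
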