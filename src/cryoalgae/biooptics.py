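"""Pigment bio-optics: extinction calibration and single-cell absorption
cross-sections.

The spectral extinction coefficient of a pigment extract is the slope of
Beer–Lambert absorbance against concentration×path-length, e = A/(l·c)
(L·g⁻¹·cm⁻¹), estimated per wavelength by ordinary least squares through
the origin across a calibration series of blank-corrected spectra.  The
mass-specific absorption coefficient follows by unit conversion
(1 L·g⁻¹·cm⁻¹ = 1e-4 m²·mg⁻¹, optionally ×ln 10 when moving from decadic
absorbance to a natural-log absorption coefficient).

A cell's absorption cross-section is reconstructed additively from the
mass absorption spectra aᵢ(λ) (m²·mg⁻¹) of its pigment classes and its
cellular contents Cᵢ (mg·cell⁻¹):

    a(λ) = Σᵢ aᵢ(λ)·Cᵢ   [m²·cell⁻¹]

— the virtual area of a completely opaque object intercepting the same
radiation.  No packaging correction is applied here; self-shading is
handled empirically in the energy budget.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .exceptions import GridError, InvalidMeasurementError, RankDeficiencyError

logger = logging.getLogger(__name__)

#: Canonical 1-nm wavelength grid for extract spectra (nm).
WAVELENGTH_GRID = np.arange(250.0, 751.0)

PIGMENT_CLASSES = ("phenolic", "chl_a", "chl_b", "psc", "ppc")

#: Pigment classes counted as photosynthetic (chlorophylls) downstream.
CHLOROPHYLL_CLASSES = ("chl_a", "chl_b")

LN10 = float(np.log(10.0))


@dataclass(frozen=True)
class CalibrationSet:
    """Absorbance spectra of extracts at known concentrations.

    ``absorbance`` is (n_samples, n_wavelengths); ``concentrations`` in
    g·L⁻¹ (same volume basis as the absorbance measurement);
    ``path_length`` in cm.  Spectra are assumed blank-corrected.
    """

    wavelengths: np.ndarray
    absorbance: np.ndarray
    concentrations: np.ndarray
    path_length: float
    cell_abundance: np.ndarray | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "wavelengths", np.asarray(self.wavelengths, float))
        object.__setattr__(self, "absorbance", np.asarray(self.absorbance, float))
        object.__setattr__(self, "concentrations",
                           np.asarray(self.concentrations, float))
        if self.path_length <= 0:
            raise InvalidMeasurementError("path_length must be positive")
        if np.any(self.concentrations < 0):
            raise InvalidMeasurementError("concentrations must be non-negative")
        if self.absorbance.shape != (self.concentrations.size, self.wavelengths.size):
            raise InvalidMeasurementError("absorbance shape mismatch")


@dataclass(frozen=True)
class PigmentSpectrum:
    """Mass-specific absorption aᵢ(λ) of one pigment class (m²·mg⁻¹)."""

    pigment_class: str
    wavelengths: np.ndarray
    mass_absorption: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "wavelengths", np.asarray(self.wavelengths, float))
        object.__setattr__(self, "mass_absorption",
                           np.asarray(self.mass_absorption, float))
        if np.any(np.diff(self.wavelengths) <= 0):
            raise GridError("wavelength grid must be strictly increasing")
        if np.any(self.mass_absorption < 0):
            raise InvalidMeasurementError("mass absorption must be non-negative")

    def resampled(self, grid: np.ndarray) -> "PigmentSpectrum":
        """Linear resample onto ``grid``; extrapolation is forbidden."""
        grid = np.asarray(grid, float)
        if grid[0] < self.wavelengths[0] - 1e-9 or grid[-1] > self.wavelengths[-1] + 1e-9:
            raise GridError(
                f"{self.pigment_class}: requested grid "
                f"[{grid[0]}, {grid[-1]}] extends beyond data "
                f"[{self.wavelengths[0]}, {self.wavelengths[-1]}]")
        vals = np.interp(grid, self.wavelengths, self.mass_absorption)
        return PigmentSpectrum(self.pigment_class, grid, vals)


@dataclass(frozen=True)
class PigmentProfile:
    """Cellular pigment contents Cᵢ in mg·cell⁻¹."""

    contents: Mapping[str, float]

    def __post_init__(self) -> None:
        for k, v in self.contents.items():
            if v < 0:
                raise InvalidMeasurementError(f"content of {k} must be >= 0")

    def scaled(self, factor: float) -> "PigmentProfile":
        return PigmentProfile({k: v * factor for k, v in self.contents.items()})


@dataclass(frozen=True)
class CellCrossSection:
    """Per-cell absorption cross-section a(λ), total and by pigment class."""

    wavelengths: np.ndarray
    by_class: Mapping[str, np.ndarray]

    @property
    def total(self) -> np.ndarray:
        return np.sum(list(self.by_class.values()), axis=0)

    def without(self, *classes: str) -> "CellCrossSection":
        """Cross-section with the named classes removed."""
        kept = {k: v for k, v in self.by_class.items() if k not in classes}
        return CellCrossSection(self.wavelengths, kept)


# ---------------------------------------------------------------------------
# calibration
# ---------------------------------------------------------------------------

def fit_extinction(calib: CalibrationSet,
                   fit_intercept: bool = False) -> pd.DataFrame:
    """Per-wavelength extinction coefficient e(λ) = slope of A vs c·l.

    Regression is through the origin by default (spectra are
    blank-corrected); ``fit_intercept=True`` adds a free intercept whose
    fitted value is reported to flag blank drift.  Negative slopes are
    clamped to zero with a warning (absorption is non-negative).

    Returns a DataFrame with columns ``wavelength_nm``, ``e_L_g_cm``,
    ``r2`` (and ``intercept`` when fitted).
    """
    x = calib.concentrations * calib.path_length
    if np.unique(calib.concentrations).size < 3:
        raise RankDeficiencyError(
            "need >= 3 distinct concentrations for slope estimation")
    A = calib.absorbance
    if fit_intercept:
        X = np.column_stack([x, np.ones_like(x)])
        coef, *_ = np.linalg.lstsq(X, A, rcond=None)
        slope, intercept = coef[0], coef[1]
        resid = A - X @ coef
        ss_tot = np.sum((A - A.mean(axis=0)) ** 2, axis=0)
    else:
        sxx = float(np.sum(x * x))
        if sxx == 0.0:
            raise RankDeficiencyError("all concentrations are zero")
        slope = (x @ A) / sxx
        intercept = None
        resid = A - np.outer(x, slope)
        ss_tot = np.sum(A ** 2, axis=0)  # uncentered: origin model
    if np.any(slope < 0):
        logger.warning("negative extinction slopes at %d wavelengths clamped to 0",
                       int(np.sum(slope < 0)))
        slope = np.clip(slope, 0.0, None)
    ss_res = np.sum(resid ** 2, axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        r2 = np.where(ss_tot > 0, 1.0 - ss_res / ss_tot, np.nan)
    out = pd.DataFrame({"wavelength_nm": calib.wavelengths,
                        "e_L_g_cm": slope, "r2": r2})
    if intercept is not None:
        out["intercept"] = intercept
    return out


def extinction_to_mass_absorption(e, natural_log: bool = False):
    """Convert L·g⁻¹·cm⁻¹ to m²·mg⁻¹ (×1e-4; ×ln 10 for natural-log form)."""
    e = np.asarray(e, float)
    if np.any(e < 0):
        raise InvalidMeasurementError("extinction must be non-negative")
    factor = 1e-4 * (LN10 if natural_log else 1.0)
    return e * factor


# ---------------------------------------------------------------------------
# cross-section reconstruction
# ---------------------------------------------------------------------------

def reconstruct_cross_section(profile: PigmentProfile,
                              spectra: Sequence[PigmentSpectrum],
                              grid: np.ndarray | None = None) -> CellCrossSection:
    """a(λ) = Σ aᵢ(λ)·Cᵢ over the pigment classes present in ``profile``.

    Spectra on mismatched grids are linearly resampled onto ``grid``
    (default: the intersection of all class grids at 1-nm spacing).
    A nonzero content with no matching spectrum is an error.
    """
    by_name = {s.pigment_class: s for s in spectra}
    active = {k: v for k, v in profile.contents.items() if v > 0}
    missing = [k for k in active if k not in by_name]
    if missing:
        raise InvalidMeasurementError(
            f"no spectrum supplied for pigment classes: {missing}")
    if grid is None:
        if active:
            lo = max(by_name[k].wavelengths[0] for k in active)
            hi = min(by_name[k].wavelengths[-1] for k in active)
        else:
            lo, hi = WAVELENGTH_GRID[0], WAVELENGTH_GRID[-1]
        if hi <= lo:
            raise GridError("pigment spectra share no wavelength overlap")
        grid = np.arange(lo, hi + 0.5)
    grid = np.asarray(grid, float)
    by_class = {}
    for k, content in profile.contents.items():
        if k in by_name:
            spec = by_name[k].resampled(grid)
            by_class[k] = spec.mass_absorption * content
        else:  # zero-content class without a spectrum contributes zero
            by_class[k] = np.zeros_like(grid)
    if not by_class:
        by_class = {"total": np.zeros_like(grid)}
    return CellCrossSection(grid, by_class)


def spectral_integral(cross_section: CellCrossSection,
                      lam_lo: float, lam_hi: float,
                      pigment_class: str | None = None) -> float:
    """Trapezoidal integral of a(λ) over [λ_lo, λ_hi] (m²·cell⁻¹·nm units)."""
    if lam_hi <= lam_lo:
        raise GridError("inverted wavelength range")
    w = cross_section.wavelengths
    if lam_lo < w[0] - 1e-9 or lam_hi > w[-1] + 1e-9:
        raise GridError("integration range outside the spectral grid")
    y = (cross_section.total if pigment_class is None
         else np.asarray(cross_section.by_class[pigment_class], float))
    mask = (w >= lam_lo) & (w <= lam_hi)
    return float(np.trapezoid(y[mask], w[mask]))


def class_fraction_at(cross_section: CellCrossSection,
                      pigment_class: str, lam: float) -> float:
    """Fraction of total absorption contributed by one class at λ."""
    w = cross_section.wavelengths
    idx = int(np.argmin(np.abs(w - lam)))
    if abs(w[idx] - lam) > 0.5:
        raise GridError(f"wavelength {lam} nm not on the grid")
    tot = float(cross_section.total[idx])
    if tot <= 0:
        raise InvalidMeasurementError(
            f"total absorption is zero at {lam} nm; fraction undefined")
    return float(cross_section.by_class[pigment_class][idx]) / tot


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def cross_section_to_frame(cs: CellCrossSection) -> pd.DataFrame:
    df = pd.DataFrame({"wavelength_nm": cs.wavelengths,
                       "total_m2_cell": cs.total})
    for k, v in cs.by_class.items():
        df[f"{k}_m2_cell"] = v
    return df


def read_calibration_csv(path, path_length: float | None = None) -> CalibrationSet:
    """Read a calibration table in long layout
    (sample_id, concentration_g_per_L, path_length_cm, wavelength_nm, absorbance)."""
    df = pd.read_csv(path)
    samples = df["sample_id"].drop_duplicates().to_list()
    grid = np.sort(df["wavelength_nm"].unique()).astype(float)
    A = np.zeros((len(samples), grid.size))
    conc = np.zeros(len(samples))
    for i, sid in enumerate(samples):
        sub = df[df["sample_id"] == sid].sort_values("wavelength_nm")
        if sub["wavelength_nm"].size != grid.size:
            raise GridError(f"sample {sid}: incomplete spectrum")
        A[i] = sub["absorbance"].to_numpy(float)
        conc[i] = float(sub["concentration_g_per_L"].iloc[0])
    if path_length is None:
        path_length = float(df["path_length_cm"].iloc[0])
    return CalibrationSet(grid, A, conc, path_length)
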