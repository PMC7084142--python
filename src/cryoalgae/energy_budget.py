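"""Cellular energy budget, instantaneous radiative forcing (IRF) and melt.

Per-cell spectral light capture is the product of the absorption
cross-section a(λ) (m²·cell⁻¹) and incident photon irradiance, reported
in fmol photons·cell⁻¹·s⁻¹·nm⁻¹ (×1e9 from µmol).  The light *available*
to a benthic cell is the incident irradiance times half the lateral
surface area of an average cell (cylinder approximation) — the upward-
facing half of a prostrate filament.  Where reconstructed absorption
exceeds availability (pigment packaging: self-shading makes the
additive reconstruction an overestimate) absorption is clipped to the
available irradiance, by default proportionally across pigment classes.

Population radiative forcing scales the per-cell absorbed power (minus
the photosynthetically used chlorophyll share) by cell abundance and a
sampled-volume-to-surface-area factor, ×3600 s·h⁻¹.  Hourly melt in cm
water equivalent follows from the spectrally integrated forcing via the
latent heat of fusion of ice, 334 J·cm⁻³, and the 1e4 cm²·m⁻² area
scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.constants import Avogadro, Planck, speed_of_light

from .biooptics import CHLOROPHYLL_CLASSES, CellCrossSection
from .exceptions import GridError, InvalidMeasurementError

#: Latent heat of fusion of ice, J·cm⁻³.
LATENT_HEAT_FUSION = 334.0

#: Square centimetres per square metre.
AREA_SCALE = 1.0e4

#: µmol → fmol.
UMOL_TO_FMOL = 1.0e9

#: Wavelength window for IRF/melt integration (nm).
MELT_WINDOW = (280.0, 750.0)

_HC_NA = Planck * speed_of_light * Avogadro  # J·m·mol⁻¹


def photons_from_energy(E_W, lam_nm):
    """W·m⁻²·nm⁻¹ → µmol photons·m⁻²·s⁻¹·nm⁻¹ at wavelength λ (nm)."""
    lam = np.asarray(lam_nm, float)
    if np.any(lam <= 0):
        raise InvalidMeasurementError("wavelength must be positive")
    return np.asarray(E_W, float) * lam * 1e-9 / _HC_NA * 1e6


def energy_from_photons(photons_umol, lam_nm):
    """Inverse of :func:`photons_from_energy` (exact reciprocal)."""
    lam = np.asarray(lam_nm, float)
    if np.any(lam <= 0):
        raise InvalidMeasurementError("wavelength must be positive")
    return np.asarray(photons_umol, float) / (lam * 1e-9) * _HC_NA * 1e-6


@dataclass(frozen=True)
class SpectralIrradiance:
    """Hourly incident spectrum in energy units, photon units derived."""

    timestamp: object
    wavelengths: np.ndarray
    irradiance_W: np.ndarray  # W·m⁻²·nm⁻¹

    def __post_init__(self) -> None:
        object.__setattr__(self, "wavelengths", np.asarray(self.wavelengths, float))
        object.__setattr__(self, "irradiance_W", np.asarray(self.irradiance_W, float))
        if np.any(self.irradiance_W < 0):
            raise InvalidMeasurementError("irradiance must be non-negative")
        if self.wavelengths.shape != self.irradiance_W.shape:
            raise GridError("wavelength/irradiance shape mismatch")

    @property
    def irradiance_photons(self) -> np.ndarray:
        """µmol photons·m⁻²·s⁻¹·nm⁻¹."""
        return photons_from_energy(self.irradiance_W, self.wavelengths)

    def total_par(self, lam_lo: float = 400.0, lam_hi: float = 700.0) -> float:
        """Integrated photon irradiance over a window (µmol·m⁻²·s⁻¹)."""
        w = self.wavelengths
        m = (w >= lam_lo) & (w <= lam_hi)
        return float(np.trapezoid(self.irradiance_photons[m], w[m]))


@dataclass(frozen=True)
class CellGeometry:
    """Average cell dimensions and the derived upward-facing area.

    Half the lateral surface of a cylinder of length L and width W:
    π·W·L/2, in m² (dimensions given in µm).  The study species'
    averages are length 29.60 µm × width 12.04 µm.
    """

    length_um: float
    width_um: float
    half_lateral_area_m2: float = field(init=False)

    def __post_init__(self) -> None:
        if self.length_um <= 0 or self.width_um <= 0:
            raise InvalidMeasurementError("cell dimensions must be positive")
        area = np.pi * self.width_um * self.length_um / 2.0 * 1e-12
        object.__setattr__(self, "half_lateral_area_m2", float(area))


#: Mean cell of the dominant filamentous glacier alga.
DEFAULT_CELL = CellGeometry(length_um=29.60, width_um=12.04)


@dataclass(frozen=True)
class EnergyBudget:
    """Per-cell absorbed vs available spectral photon flux.

    ``absorbed_by_class`` and ``available`` in
    fmol photons·cell⁻¹·s⁻¹·nm⁻¹ on a common grid; ``clipped`` marks
    wavelengths where the packaging correction was applied.
    """

    wavelengths: np.ndarray
    absorbed_by_class: Mapping[str, np.ndarray]
    available: np.ndarray
    clipped: np.ndarray | None = None

    @property
    def absorbed_total(self) -> np.ndarray:
        return np.sum(list(self.absorbed_by_class.values()), axis=0)

    def fractions(self) -> dict[str, float]:
        """Spectrally integrated share of available light per class,
        plus the unabsorbed remainder; sums to 1."""
        w = self.wavelengths
        avail = float(np.trapezoid(self.available, w))
        if avail <= 0:
            raise InvalidMeasurementError("no available light; fractions undefined")
        out = {k: float(np.trapezoid(v, w)) / avail
               for k, v in self.absorbed_by_class.items()}
        out["unabsorbed"] = 1.0 - sum(out.values())
        return out


def _common_grid(w1: np.ndarray, w2: np.ndarray) -> np.ndarray:
    lo, hi = max(w1[0], w2[0]), min(w1[-1], w2[-1])
    if hi <= lo:
        raise GridError("wavelength grids do not overlap")
    step = min(np.min(np.diff(w1)), np.min(np.diff(w2)))
    return np.arange(lo, hi + step / 2, step)


def absorbed_per_cell(cross_section: CellCrossSection,
                      irr: SpectralIrradiance) -> EnergyBudget:
    """Per-class absorbed photon flux aᵢ(λ)Cᵢ × E_photons(λ) × 1e9.

    Cross-section and irradiance are intersected onto a common grid.
    The returned budget has no availability cap yet (``available`` is
    NaN-free but the packaging clip is applied separately).
    """
    grid = _common_grid(cross_section.wavelengths, irr.wavelengths)
    e_phot = np.interp(grid, irr.wavelengths, irr.irradiance_photons)
    absorbed = {}
    for k, a in cross_section.by_class.items():
        a_g = np.interp(grid, cross_section.wavelengths, a)
        absorbed[k] = a_g * e_phot * UMOL_TO_FMOL
    return EnergyBudget(grid, absorbed,
                        available=np.full_like(grid, np.nan))


def available_per_cell(geometry: CellGeometry,
                       irr: SpectralIrradiance,
                       grid: np.ndarray | None = None) -> np.ndarray:
    """Photon flux geometrically available to a benthic cell
    (fmol photons·cell⁻¹·s⁻¹·nm⁻¹)."""
    if grid is None:
        grid = irr.wavelengths
        e_phot = irr.irradiance_photons
    else:
        e_phot = np.interp(grid, irr.wavelengths, irr.irradiance_photons)
    return e_phot * geometry.half_lateral_area_m2 * UMOL_TO_FMOL


def build_budget(cross_section: CellCrossSection, geometry: CellGeometry,
                 irr: SpectralIrradiance) -> EnergyBudget:
    """Absorbed and available flux on a shared grid, packaging-corrected."""
    b = absorbed_per_cell(cross_section, irr)
    avail = available_per_cell(geometry, irr, grid=b.wavelengths)
    return packaging_correction(
        EnergyBudget(b.wavelengths, b.absorbed_by_class, avail))


def packaging_correction(budget: EnergyBudget,
                         allocation: str = "proportional") -> EnergyBudget:
    """Clip absorbed flux to the available flux wavelength-by-wavelength.

    Reconstructed (unpackaged) absorption can exceed what the cell
    geometrically intercepts; at such wavelengths every class is
    rescaled by the common factor available/absorbed (``proportional``),
    or the phenolic class absorbs the residual after the others
    (``phenolics_last``).
    """
    total = budget.absorbed_total
    avail = np.asarray(budget.available, float)
    if np.any(total < 0) or np.any(avail < 0):
        raise InvalidMeasurementError("negative flux in packaging correction")
    over = total > avail
    if allocation == "proportional":
        with np.errstate(divide="ignore", invalid="ignore"):
            factor = np.where(over & (total > 0), avail / np.where(total > 0, total, 1.0), 1.0)
        corrected = {k: v * factor for k, v in budget.absorbed_by_class.items()}
    elif allocation == "phenolics_last":
        corrected = {k: np.asarray(v, float).copy()
                     for k, v in budget.absorbed_by_class.items()}
        others = np.sum([v for k, v in corrected.items() if k != "phenolic"], axis=0)
        if "phenolic" in corrected:
            corrected["phenolic"] = np.where(
                over, np.clip(avail - others, 0.0, None), corrected["phenolic"])
            others_over = others > avail
            scale = np.where(others_over & (others > 0),
                             avail / np.where(others > 0, others, 1.0), 1.0)
            corrected = {k: (v * scale if k != "phenolic" else v)
                         for k, v in corrected.items()}
        else:
            scale = np.where(over & (total > 0),
                             avail / np.where(total > 0, total, 1.0), 1.0)
            corrected = {k: v * scale for k, v in corrected.items()}
    else:
        raise ValueError(f"unknown allocation: {allocation!r}")
    return EnergyBudget(budget.wavelengths, corrected, avail, clipped=over)


# ---------------------------------------------------------------------------
# IRF and melt
# ---------------------------------------------------------------------------

def absorbed_power_per_cell(budget: EnergyBudget,
                            exclude_classes: Sequence[str] = CHLOROPHYLL_CLASSES
                            ) -> np.ndarray:
    """Per-cell absorbed power spectrum in W·cell⁻¹·nm⁻¹.

    Chlorophyll classes are excluded by default: light used for
    photochemistry is not dissipated as heat at the ice surface.
    """
    w = budget.wavelengths
    fmol = np.sum([v for k, v in budget.absorbed_by_class.items()
                   if k not in exclude_classes], axis=0)
    return energy_from_photons(fmol / UMOL_TO_FMOL, w)


def volume_to_area_factor(depth_cm: float = 2.0,
                          density_ratio: float = 0.9) -> float:
    """Melted-sample volume per unit ice surface, mL·m⁻².

    Abundances are counted per mL of melted surface ice sampled to
    ``depth_cm``; one m² of ice to that depth yields
    depth_cm × 1e4 cm³ of ice ≈ ×(ρ_ice/ρ_water) mL of meltwater.
    """
    if depth_cm <= 0 or density_ratio <= 0:
        raise InvalidMeasurementError("depth and density ratio must be positive")
    return depth_cm * 1e4 * density_ratio


def irf_per_m2(per_cell_power: np.ndarray, abundance: float,
               vol_to_area: float) -> np.ndarray:
    """Population IRF spectrum, W·m⁻²·h⁻¹·nm⁻¹ (i.e. J·m⁻²·h⁻¹·nm⁻¹/3600·3600).

    IRF(λ) = per-cell power (W·cell⁻¹·nm⁻¹) × abundance (cells·mL⁻¹)
    × vol_to_area (mL·m⁻²) × 3600 s·h⁻¹.  ``vol_to_area`` has no silent
    default; compute one with :func:`volume_to_area_factor`.
    """
    if abundance < 0:
        raise InvalidMeasurementError("abundance must be non-negative")
    if vol_to_area is None or vol_to_area <= 0:
        raise InvalidMeasurementError(
            "vol_to_area factor is required (see volume_to_area_factor)")
    return np.asarray(per_cell_power, float) * abundance * vol_to_area * 3600.0


def melt_from_irf(irf_spectrum: np.ndarray, wavelengths: np.ndarray,
                  lam_lo: float = MELT_WINDOW[0],
                  lam_hi: float = MELT_WINDOW[1]) -> float:
    """Hourly melt (cm w.e.) from an IRF spectrum in W·m⁻²·h⁻¹·nm⁻¹.

    melt = ∫IRF dλ × 1/(1e4 cm²·m⁻² × 334 J·cm⁻³); the ×3600 s·h⁻¹ is
    already inside the IRF units, so ∫IRF dλ is J·m⁻²·h⁻¹.
    """
    if lam_hi <= lam_lo:
        raise GridError("inverted wavelength range")
    w = np.asarray(wavelengths, float)
    m = (w >= lam_lo) & (w <= lam_hi)
    energy = float(np.trapezoid(np.asarray(irf_spectrum, float)[m], w[m]))
    return energy / (AREA_SCALE * LATENT_HEAT_FUSION)


@dataclass(frozen=True)
class AbundanceSample:
    """Measured cell abundances (cells·mL⁻¹) in one biomass category."""

    category: str
    abundances: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "abundances", np.asarray(self.abundances, float))
        if np.any(self.abundances <= 0):
            raise InvalidMeasurementError("abundances must be positive")

    @property
    def n(self) -> int:
        return int(self.abundances.size)

    @property
    def mean(self) -> float:
        return float(self.abundances.mean())

    @property
    def sd(self) -> float:
        return float(np.std(self.abundances, ddof=1)) if self.n > 1 else float("nan")

    @property
    def se(self) -> float:
        return self.sd / np.sqrt(self.n) if self.n > 1 else float("nan")


@dataclass(frozen=True)
class MeltResult:
    """Diel IRF/melt summary for one abundance category."""

    category: str
    hourly_irf_W_m2: np.ndarray     # spectrally integrated, at mean abundance
    hourly_melt_cm_we: np.ndarray   # at mean abundance
    daily_melt_per_abundance: np.ndarray
    daily_melt_mean: float
    daily_melt_sd: float
    daily_melt_se: float

    @property
    def daily_melt_cm_we(self) -> float:
        return float(np.sum(self.hourly_melt_cm_we))


def diel_melt(cross_section: CellCrossSection, geometry: CellGeometry,
              irradiance_series: Sequence[SpectralIrradiance],
              abundance_sample: AbundanceSample, vol_to_area: float,
              exclude_classes: Sequence[str] = CHLOROPHYLL_CLASSES,
              lam_lo: float = MELT_WINDOW[0],
              lam_hi: float = MELT_WINDOW[1]) -> MeltResult:
    """Diel-cycle melt generation for every abundance in a category.

    Requires the full 24 hourly spectra (no interpolation).  Melt is
    exactly linear in abundance, so per-abundance daily melt is the
    unit-abundance melt times each abundance; mean/SD/SE follow.
    """
    if len(irradiance_series) != 24:
        raise InvalidMeasurementError(
            f"need 24 hourly spectra, got {len(irradiance_series)}")
    unit_hourly_melt = np.empty(24)
    unit_hourly_irf = np.empty(24)
    for i, irr in enumerate(irradiance_series):
        budget = build_budget(cross_section, geometry, irr)
        power = absorbed_power_per_cell(budget, exclude_classes)
        irf = irf_per_m2(power, 1.0, vol_to_area)
        unit_hourly_melt[i] = melt_from_irf(irf, budget.wavelengths, lam_lo, lam_hi)
        w = budget.wavelengths
        m = (w >= lam_lo) & (w <= lam_hi)
        unit_hourly_irf[i] = float(np.trapezoid(irf[m], w[m])) / 3600.0  # W·m⁻²
    daily_unit = float(np.sum(unit_hourly_melt))
    per_ab = daily_unit * abundance_sample.abundances
    n = abundance_sample.n
    sd = float(np.std(per_ab, ddof=1)) if n > 1 else float("nan")
    return MeltResult(
        category=abundance_sample.category,
        hourly_irf_W_m2=unit_hourly_irf * abundance_sample.mean,
        hourly_melt_cm_we=unit_hourly_melt * abundance_sample.mean,
        daily_melt_per_abundance=per_ab,
        daily_melt_mean=float(per_ab.mean()),
        daily_melt_sd=sd,
        daily_melt_se=sd / np.sqrt(n) if n > 1 else float("nan"))
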