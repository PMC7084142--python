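"""Synthetic inputs with the statistical structure of the field data.

Every stage of the analysis can run offline: generators here emulate
rapid light curves (saturating, optionally photoinhibited, reaching
4,000 µmol photons·m⁻²·s⁻¹), phenolic-dominated absorption spectra
(UV-B maximum at 300 nm, 335-nm shoulder, red-decreasing visible tail),
extract calibration series (53 samples spanning 187–2.1×10⁴ cells·mL⁻¹),
diel clear-sky spectral irradiance (solar-geometry envelope × smooth
solar template, ~1,700 µmol photons·m⁻²·s⁻¹ peak PAR), an ablation-season
hourly forcing with snow retreat, and zero-truncated lognormal abundance
categories moment-matched to the field means/SDs.

All randomness flows through an explicit ``numpy.random.Generator``
seeded per call; identical arguments give bitwise-identical outputs.
Spectral shapes are smooth analytic forms, not digitized figures.
"""

from __future__ import annotations

import datetime as _dt
from typing import Sequence

import numpy as np
import pandas as pd

from .biooptics import (PigmentProfile, PigmentSpectrum, CalibrationSet,
                        WAVELENGTH_GRID, reconstruct_cross_section,
                        class_fraction_at)
from .energy_budget import AbundanceSample, SpectralIrradiance
from .exceptions import InvalidMeasurementError
from .photophysiology import RLCCurve, platt_model, platt_retrmax

#: The nine-step actinic sequence, 0–4,000 µmol photons·m⁻²·s⁻¹.
DEFAULT_E_STEPS = np.array([0.0, 50, 100, 250, 500, 1000, 1500, 2500, 4000])

#: Field abundance categories: mean, SD (cells·mL⁻¹) and sample size.
ABUNDANCE_CATEGORIES = {
    "low": (186.0, 276.0, 27),
    "medium": (3711.0, 2333.0, 34),
    "high": (8989.0, 4773.0, 103),
}

#: Phenolic content per cell, mg (0.041 ng·cell⁻¹).
PHENOLIC_CONTENT_MG = 4.1e-8


# ---------------------------------------------------------------------------
# rapid light curves
# ---------------------------------------------------------------------------

def gen_rlc(alpha: float = 0.45, retrmax: float = 420.0, beta: float = 0.0,
            noise_cv: float = 0.0, steps: np.ndarray = DEFAULT_E_STEPS,
            seed: int = 0, sample_id: str = "synthetic",
            dark_fvfm: float = 0.65, psii_fraction: float = 0.5) -> RLCCurve:
    """Forward-simulate one RLC from a Platt-type P–E model.

    Y(PSII) at each step is the model rETR divided by E×psii_fraction;
    multiplicative Gaussian noise of coefficient ``noise_cv`` perturbs
    the yields, which are then embedded in fluorescence pairs (F, Fm′)
    with an irradiance-saturating quenching of Fm′.  The implied yields
    must stay within [0, 1]; parameter sets violating that (e.g. very
    large α) cannot be expressed as physical fluorescence and raise.
    """
    if noise_cv < 0:
        raise InvalidMeasurementError("noise_cv must be non-negative")
    rng = np.random.default_rng(seed)
    E = np.asarray(steps, float)
    ps = retrmax if beta == 0 else _ps_from_retrmax(retrmax, alpha, beta)
    retr = platt_model(E, ps, alpha, beta)
    with np.errstate(divide="ignore", invalid="ignore"):
        y = np.where(E > 0, retr / (E * psii_fraction), dark_fvfm)
    if np.any(y > 1.0 + 1e-12):
        raise InvalidMeasurementError(
            "implied Y(PSII) exceeds 1; parameters not expressible as yields "
            "(use fit_rlc_points on raw rETR instead)")
    if noise_cv > 0:
        y = y * (1.0 + noise_cv * rng.standard_normal(y.size))
        y = np.clip(y, 0.0, 0.999)
    dark_Fm = 1000.0
    dark_F0 = dark_Fm * (1.0 - dark_fvfm)
    npq_sv = 1.5 * E / (E + 800.0)  # Stern–Volmer quench rising with E
    Fm_prime = dark_Fm / (1.0 + npq_sv)
    F = Fm_prime * (1.0 - y)
    return RLCCurve(sample_id=sample_id, dark_F0=dark_F0, dark_Fm=dark_Fm,
                    E=E, F=F, Fm_prime=Fm_prime)


def _ps_from_retrmax(retrmax: float, alpha: float, beta: float) -> float:
    """Invert the analytic maximum to the Platt scale parameter Ps."""
    factor = (alpha / (alpha + beta)) * (beta / (alpha + beta)) ** (beta / alpha)
    return retrmax / factor


def gen_rlc_set(n_curves: int, alpha: float = 0.45, retrmax: float = 420.0,
                beta: float = 0.0, noise_cv: float = 0.05,
                seed: int = 0, **kw) -> list[RLCCurve]:
    """Independent noisy replicates with derived per-curve seeds."""
    root = np.random.default_rng(seed)
    seeds = root.integers(0, 2**31 - 1, size=n_curves)
    return [gen_rlc(alpha, retrmax, beta, noise_cv, seed=int(s),
                    sample_id=f"synthetic-{i:03d}", **kw)
            for i, s in enumerate(seeds)]


# ---------------------------------------------------------------------------
# pigment spectra and calibration
# ---------------------------------------------------------------------------

def _gauss(w, mu, sigma):
    return np.exp(-0.5 * ((w - mu) / sigma) ** 2)


def phenolic_template(wavelengths: np.ndarray = WAVELENGTH_GRID) -> np.ndarray:
    """Unit-scale phenolic extract shape: UV-B peak at 300 nm, 335-nm
    shoulder, broad absorbance decreasing across the visible."""
    w = np.asarray(wavelengths, float)
    return (_gauss(w, 300.0, 14.0) + 0.5 * _gauss(w, 335.0, 13.0)
            + 0.28 * np.exp(-(w - 300.0) / 260.0))


def gen_phenolic_spectrum(scale: float = 0.26,
                          wavelengths: np.ndarray = WAVELENGTH_GRID
                          ) -> PigmentSpectrum:
    """Phenolic mass-absorption spectrum (m²·mg⁻¹) from the template."""
    return PigmentSpectrum("phenolic", np.asarray(wavelengths, float),
                           scale * phenolic_template(wavelengths))


def default_pigment_spectra(wavelengths: np.ndarray = WAVELENGTH_GRID
                            ) -> dict[str, PigmentSpectrum]:
    """SYNTHETIC stand-ins for literature in-vivo mass absorption of
    chlorophylls and carotenoids (Gaussian band composites at the
    canonical band positions; order-of-magnitude realistic, not
    transcribed values — nothing downstream depends on their exactness).
    """
    w = np.asarray(wavelengths, float)
    specs = {
        "chl_a": 0.020 * (_gauss(w, 435, 25) + 0.7 * _gauss(w, 675, 20)),
        "chl_b": 0.018 * (_gauss(w, 465, 22) + 0.45 * _gauss(w, 650, 18)),
        "ppc": 0.015 * _gauss(w, 470, 40),
        "psc": 0.012 * _gauss(w, 490, 35),
    }
    return {k: PigmentSpectrum(k, w, v) for k, v in specs.items()}


def default_cell_model(fraction_660: float = 0.94,
                       wavelengths: np.ndarray = WAVELENGTH_GRID
                       ) -> tuple[dict[str, PigmentSpectrum], PigmentProfile]:
    """Pigment spectra + cellular contents of a representative cell.

    Contents reflect the measured hierarchy (phenolics ≈ 11× chl a,
    0.041 ng phenol per cell); the phenolic spectrum amplitude is
    inverse-designed so phenolics contribute ``fraction_660`` (default
    94 %) of total cellular absorption at 660 nm.
    """
    if not 0.0 < fraction_660 < 1.0:
        raise InvalidMeasurementError("fraction_660 must lie in (0, 1)")
    w = np.asarray(wavelengths, float)
    spectra = default_pigment_spectra(w)
    contents = {"phenolic": PHENOLIC_CONTENT_MG,
                "chl_a": PHENOLIC_CONTENT_MG / 11.0,
                "chl_b": 1.2e-9, "ppc": 2.0e-9}
    idx = int(np.argmin(np.abs(w - 660.0)))
    others_660 = sum(spectra[k].mass_absorption[idx] * contents[k]
                     for k in contents if k != "phenolic")
    target_phen_660 = fraction_660 / (1.0 - fraction_660) * others_660
    template_660 = phenolic_template(w)[idx]
    scale = target_phen_660 / (PHENOLIC_CONTENT_MG * template_660)
    spectra["phenolic"] = gen_phenolic_spectrum(scale, w)
    return spectra, PigmentProfile(contents)


def default_cross_section(fraction_660: float = 0.94,
                          wavelengths: np.ndarray = WAVELENGTH_GRID):
    """Reconstructed cross-section of the representative cell; the
    phenolic fraction at 660 nm equals ``fraction_660`` by design."""
    spectra, profile = default_cell_model(fraction_660, wavelengths)
    cs = reconstruct_cross_section(profile, list(spectra.values()))
    assert abs(class_fraction_at(cs, "phenolic", 660.0) - fraction_660) < 1e-9
    return cs


def gen_calibration(e_true: np.ndarray, n_samples: int = 53,
                    conc_range: tuple[float, float] = (7.7e-6, 8.6e-4),
                    noise_cv: float = 0.0, path_length: float = 1.0,
                    seed: int = 0,
                    wavelengths: np.ndarray = WAVELENGTH_GRID) -> CalibrationSet:
    """Beer–Lambert calibration series A = e·c·l·(1+ε).

    Concentrations are log-uniform over ``conc_range`` (g·L⁻¹); the
    default range corresponds to 187–2.1×10⁴ cells·mL⁻¹ at the default
    phenolic quota, with n = 53 samples.  ``noise_cv`` is the relative
    SD of the multiplicative measurement noise.
    """
    if n_samples < 3:
        raise InvalidMeasurementError("need at least 3 calibration samples")
    lo, hi = conc_range
    if not 0 < lo < hi:
        raise InvalidMeasurementError("degenerate concentration range")
    rng = np.random.default_rng(seed)
    conc = np.exp(rng.uniform(np.log(lo), np.log(hi), size=n_samples))
    conc[0], conc[-1] = lo, hi  # pin the stated range
    e_true = np.asarray(e_true, float)
    A = np.outer(conc * path_length, e_true)
    if noise_cv > 0:
        A = A * (1.0 + noise_cv * rng.standard_normal(A.shape))
    cells_per_mL = conc / (PHENOLIC_CONTENT_MG * 1e-3) / 1e3  # g/L → cells/mL
    return CalibrationSet(np.asarray(wavelengths, float), A, conc,
                          path_length, cell_abundance=cells_per_mL)


# ---------------------------------------------------------------------------
# irradiance
# ---------------------------------------------------------------------------

def _solar_elevation_sin(latitude: float, doy: int, hour: float) -> float:
    """Sine of solar elevation from declination and hour angle."""
    decl = np.deg2rad(-23.44) * np.cos(2 * np.pi * (doy + 10) / 365.0)
    phi = np.deg2rad(latitude)
    H = np.deg2rad(15.0 * (hour - 12.0))
    return float(np.sin(phi) * np.sin(decl) + np.cos(phi) * np.cos(decl) * np.cos(H))


def solar_spectrum_template(wavelengths: np.ndarray) -> np.ndarray:
    """Smooth clear-sky energy spectrum shape: ~5,800 K Planck curve with
    a sigmoidal ozone/Rayleigh cutoff below ~315 nm.  Arbitrary scale."""
    w_m = np.asarray(wavelengths, float) * 1e-9
    planck = w_m ** -5 / np.expm1(1.4388e-2 / (w_m * 5800.0))
    cutoff = 1.0 / (1.0 + np.exp(-(np.asarray(wavelengths, float) - 315.0) / 10.0))
    return planck * cutoff


def gen_irradiance_day(latitude: float = 67.0,
                       date: str | _dt.date = "2016-07-26",
                       peak_par: float = 1700.0,
                       wavelengths: np.ndarray | None = None,
                       seed: int = 0) -> list[SpectralIrradiance]:
    """24 hourly clear-sky spectra (280–750 nm, 1-nm grid by default).

    The spectral shape is fixed; the amplitude follows the sine of
    solar elevation, normalized so the solar-noon PAR (400–700 nm
    photon integral) equals ``peak_par`` µmol photons·m⁻²·s⁻¹.
    Deterministic: the seed is accepted for interface uniformity.
    """
    if abs(latitude) > 90:
        raise InvalidMeasurementError("latitude must lie in [-90, 90]")
    date = _dt.date.fromisoformat(date) if isinstance(date, str) else date
    doy = date.timetuple().tm_yday
    w = np.arange(280.0, 751.0) if wavelengths is None else np.asarray(wavelengths, float)
    shape = solar_spectrum_template(w)
    # normalize: unit-amplitude spectrum has PAR == 1
    probe = SpectralIrradiance(None, w, shape)
    shape = shape / probe.total_par(400.0, 700.0)
    elev = np.array([_solar_elevation_sin(latitude, doy, h) for h in range(24)])
    noon = elev.max()
    if noon <= 0:
        amp = np.zeros(24)
    else:
        amp = peak_par * np.clip(elev, 0.0, None) / noon
    out = []
    for h in range(24):
        ts = _dt.datetime.combine(date, _dt.time(hour=h))
        out.append(SpectralIrradiance(ts, w, shape * amp[h]))
    return out


# ---------------------------------------------------------------------------
# seasonal forcing and abundances
# ---------------------------------------------------------------------------

def gen_forcing_season(start: str = "2016-06-01", end: str = "2016-09-01",
                       snow_free_date: str = "2016-06-25",
                       seed: int = 0) -> pd.DataFrame:
    """Hourly ablation-season forcing: snow height decaying to bare ice
    at ``snow_free_date`` (held strictly ≥ 2 cm before it), a diurnal
    shortwave cycle, and a diurnal+seasonal air-temperature cycle
    crossing the 0.5 °C melt threshold.  Columns: timestamp_iso, SH_cm,
    SWD_W_m2, TT_C.
    """
    t0 = pd.Timestamp(start)
    t1 = pd.Timestamp(end)
    if t0 >= t1:
        raise InvalidMeasurementError("start must precede end")
    idx = pd.date_range(t0, t1, freq="h", inclusive="left")
    rng = np.random.default_rng(seed)
    n = idx.size
    hours = idx.hour.to_numpy(float)
    frac = (idx - t0).total_seconds().to_numpy() / (t1 - t0).total_seconds()

    snow_free = pd.Timestamp(snow_free_date)
    t_to_free = (snow_free - t0).total_seconds()
    elapsed = (idx - t0).total_seconds().to_numpy()
    if t_to_free > 0:
        pre = elapsed < t_to_free
        sh = np.where(pre, 2.0 + 28.0 * (1.0 - elapsed / t_to_free), 0.0)
    else:
        sh = np.zeros(n)

    swd = 650.0 * np.clip(np.sin(np.pi * (hours - 4.0) / 16.0), 0.0, None)
    swd = np.clip(swd + rng.normal(0.0, 15.0, n), 0.0, None)

    seasonal = -1.0 + 5.0 * np.sin(np.pi * frac)
    tt = seasonal + 3.0 * np.cos(2 * np.pi * (hours - 14.0) / 24.0)
    tt = tt + rng.normal(0.0, 0.4, n)

    return pd.DataFrame({"timestamp_iso": idx.strftime("%Y-%m-%dT%H:%M:%S"),
                         "SH_cm": sh, "SWD_W_m2": swd, "TT_C": tt})


def gen_abundances(category: str, seed: int = 0,
                   n: int | None = None) -> AbundanceSample:
    """Zero-truncated lognormal cell abundances moment-matched to the
    field category statistics (low 186±276 n=27, medium 3,711±2,333
    n=34, high 8,989±4,773 n=103 cells·mL⁻¹)."""
    if category not in ABUNDANCE_CATEGORIES:
        raise InvalidMeasurementError(
            f"category must be one of {sorted(ABUNDANCE_CATEGORIES)}")
    mean, sd, n_default = ABUNDANCE_CATEGORIES[category]
    n = n_default if n is None else n
    sigma2 = np.log(1.0 + (sd / mean) ** 2)
    mu = np.log(mean) - sigma2 / 2.0
    rng = np.random.default_rng(seed)
    vals = rng.lognormal(mu, np.sqrt(sigma2), size=n)
    return AbundanceSample(category, vals)


def gen_productivity_table(mu: float, K: float, n: int = 20,
                           noise_cv: float = 0.0, seed: int = 0
                           ) -> pd.DataFrame:
    """(biomass, net productivity) pairs from a logistic curve, for
    exercising the (µ, K) fitting helper."""
    rng = np.random.default_rng(seed)
    B = np.linspace(K / n, K * 0.95, n)
    g = mu * B * (1.0 - B / K)
    if noise_cv > 0:
        g = g * (1.0 + noise_cv * rng.standard_normal(n))
    return pd.DataFrame({"biomass_ngDW_mL": B, "net_productivity_ngDW_mL_d": g})
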