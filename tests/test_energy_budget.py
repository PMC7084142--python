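"""Per-cell energy budget, packaging clip, IRF and melt conversion."""

import numpy as np
import pytest

from cryoalgae import biooptics as bo
from cryoalgae import energy_budget as eb
from cryoalgae import synthetic as syn
from cryoalgae.exceptions import GridError, InvalidMeasurementError

W = np.arange(280.0, 751.0)


# ---------------------------------------------------------------------------
# photon/energy conversion
# ---------------------------------------------------------------------------

def test_photon_conversion_at_550nm():
    assert eb.photons_from_energy(1.0, 550.0) == pytest.approx(4.598, abs=1e-3)


def test_photon_conversion_zero():
    assert eb.photons_from_energy(0.0, 550.0) == 0.0


def test_round_trip_identity():
    x = np.linspace(0.01, 2.0, 100)
    lam = np.linspace(280, 750, 100)
    back = eb.energy_from_photons(eb.photons_from_energy(x, lam), lam)
    assert np.allclose(back, x, rtol=1e-12)


def test_nonpositive_wavelength_errors():
    with pytest.raises(InvalidMeasurementError):
        eb.photons_from_energy(1.0, 0.0)


# ---------------------------------------------------------------------------
# absorbed / available
# ---------------------------------------------------------------------------

def _flat_cs(value=1e-10):
    return bo.CellCrossSection(W, {"phenolic": np.full(W.size, value)})


def test_absorbed_unit_bookkeeping(flat_irradiance):
    """1e-10 m²/cell × 1 µmol photons/m²/s/nm → 0.1 fmol/cell/s/nm."""
    b = eb.absorbed_per_cell(_flat_cs(), flat_irradiance)
    assert np.allclose(b.absorbed_by_class["phenolic"], 0.1, rtol=1e-9)


def test_absorbed_zero_irradiance():
    dark = eb.SpectralIrradiance(None, W, np.zeros(W.size))
    b = eb.absorbed_per_cell(_flat_cs(), dark)
    assert np.all(b.absorbed_total == 0.0)


def test_absorbed_linear_in_irradiance(noon_irradiance):
    b1 = eb.absorbed_per_cell(_flat_cs(), noon_irradiance)
    double = eb.SpectralIrradiance(None, noon_irradiance.wavelengths,
                                   2.0 * noon_irradiance.irradiance_W)
    b2 = eb.absorbed_per_cell(_flat_cs(), double)
    assert np.allclose(b2.absorbed_total, 2.0 * b1.absorbed_total, rtol=1e-12)


def test_half_lateral_area_of_mean_cell():
    """π × 12.04 × 29.60 / 2 µm² = 559.8 µm² = 5.598e-10 m²."""
    assert eb.DEFAULT_CELL.half_lateral_area_m2 == pytest.approx(
        np.pi * 12.04 * 29.60 / 2 * 1e-12, rel=1e-12)
    assert eb.DEFAULT_CELL.half_lateral_area_m2 == pytest.approx(5.598e-10,
                                                                 rel=1e-3)


def test_available_proportional_to_length(flat_irradiance):
    a1 = eb.available_per_cell(eb.CellGeometry(29.60, 12.04), flat_irradiance)
    a2 = eb.available_per_cell(eb.CellGeometry(59.20, 12.04), flat_irradiance)
    assert np.allclose(a2, 2.0 * a1, rtol=1e-12)


# ---------------------------------------------------------------------------
# packaging correction
# ---------------------------------------------------------------------------

def _budget(absorbed_by_class, available):
    grid = np.arange(400.0, 400.0 + len(available))
    return eb.EnergyBudget(grid,
                           {k: np.asarray(v, float)
                            for k, v in absorbed_by_class.items()},
                           np.asarray(available, float))


def test_proportional_clip():
    b = eb.packaging_correction(_budget({"A": [1.5], "B": [0.5]}, [1.0]))
    assert b.absorbed_by_class["A"][0] == pytest.approx(0.75)
    assert b.absorbed_by_class["B"][0] == pytest.approx(0.25)
    assert b.absorbed_total[0] == pytest.approx(1.0)
    assert b.clipped[0]


def test_no_clip_when_under_available():
    b = eb.packaging_correction(_budget({"A": [0.5]}, [1.0]))
    assert b.absorbed_by_class["A"][0] == 0.5
    assert not b.clipped[0]


def test_phenolics_last_allocation():
    b = eb.packaging_correction(
        _budget({"phenolic": [1.5], "chl_a": [0.3]}, [1.0]),
        allocation="phenolics_last")
    assert b.absorbed_by_class["chl_a"][0] == pytest.approx(0.3)
    assert b.absorbed_by_class["phenolic"][0] == pytest.approx(0.7)


def test_packaging_conservation_random_sweep():
    """Corrected absorption never exceeds availability (1,000 random spectra)."""
    rng = np.random.default_rng(42)
    for _ in range(1000):
        n = 8
        absorbed = {"a": rng.uniform(0, 2, n), "b": rng.uniform(0, 2, n)}
        avail = rng.uniform(0.1, 2, n)
        b = eb.packaging_correction(_budget(absorbed, avail))
        assert np.all(b.absorbed_total <= b.available * (1 + 1e-12))


def test_fractions_partition_unity(default_cross_section, noon_irradiance):
    b = eb.build_budget(default_cross_section, eb.DEFAULT_CELL, noon_irradiance)
    fr = b.fractions()
    assert abs(sum(fr.values()) - 1.0) < 1e-9
    assert all(-1e-12 <= v <= 1.0 + 1e-12 for v in fr.values())


# ---------------------------------------------------------------------------
# IRF and melt
# ---------------------------------------------------------------------------

def test_irf_zero_abundance():
    irf = eb.irf_per_m2(np.ones(W.size) * 1e-12, 0.0, 1.8e4)
    assert np.all(irf == 0.0)


def test_irf_linear_in_abundance():
    p = np.linspace(1e-13, 1e-12, W.size)
    assert np.allclose(eb.irf_per_m2(p, 2000.0, 1.8e4),
                       2.0 * eb.irf_per_m2(p, 1000.0, 1.8e4), rtol=1e-15)


def test_irf_category_ratio():
    """IRF(high)/IRF(medium) = 8989/3711 everywhere, by linearity."""
    p = np.linspace(1e-13, 1e-12, W.size)
    hi = eb.irf_per_m2(p, 8989.0, 1.8e4)
    med = eb.irf_per_m2(p, 3711.0, 1.8e4)
    assert np.allclose(hi / med, 8989.0 / 3711.0, rtol=1e-12)


def test_missing_vol_to_area_errors():
    with pytest.raises(InvalidMeasurementError):
        eb.irf_per_m2(np.ones(3), 100.0, None)


def test_volume_to_area_default():
    assert eb.volume_to_area_factor() == pytest.approx(1.8e4)


def test_melt_unit_identity():
    """One hour of 334e4/3600 W/m² (≈927.78) melts exactly 1 cm w.e."""
    power = eb.LATENT_HEAT_FUSION * eb.AREA_SCALE / 3600.0
    width = eb.MELT_WINDOW[1] - eb.MELT_WINDOW[0]
    irf = np.full(W.size, power * 3600.0 / width)  # W·m⁻²·h⁻¹·nm⁻¹, flat
    assert eb.melt_from_irf(irf, W) == pytest.approx(1.0, abs=1e-6)


def test_melt_zero():
    assert eb.melt_from_irf(np.zeros(W.size), W) == 0.0


def test_melt_halved_window():
    irf = np.full(W.size, 5.0)
    full = eb.melt_from_irf(irf, W, 280, 750)
    half = eb.melt_from_irf(irf, W, 280, 515)
    assert half == pytest.approx(full / 2, rel=1e-12)


def test_melt_inverted_window_errors():
    with pytest.raises(GridError):
        eb.melt_from_irf(np.ones(W.size), W, 700, 400)


def test_chlorophyll_exclusion_never_increases_power(default_cross_section,
                                                     noon_irradiance):
    b = eb.build_budget(default_cross_section, eb.DEFAULT_CELL, noon_irradiance)
    with_chl = eb.absorbed_power_per_cell(b, exclude_classes=())
    without = eb.absorbed_power_per_cell(b)
    assert np.all(without <= with_chl + 1e-30)


# ---------------------------------------------------------------------------
# diel melt
# ---------------------------------------------------------------------------

def test_all_night_zero_melt(default_cross_section):
    dark = [eb.SpectralIrradiance(h, W, np.zeros(W.size)) for h in range(24)]
    sample = eb.AbundanceSample("high", np.array([1000.0, 5000.0]))
    res = eb.diel_melt(default_cross_section, eb.DEFAULT_CELL, dark, sample,
                       eb.volume_to_area_factor())
    assert res.daily_melt_mean == 0.0
    assert np.all(res.hourly_melt_cm_we == 0.0)


def test_single_abundance_se_undefined(default_cross_section, diel_irradiance):
    sample = eb.AbundanceSample("high", np.array([8989.0]))
    res = eb.diel_melt(default_cross_section, eb.DEFAULT_CELL, diel_irradiance,
                       sample, eb.volume_to_area_factor())
    assert np.isnan(res.daily_melt_se)
    assert res.daily_melt_mean > 0


def test_category_mean_equals_melt_at_mean_abundance(default_cross_section,
                                                     diel_irradiance):
    """Linearity: the category-mean daily melt equals the melt evaluated
    at the mean abundance, verified against a per-sample brute force."""
    sample = syn.gen_abundances("medium", seed=3)
    v2a = eb.volume_to_area_factor()
    res = eb.diel_melt(default_cross_section, eb.DEFAULT_CELL, diel_irradiance,
                       sample, v2a)
    brute = []
    for a in sample.abundances:
        one = eb.diel_melt(default_cross_section, eb.DEFAULT_CELL,
                           diel_irradiance,
                           eb.AbundanceSample("x", np.array([a])), v2a)
        brute.append(one.daily_melt_cm_we)
    assert np.allclose(res.daily_melt_per_abundance, brute, rtol=1e-12)
    assert res.daily_melt_mean == pytest.approx(np.mean(brute), rel=1e-12)
    assert res.daily_melt_mean == pytest.approx(res.daily_melt_cm_we, rel=1e-12)


def test_missing_hours_error(default_cross_section, diel_irradiance):
    sample = eb.AbundanceSample("low", np.array([186.0]))
    with pytest.raises(InvalidMeasurementError):
        eb.diel_melt(default_cross_section, eb.DEFAULT_CELL,
                     diel_irradiance[:23], sample, 1.8e4)
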