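"""Fluorescence quantities, RLC fitting and the phenolic-shading correction."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from cryoalgae import photophysiology as pp
from cryoalgae import synthetic as syn
from cryoalgae.exceptions import (DegenerateCurveError, InsufficientDataError,
                                  InvalidMeasurementError)

E9 = syn.DEFAULT_E_STEPS


# ---------------------------------------------------------------------------
# scalar quantities
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("f0,fm,expected", [
    (100, 400, 0.75), (0, 350, 1.0), (350, 350, 0.0)])
def test_fvfm_examples(f0, fm, expected):
    assert pp.compute_fvfm(f0, fm) == pytest.approx(expected, abs=1e-12)


@pytest.mark.parametrize("f0,fm", [(100, 0), (100, -5), (500, 400)])
def test_fvfm_invalid(f0, fm):
    with pytest.raises(InvalidMeasurementError):
        pp.compute_fvfm(f0, fm)


@pytest.mark.parametrize("y,E,expected", [
    (0.6, 100, 30.0), (0.75, 0, 0.0), (0.0, 4000, 0.0)])
def test_retr_examples(y, E, expected):
    assert pp.compute_retr(y, E) == pytest.approx(expected, abs=1e-12)


def test_retr_domain_error():
    with pytest.raises(InvalidMeasurementError):
        pp.compute_retr(1.2, 100)


@pytest.mark.parametrize("fm,fmp,conv,expected", [
    (400, 250, "fm", 0.375),
    (400, 400, "fm", 0.0),
    (400, 250, "stern_volmer", 0.6)])
def test_npq_examples(fm, fmp, conv, expected):
    assert pp.compute_npq(fm, fmp, conv) == pytest.approx(expected, abs=1e-12)


def test_npq_negative_clamped_to_zero(caplog):
    # a transient Fm' rise above Fm must not yield negative quenching
    assert pp.compute_npq(400, 410) == 0.0


@given(f0=st.floats(0, 1e3), dfm=st.floats(1e-6, 1e3))
@settings(derandomize=True, max_examples=50)
def test_fvfm_always_in_unit_interval(f0, dfm):
    assert 0.0 <= pp.compute_fvfm(f0, f0 + dfm) <= 1.0


@given(fmp=st.floats(1e-3, 400), dfm=st.floats(0, 400))
@settings(derandomize=True, max_examples=50)
def test_npq_fm_convention_in_unit_interval(fmp, dfm):
    assert 0.0 <= pp.compute_npq(fmp + dfm, fmp) < 1.0


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------

def test_noiseless_platt_recovery():
    """Forward-generated noiseless curve must be inverted essentially exactly."""
    retr = pp.platt_model(E9, 60.0, 0.3, 0.0)
    fit = pp.fit_rlc_points(E9, retr)
    assert fit.alpha == pytest.approx(0.3, rel=1e-6)
    assert fit.rETRmax == pytest.approx(60.0, rel=1e-6)
    assert fit.Ek == pytest.approx(200.0, rel=1e-6)


def test_noiseless_recovery_with_photoinhibition():
    alpha, beta = 0.3, 0.3 / 50
    ps = syn._ps_from_retrmax(60.0, alpha, beta)
    retr = pp.platt_model(E9, ps, alpha, beta)
    fit = pp.fit_rlc_points(E9, retr)
    assert fit.alpha == pytest.approx(alpha, rel=1e-5)
    assert fit.beta == pytest.approx(beta, rel=1e-5)
    assert fit.rETRmax == pytest.approx(60.0, rel=1e-5)
    # the analytic maximum lies below the scale parameter when beta > 0
    assert fit.rETRmax < fit.ps


def test_webb_model_fit():
    retr = pp.webb_model(E9, 60.0, 0.3)
    fit = pp.fit_rlc_points(E9, retr, model_name="webb_exponential")
    assert fit.beta == 0.0
    assert fit.alpha == pytest.approx(0.3, rel=1e-6)
    assert fit.rETRmax == pytest.approx(60.0, rel=1e-6)


def test_noisy_recovery_median_within_10pct():
    curves = syn.gen_rlc_set(100, alpha=0.3, retrmax=60.0, noise_cv=0.05, seed=7)
    alphas = np.array([pp.fit_rlc(c).alpha for c in curves])
    med_err = np.median(np.abs(alphas - 0.3) / 0.3)
    assert med_err <= 0.10


def test_all_zero_retr_degenerate():
    with pytest.raises(DegenerateCurveError):
        pp.fit_rlc_points(E9, np.zeros_like(E9))


def test_too_few_steps():
    with pytest.raises(InsufficientDataError):
        pp.fit_rlc_points([0, 100, 200, 300], [0, 10, 15, 18])


def test_ek_identity_enforced():
    fit = pp.RLCFit("platt_photoinhibition", alpha=0.25, rETRmax=50.0, beta=0.0)
    assert abs(fit.Ek - fit.rETRmax / fit.alpha) <= 1e-12 * fit.Ek


def test_axis_scaling_property():
    """Scaling E by s scales rETRmax and Ek by s and leaves alpha fixed."""
    retr = pp.platt_model(E9, 60.0, 0.3, 0.0)
    base = pp.fit_rlc_points(E9, retr)
    s = 3.7
    scaled = pp.fit_rlc_points(E9 * s, retr)
    assert scaled.alpha == pytest.approx(base.alpha / s, rel=1e-6)
    assert scaled.rETRmax == pytest.approx(base.rETRmax, rel=1e-6)
    assert scaled.Ek == pytest.approx(base.Ek * s, rel=1e-6)


def test_predicted_curve_monotone_when_no_photoinhibition():
    fit = pp.fit_rlc_points(E9, pp.platt_model(E9, 60.0, 0.3, 0.0))
    grid = np.linspace(0, 4000, 500)
    assert np.all(np.diff(fit.predict(grid)) >= -1e-12)


# ---------------------------------------------------------------------------
# shading correction
# ---------------------------------------------------------------------------

def test_shading_zero_is_identity():
    curve = syn.gen_rlc(noise_cv=0)
    corrected = pp.apply_shading_correction(curve, 0.0)
    f1, f2 = pp.fit_rlc(curve), pp.fit_rlc(corrected)
    assert f1.alpha == pytest.approx(f2.alpha, rel=1e-12)
    assert f1.Ek == pytest.approx(f2.Ek, rel=1e-12)


def test_shading_94pct_scales_ek():
    """Whole-cell Ek≈938 becomes chloroplast-level Ek = 0.06×938 = 56.28."""
    curve = syn.gen_rlc(alpha=0.45, retrmax=0.45 * 938, noise_cv=0)
    whole = pp.fit_rlc(curve)
    assert whole.Ek == pytest.approx(938.0, rel=1e-6)
    chloro = pp.fit_rlc(pp.apply_shading_correction(curve, 0.94))
    assert chloro.Ek == pytest.approx(938.0 * 0.06, rel=1e-6)
    # both axes shrink by (1-p): the initial slope alpha is invariant
    assert chloro.alpha == pytest.approx(whole.alpha, rel=1e-6)


def test_shading_half_keeps_slope():
    """E and rETR both halve under p=0.5, so the initial slope is invariant."""
    curve = syn.gen_rlc(alpha=0.45, retrmax=420.0, noise_cv=0)
    whole = pp.fit_rlc(curve)
    half = pp.fit_rlc(pp.apply_shading_correction(curve, 0.5))
    # yields are unchanged, so rETR = Y·E'·0.5 halves along with E'
    assert half.alpha == pytest.approx(whole.alpha, rel=1e-6)
    assert half.rETRmax == pytest.approx(whole.rETRmax / 2, rel=1e-6)
    assert half.Ek == pytest.approx(whole.Ek / 2, rel=1e-6)


def test_full_shading_gives_dark_curve():
    curve = syn.gen_rlc(noise_cv=0)
    with pytest.raises(DegenerateCurveError):
        pp.apply_shading_correction(curve, 1.0)


# ---------------------------------------------------------------------------
# group summaries and I/O
# ---------------------------------------------------------------------------

def _fit_with_ek(ek, alpha=0.3):
    return pp.RLCFit("platt_photoinhibition", alpha=alpha,
                     rETRmax=alpha * ek, beta=0.0)


def test_group_comparison_arithmetic():
    group = [_fit_with_ek(e) for e in (40, 46, 52)]
    table = pp.compare_rlc_groups(group, group)
    ek = table[(table["parameter"] == "Ek") & (table["group"] == "a")].iloc[0]
    assert ek["mean"] == pytest.approx(46.0)
    assert ek["se"] == pytest.approx(6.0 / np.sqrt(3), rel=1e-6)  # SD=6, n=3
    # identical groups: zero difference in every parameter mean
    a = table[table["group"] == "a"].set_index("parameter")["mean"]
    b = table[table["group"] == "b"].set_index("parameter")["mean"]
    assert (a == b).all()


def test_single_fit_group_se_undefined():
    table = pp.compare_rlc_groups([_fit_with_ek(40)], [_fit_with_ek(50)])
    assert table["se"].isna().all()


def test_empty_group_errors():
    with pytest.raises(InsufficientDataError):
        pp.compare_rlc_groups([], [_fit_with_ek(40)])


def test_rlc_csv_round_trip(tmp_path):
    import pandas as pd
    curve = syn.gen_rlc(noise_cv=0)
    rows = [{"sample_id": curve.sample_id, "step_index": 0,
             "E_umol_m2_s": 0.0, "F": curve.dark_F0,
             "Fm_prime": curve.dark_Fm}]
    for i in range(curve.E.size):
        rows.append({"sample_id": curve.sample_id, "step_index": i + 1,
                     "E_umol_m2_s": curve.E[i] + (i == 0) * 1e-9,
                     "F": curve.F[i], "Fm_prime": curve.Fm_prime[i]})
    path = tmp_path / "rlc.csv"
    pd.DataFrame(rows[:1] + rows[2:]).to_csv(path, index=False)  # drop dup E=0
    curves = pp.read_rlc_csv(path)
    assert len(curves) == 1
    fit = pp.fit_rlc(curves[0])
    assert fit.alpha == pytest.approx(0.45, rel=1e-6)
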