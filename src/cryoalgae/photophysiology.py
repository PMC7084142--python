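"""Chlorophyll-fluorescence photophysiology: quantum yields, NPQ and
rapid-light-curve (RLC) fitting.

An RLC steps a dark-adapted sample through increasing actinic irradiance
E (µmol photons·m⁻²·s⁻¹), recording the steady-state yield F and the
saturating-pulse maximum Fm′ at each step.  Relative electron transport
through photosystem II is

    rETR = Y(PSII) × E × 0.5,    Y(PSII) = (Fm′ − F)/Fm′,

the 0.5 assuming equal excitation of PSI and PSII.  The rETR–E response
is fitted with a saturating model with optional photoinhibition
(Platt-type double exponential) yielding the light-utilisation
efficiency α, the maximum rate rETRmax and the saturation irradiance
Ek = rETRmax/α.

Glacier algae screen their chloroplasts with vacuolar phenolic pigment;
at the fluorometer wavelength (660 nm) ~94 % of cellular absorption is
phenolic, so the chloroplasts see only ~6 % of the applied excitation.
``apply_shading_correction`` rescales E accordingly; refitting the
corrected curve gives chloroplast-level parameters.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .exceptions import (
    DegenerateCurveError,
    InsufficientDataError,
    InvalidMeasurementError,
)

logger = logging.getLogger(__name__)

#: PSII/PSI excitation split assumed when converting quantum yield to rETR.
PSII_FRACTION = 0.5

#: Minimum number of non-dark steps required for curve fitting.
MIN_FIT_STEPS = 4


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RLCCurve:
    """A rapid light curve: dark yields plus ordered actinic light steps.

    Parameters
    ----------
    sample_id
        Free-text sample label.
    dark_F0, dark_Fm
        Minimum and maximum fluorescence yield in the dark-adapted state
        (arbitrary units), ``dark_Fm >= dark_F0 >= 0``.
    E, F, Fm_prime
        Per-step incident PAR (µmol photons·m⁻²·s⁻¹, non-negative and
        strictly increasing), steady-state yield and light-adapted
        maximum yield, ``Fm_prime >= F >= 0``.
    """

    sample_id: str
    dark_F0: float
    dark_Fm: float
    E: np.ndarray
    F: np.ndarray
    Fm_prime: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "E", np.asarray(self.E, dtype=float))
        object.__setattr__(self, "F", np.asarray(self.F, dtype=float))
        object.__setattr__(self, "Fm_prime", np.asarray(self.Fm_prime, dtype=float))
        if not (self.E.shape == self.F.shape == self.Fm_prime.shape):
            raise InvalidMeasurementError("E, F, Fm_prime must have equal length")
        if np.any(self.E < 0):
            raise InvalidMeasurementError("incident PAR must be non-negative")
        if np.any(np.diff(self.E) <= 0):
            raise InvalidMeasurementError("E values must be strictly increasing")
        if not (self.dark_Fm >= self.dark_F0 >= 0):
            raise InvalidMeasurementError("require dark_Fm >= dark_F0 >= 0")
        if np.any(self.F < 0) or np.any(self.Fm_prime < self.F):
            raise InvalidMeasurementError("require Fm_prime >= F >= 0 at every step")

    @property
    def y_psii(self) -> np.ndarray:
        """Effective PSII quantum yield (Fm′−F)/Fm′ per step (0 where Fm′=0)."""
        with np.errstate(divide="ignore", invalid="ignore"):
            y = np.where(self.Fm_prime > 0,
                         (self.Fm_prime - self.F) / self.Fm_prime, 0.0)
        return y

    def retr(self, psii_fraction: float = PSII_FRACTION) -> np.ndarray:
        """Relative electron transport rate per step."""
        return self.y_psii * self.E * psii_fraction


@dataclass(frozen=True)
class RLCFit:
    """Fitted photosynthesis–irradiance parameters of one RLC.

    ``Ek = rETRmax/alpha`` holds by construction.  For the
    photoinhibited model ``rETRmax`` is the analytic maximum of the
    fitted curve, which differs from the scale parameter Ps when β>0.
    """

    model_name: str
    alpha: float
    rETRmax: float
    beta: float
    Ek: float = field(init=False)
    rss: float = 0.0
    converged: bool = True
    ps: float = float("nan")
    sample_id: str = ""

    def __post_init__(self) -> None:
        if self.alpha <= 0 or self.rETRmax <= 0:
            raise InvalidMeasurementError("alpha and rETRmax must be positive")
        if self.beta < 0:
            raise InvalidMeasurementError("beta must be non-negative")
        object.__setattr__(self, "Ek", self.rETRmax / self.alpha)

    def predict(self, E: np.ndarray) -> np.ndarray:
        if self.model_name == "webb_exponential":
            return webb_model(np.asarray(E, float), self.rETRmax, self.alpha)
        return platt_model(np.asarray(E, float), self.ps, self.alpha, self.beta)


@dataclass(frozen=True)
class ShadingFactor:
    """Fraction of total cellular absorption due to phenolics at one λ."""

    wavelength: float
    fraction_phenolic: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.fraction_phenolic <= 1.0:
            raise InvalidMeasurementError("fraction_phenolic must lie in [0, 1]")


# ---------------------------------------------------------------------------
# scalar quantities
# ---------------------------------------------------------------------------

def compute_fvfm(dark_F0: float, dark_Fm: float) -> float:
    """Maximum quantum efficiency of PSII, (Fm − F0)/Fm ∈ [0, 1]."""
    if dark_Fm <= 0:
        raise InvalidMeasurementError("dark Fm must be positive")
    if not 0 <= dark_F0 <= dark_Fm:
        raise InvalidMeasurementError("require 0 <= F0 <= Fm")
    return (dark_Fm - dark_F0) / dark_Fm


def compute_retr(y_psii: float, E: float,
                 psii_fraction: float = PSII_FRACTION) -> float:
    """rETR = Y(PSII) × E × psii_fraction (default split 0.5)."""
    y = np.asarray(y_psii, float)
    if np.any((y < 0) | (y > 1)):
        raise InvalidMeasurementError("Y(PSII) must lie in [0, 1]")
    if np.any(np.asarray(E, float) < 0):
        raise InvalidMeasurementError("E must be non-negative")
    return y_psii * E * psii_fraction


def compute_npq(Fm: float, Fm_prime: float, convention: str = "fm") -> float:
    """Non-photochemical quenching from dark Fm and light-adapted Fm′.

    ``convention="fm"`` computes (Fm − Fm′)/Fm; ``"stern_volmer"``
    computes the conventional Stern–Volmer form (Fm − Fm′)/Fm′.
    Fm′ > Fm (apparent negative quenching, seen transiently in noisy
    field data) is clamped to 0 with a logged warning.
    """
    if Fm <= 0 or Fm_prime <= 0:
        raise InvalidMeasurementError("Fm and Fm_prime must be positive")
    if Fm_prime > Fm:
        logger.warning("Fm_prime (%g) exceeds Fm (%g); NPQ clamped to 0",
                       Fm_prime, Fm)
        return 0.0
    if convention == "fm":
        return (Fm - Fm_prime) / Fm
    if convention in ("stern_volmer", "stern_volmer_prime"):
        return (Fm - Fm_prime) / Fm_prime
    raise ValueError(f"unknown NPQ convention: {convention!r}")


# ---------------------------------------------------------------------------
# P–E models
# ---------------------------------------------------------------------------

def platt_model(E, ps, alpha, beta):
    """Saturating P–E curve with photoinhibition:
    rETR(E) = Ps·(1 − exp(−αE/Ps))·exp(−βE/Ps)."""
    E = np.asarray(E, float)
    return ps * (1.0 - np.exp(-alpha * E / ps)) * np.exp(-beta * E / ps)


def webb_model(E, retrmax, alpha):
    """Exponential saturating P–E curve: rETR(E) = Pm·(1 − exp(−αE/Pm))."""
    E = np.asarray(E, float)
    return retrmax * (1.0 - np.exp(-alpha * E / retrmax))


def platt_retrmax(ps: float, alpha: float, beta: float) -> float:
    """Analytic maximum of the photoinhibited curve over E ≥ 0.

    For β>0 the curve peaks below Ps:
    Pmax = Ps·(α/(α+β))·(β/(α+β))^(β/α); for β=0 the plateau is Ps.
    """
    if beta <= 0:
        return ps
    return ps * (alpha / (alpha + beta)) * (beta / (alpha + beta)) ** (beta / alpha)


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------

def fit_rlc_points(E: np.ndarray, retr: np.ndarray,
                   model_name: str = "platt_photoinhibition",
                   n_starts: int = 5, seed: int = 12345,
                   sample_id: str = "") -> RLCFit:
    """Least-squares fit of rETR vs E observations.

    The dark step (E=0) is excluded from the objective: rETR is
    identically zero there and conveys no slope information.  A bounded
    multistart (default 5 seeded starts around a slope/plateau initial
    guess) guards against local minima; if no start converges the best
    candidate is returned with ``converged=False``.
    """
    E = np.asarray(E, dtype=float)
    retr = np.asarray(retr, dtype=float)
    mask = E > 0
    E, retr = E[mask], retr[mask]
    if E.size < MIN_FIT_STEPS:
        raise InsufficientDataError(
            f"need >= {MIN_FIT_STEPS} non-dark steps, got {E.size}")
    if np.all(retr == 0):
        raise DegenerateCurveError("all rETR values are zero")

    # initial guesses: alpha from the initial slope, Ps from the plateau
    order = np.argsort(E)
    Es, Ps_obs = E[order], retr[order]
    alpha0 = max(Ps_obs[0] / Es[0], 1e-8)
    if Es.size >= 2 and Es[1] > Es[0]:
        slope2 = (Ps_obs[1] - Ps_obs[0]) / (Es[1] - Es[0])
        if slope2 > 0:
            alpha0 = max(alpha0, slope2)
    ps0 = max(float(np.max(retr)), 1e-8)

    if model_name == "webb_exponential":
        def resid(theta):
            return webb_model(E, np.exp(theta[0]), np.exp(theta[1])) - retr
        x0 = np.log([ps0, alpha0])
    elif model_name == "platt_photoinhibition":
        # beta through softplus-free positive parameterization: beta = exp(t)-tiny
        def resid(theta):
            ps, alpha = np.exp(theta[0]), np.exp(theta[1])
            beta = theta[2] ** 2  # >= 0, allows exact zero
            return platt_model(E, ps, alpha, beta) - retr
        x0 = np.concatenate([np.log([ps0, alpha0]), [0.0]])
    else:
        raise ValueError(f"unknown model: {model_name!r}")

    rng = np.random.default_rng(seed)
    best = None
    starts = [x0] + [x0 + rng.normal(scale=0.3, size=x0.size)
                     for _ in range(max(n_starts - 1, 0))]
    for s in starts:
        try:
            sol = least_squares(resid, s, method="lm",
                                xtol=1e-15, ftol=1e-15, gtol=1e-15,
                                max_nfev=20000)
        except Exception:  # pragma: no cover - lm rarely raises
            continue
        if best is None or sol.cost < best.cost:
            best = sol
    if best is None:
        raise DegenerateCurveError("optimizer failed on every start")

    rss = float(2 * best.cost)
    converged = bool(best.success)
    if model_name == "webb_exponential":
        retrmax, alpha = np.exp(best.x)
        beta, ps = 0.0, retrmax
    else:
        ps, alpha = np.exp(best.x[:2])
        beta = float(best.x[2] ** 2)
        if beta < 1e-12 * alpha:  # numerically zero photoinhibition
            beta = 0.0
        retrmax = platt_retrmax(ps, alpha, beta)
    return RLCFit(model_name=model_name, alpha=float(alpha),
                  rETRmax=float(retrmax), beta=float(beta), rss=rss,
                  converged=converged, ps=float(ps), sample_id=sample_id)


def fit_rlc(curve: RLCCurve, model_name: str = "platt_photoinhibition",
            psii_fraction: float = PSII_FRACTION, n_starts: int = 5,
            seed: int = 12345) -> RLCFit:
    """Fit an RLC: derive per-step rETR from yields, then invert the P–E model."""
    if np.all(curve.E == 0):
        raise DegenerateCurveError("curve has no non-dark steps (all E = 0)")
    return fit_rlc_points(curve.E, curve.retr(psii_fraction),
                          model_name=model_name, n_starts=n_starts,
                          seed=seed, sample_id=curve.sample_id)


def apply_shading_correction(curve: RLCCurve,
                             shading: ShadingFactor | float) -> RLCCurve:
    """Rescale incident excitation by the unshaded fraction (1 − p).

    Phenolic pigment intercepts a proportion p of the fluorometer's
    excitation before it reaches the chloroplast, so the chloroplast-
    level curve has E′ = E·(1 − p) with yields unchanged.  Refitting the
    corrected curve scales rETRmax and Ek by (1 − p) and leaves α
    invariant.
    """
    p = shading.fraction_phenolic if isinstance(shading, ShadingFactor) else float(shading)
    if not 0.0 <= p <= 1.0:
        raise InvalidMeasurementError("shading fraction must lie in [0, 1]")
    if p == 1.0:
        raise DegenerateCurveError(
            "full shading leaves an all-dark curve with no fittable signal")
    return replace(curve, E=curve.E * (1.0 - p))


# ---------------------------------------------------------------------------
# group summaries and I/O
# ---------------------------------------------------------------------------

_PARAMS = ("alpha", "rETRmax", "beta", "Ek")


def summarize_fits(fits: Sequence[RLCFit], group: str = "") -> pd.DataFrame:
    if len(fits) == 0:
        raise InsufficientDataError("empty fit group")
    rows = []
    for p in _PARAMS:
        vals = np.array([getattr(f, p) for f in fits], float)
        n = vals.size
        sd = float(np.std(vals, ddof=1)) if n > 1 else float("nan")
        rows.append({"group": group, "parameter": p, "mean": float(vals.mean()),
                     "sd": sd, "se": sd / np.sqrt(n) if n > 1 else float("nan"),
                     "n": n})
    return pd.DataFrame(rows)


def compare_rlc_groups(fits_a: Sequence[RLCFit],
                       fits_b: Sequence[RLCFit],
                       labels: tuple[str, str] = ("a", "b")) -> pd.DataFrame:
    """Per-parameter mean/SD/SE/n for two fit groups (e.g. DTT vs control).

    Descriptive only; no hypothesis testing.  SE is NaN for n=1.
    """
    return pd.concat([summarize_fits(fits_a, labels[0]),
                      summarize_fits(fits_b, labels[1])], ignore_index=True)


def read_rlc_csv(path) -> list[RLCCurve]:
    """Read RLC curves from a long-layout CSV.

    Columns: sample_id, step_index, E_umol_m2_s, F, Fm_prime; the
    step_index=0 row is the dark measurement carrying F0 (in F) and Fm
    (in Fm_prime).  A ``treatment`` column, if present, is appended to
    the sample id.
    """
    df = pd.read_csv(path)
    curves = []
    keys = ["sample_id"] + (["treatment"] if "treatment" in df.columns else [])
    for key, grp in df.groupby(keys, sort=False):
        grp = grp.sort_values("step_index")
        dark = grp[grp["step_index"] == 0]
        if dark.empty:
            raise InvalidMeasurementError(f"sample {key}: missing dark row")
        light = grp[grp["step_index"] > 0]
        sid = key if isinstance(key, str) else "/".join(map(str, key))
        curves.append(RLCCurve(
            sample_id=sid,
            dark_F0=float(dark["F"].iloc[0]),
            dark_Fm=float(dark["Fm_prime"].iloc[0]),
            E=light["E_umol_m2_s"].to_numpy(float),
            F=light["F"].to_numpy(float),
            Fm_prime=light["Fm_prime"].to_numpy(float)))
    return curves


def fits_to_frame(fits: Iterable[RLCFit]) -> pd.DataFrame:
    """Tabulate fits (one row per sample) for CSV export."""
    return pd.DataFrame([{
        "sample_id": f.sample_id, "model": f.model_name, "alpha": f.alpha,
        "rETRmax": f.rETRmax, "beta": f.beta, "Ek": f.Ek, "rss": f.rss,
        "converged": f.converged} for f in fits])
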