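"""Threshold-gated logistic bloom model for glacier algae in surface ice.

Daily biomass B (ng dry weight·mL⁻¹) follows a forward-Euler day step

    B' = B + f·µB(1 − B/K) − d·B

where f is the fraction of the 24 hourly records that satisfy all three
growth prerequisites — snow-free ice (snow height SH < 2 cm), light
sufficient for photochemistry (shortwave-down SWD > 10 W·m⁻²) and
liquid water present (air temperature TT > 0.5 °C), strict inequalities
— µ and K parameterize net productivity as a logistic function of
biomass, and d is a fixed daily loss (default 10 %/day) for mortality
and export.  Growth and loss are applied simultaneously within the step;
the population persists only where f·µ > d, with a forcing-dependent
equilibrium B* = K(1 − d/(f·µ)) — an *emergent* carrying capacity below
the physiological K.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .exceptions import ForcingError, InvalidMeasurementError

#: Growth-permissive thresholds: (max snow height cm, min SWD W·m⁻², min air T °C).
DEFAULT_THRESHOLDS = (2.0, 10.0, 0.5)


@dataclass(frozen=True)
class BloomParams:
    """Parameters of the threshold-gated logistic bloom model.

    ``mu`` (d⁻¹) and ``K`` (ng DW·mL⁻¹) describe the logistic
    net-productivity curve; ``loss`` is the daily loss fraction;
    ``b0`` the initial inoculum; ``b_min`` an optional refuge floor.
    """

    mu: float
    K: float
    b0: float
    loss: float = 0.10
    thresholds: tuple[float, float, float] = DEFAULT_THRESHOLDS
    b_min: float = 0.0
    hard_gate: bool = False  # if True, zero out net-negative days

    def __post_init__(self) -> None:
        if self.mu <= 0 or self.K <= 0 or self.b0 <= 0:
            raise InvalidMeasurementError("mu, K and b0 must be positive")
        if not 0.0 <= self.loss < 1.0:
            raise InvalidMeasurementError("loss must lie in [0, 1)")


def productive_fraction(sh_cm: np.ndarray, swd_w_m2: np.ndarray,
                        tt_c: np.ndarray,
                        thresholds: tuple[float, float, float] = DEFAULT_THRESHOLDS
                        ) -> float:
    """Fraction of 24 hourly records permissive for growth.

    Strict inequalities throughout: an hour with SH exactly 2 cm, SWD
    exactly 10 W·m⁻² or TT exactly 0.5 °C is non-productive.
    """
    sh = np.asarray(sh_cm, float)
    swd = np.asarray(swd_w_m2, float)
    tt = np.asarray(tt_c, float)
    if not (sh.size == swd.size == tt.size == 24):
        raise ForcingError(f"need exactly 24 hourly records, got {sh.size}")
    sh_max, swd_min, tt_min = thresholds
    ok = (sh < sh_max) & (swd > swd_min) & (tt > tt_min)
    return float(np.count_nonzero(ok)) / 24.0


def logistic_net_growth(B: float, params: BloomParams) -> float:
    """Optimal daily net growth g = µB(1 − B/K), floored at 0 above K."""
    if B < 0:
        raise InvalidMeasurementError("biomass must be non-negative")
    return max(params.mu * B * (1.0 - B / params.K), 0.0)


def step_day(B: float, f: float, params: BloomParams) -> float:
    """One Euler day step B' = B + f·g(B) − loss·B, floored at b_min."""
    g = logistic_net_growth(B, params)
    net = f * g - params.loss * B
    if params.hard_gate and net < 0:
        net = 0.0
    return max(B + net, params.b_min)


def equilibrium_biomass(params: BloomParams, f: float) -> float:
    """Fixed point B* = K(1 − loss/(f·µ)); 0 if the population cannot persist."""
    if f * params.mu <= params.loss:
        return 0.0
    return params.K * (1.0 - params.loss / (f * params.mu))


def run_season(forcing: pd.DataFrame, params: BloomParams) -> pd.DataFrame:
    """Simulate daily biomass over the forcing period.

    ``forcing`` must carry hourly rows with columns ``timestamp_iso``
    (or a DatetimeIndex), ``SH_cm``, ``SWD_W_m2``, ``TT_C`` and cover
    each simulated day completely; days with missing hours abort with
    an error listing the offending dates.  Returns a daily frame with
    productive fraction, growth, loss and end-of-day biomass.
    """
    df = forcing.copy()
    if "timestamp_iso" in df.columns:
        ts = pd.to_datetime(df["timestamp_iso"])
    elif isinstance(df.index, pd.DatetimeIndex):
        ts = df.index.to_series().reset_index(drop=True)
        df = df.reset_index(drop=True)
    else:
        raise ForcingError("forcing needs a timestamp_iso column or datetime index")
    df = df.assign(_date=ts.dt.date.values)
    counts = df.groupby("_date").size()
    bad = counts[counts != 24]
    if len(bad):
        raise ForcingError(
            "incomplete forcing days: "
            + ", ".join(str(d) for d in bad.index.tolist()))
    B = params.b0
    rows = []
    for date, day in df.groupby("_date", sort=True):
        f = productive_fraction(day["SH_cm"].to_numpy(),
                                day["SWD_W_m2"].to_numpy(),
                                day["TT_C"].to_numpy(), params.thresholds)
        growth = f * logistic_net_growth(B, params)
        loss = params.loss * B
        B = step_day(B, f, params)
        rows.append({"date": date, "productive_fraction": f,
                     "growth_ngDW_mL_d": growth, "loss_ngDW_mL_d": loss,
                     "biomass_ngDW_mL": B})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# supporting conversions and fitting
# ---------------------------------------------------------------------------

def cell_biovolume_um3(length_um: float, width_um: float) -> float:
    """Cylinder biovolume π(w/2)²·L of a filamentous cell, µm³."""
    if length_um <= 0 or width_um <= 0:
        raise InvalidMeasurementError("cell dimensions must be positive")
    return float(np.pi * (width_um / 2.0) ** 2 * length_um)


def biovolume_to_dw(biovolume_um3_per_mL: float,
                    conversion_ng_per_um3: float) -> float:
    """Total biovolume (µm³·mL⁻¹) → dry-weight biomass (ng DW·mL⁻¹).

    The conversion factor is sample-specific and must be supplied
    explicitly (no default is scientifically defensible here).
    """
    if conversion_ng_per_um3 is None or conversion_ng_per_um3 <= 0:
        raise InvalidMeasurementError(
            "a positive biovolume→dry-weight conversion factor is required")
    if biovolume_um3_per_mL < 0:
        raise InvalidMeasurementError("biovolume must be non-negative")
    return biovolume_um3_per_mL * conversion_ng_per_um3


def fit_logistic_productivity(biomass: Sequence[float],
                              net_productivity: Sequence[float]
                              ) -> tuple[float, float]:
    """Least-squares estimate of (µ, K) from a productivity table.

    Fits g = µB − (µ/K)B² by linear least squares on the design
    [B, B²]; exact on noiseless logistic data.
    """
    B = np.asarray(biomass, float)
    g = np.asarray(net_productivity, float)
    if B.size < 3:
        raise InvalidMeasurementError("need >= 3 (biomass, productivity) points")
    X = np.column_stack([B, B * B])
    coef, *_ = np.linalg.lstsq(X, g, rcond=None)
    mu = float(coef[0])
    if mu <= 0 or coef[1] >= 0:
        raise InvalidMeasurementError(
            "productivity table is not logistic-shaped (mu<=0 or no saturation)")
    K = float(-mu / coef[1])
    return mu, K


def read_forcing_csv(path) -> pd.DataFrame:
    """Read an hourly forcing CSV (timestamp_iso, SH_cm, SWD_W_m2, TT_C)."""
    df = pd.read_csv(path)
    needed = {"timestamp_iso", "SH_cm", "SWD_W_m2", "TT_C"}
    missing = needed - set(df.columns)
    if missing:
        raise ForcingError(f"forcing CSV missing columns: {sorted(missing)}")
    return df
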