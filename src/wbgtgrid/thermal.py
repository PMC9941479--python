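"""Point-wise thermal formulas for the WBGT heat-stress approximation.

The WBGT combines natural wet-bulb, globe and dry-bulb temperature with
the ISO weights::

    WBGT = 0.7*Tw + 0.2*Tg + 0.1*Ta          (all in deg C)

Globe temperature is recovered from mean radiant temperature (TMRT) by
inverting the forced-convection globe heat balance

    TMRT**4 = Tg**4 + (hcg / (eps * D**0.4)) * (Tg - Ta)      [Kelvin]

with hcg = 1.1e8 * va**0.6, and the natural wet-bulb temperature comes
from Stull's empirical atan fit of air temperature and relative humidity.
Everything here is a pure function operating element-wise on scalars or
numpy arrays; there is no spatial coupling, so the same code serves a
single station record and a global grid.
"""

from __future__ import annotations

import dataclasses
from typing import Literal

import numpy as np

from .constants import DEFAULT_CONSTANTS, KELVIN_OFFSET, ThermalConstants

__all__ = [
    "AirState",
    "WBGTComponents",
    "saturation_vapour_pressure",
    "relative_humidity",
    "mean_convection_coefficient",
    "globe_temperature",
    "wet_bulb_stull",
    "wbgt_combine",
    "wbgt_brimicombe",
    "wbgt_acsm87",
    "wbgt_acsm87_from_state",
]


@dataclasses.dataclass
class AirState:
    """Meteorological state of one or more grid cells / time steps.

    ta, td, tmrt in Kelvin, va (10 m wind speed) in m/s; each field may be
    a scalar or an array, broadcastable against the others.
    """

    ta: np.ndarray
    td: np.ndarray
    va: np.ndarray
    tmrt: np.ndarray

    def __post_init__(self) -> None:
        self.ta, self.td, self.va, self.tmrt = (
            np.asarray(x, dtype=float) for x in (self.ta, self.td, self.va, self.tmrt)
        )
        if np.any(self.ta[np.isfinite(self.ta)] <= 0):
            raise ValueError("air temperature must be positive (Kelvin)")
        if np.any(self.tmrt[np.isfinite(self.tmrt)] <= 0):
            raise ValueError("mean radiant temperature must be positive (Kelvin)")
        if np.any(self.va[np.isfinite(self.va)] < 0):
            raise ValueError("wind speed must be non-negative")


@dataclasses.dataclass
class WBGTComponents:
    """Wet-bulb, globe and combined WBGT (all deg C) plus validity flags."""

    tw: np.ndarray
    tg: np.ndarray
    wbgt: np.ndarray
    method: str
    valid: np.ndarray


def saturation_vapour_pressure(t_kelvin):
    """Saturation vapour pressure over a plane water surface, in hPa.

    Buck's over-water formula; water-phase only (WBGT is a human heat
    index, so ice-phase saturation is deliberately not used). Strictly
    increasing in temperature; ~6.11 hPa at 0 deg C.
    """
    t = np.asarray(t_kelvin, dtype=float) - KELVIN_OFFSET
    return 6.1121 * np.exp(17.502 * t / (240.97 + t))


def relative_humidity(ta_kelvin, td_kelvin):
    """Relative humidity (%) from air and dew-point temperature.

    RH = 100 * svp(Td) / svp(Ta), clamped to (0, 100]. Supersaturated
    input (Td > Ta) clamps to 100; use the returned value together with
    the caller's own flagging if that case must be detected.
    """
    rh = 100.0 * saturation_vapour_pressure(td_kelvin) / saturation_vapour_pressure(ta_kelvin)
    return np.minimum(rh, 100.0)


def mean_convection_coefficient(va, consts: ThermalConstants = DEFAULT_CONSTANTS):
    """Wind-dependent mean convection coefficient hcg = 1.1e8 * va**0.6.

    The sub-linear exponent damps the weighting of high wind speeds on the
    solved globe temperature. Raises on negative wind.
    """
    va = np.asarray(va, dtype=float)
    if np.any(va[np.isfinite(va)] < 0):
        raise ValueError("wind speed must be non-negative")
    return consts.hcg_coeff * va**consts.hcg_exp


def globe_temperature(tmrt, ta, va, consts: ThermalConstants = DEFAULT_CONSTANTS):
    """Globe temperature (K) from mean radiant temperature, air temperature
    and wind speed.

    Solves f(Tg) = Tg**4 + C*Tg - (TMRT**4 + C*Ta) = 0 with
    C = hcg / (eps * D**0.4). f is strictly increasing for Tg > 0, so the
    physical root is unique and lies in the closed interval bounded by Ta
    and TMRT. A safeguarded Newton iteration from the bracket midpoint
    converges quadratically; each cell is independent (no coupled fields,
    no unbounded per-cell loops).

    Exact limits are honoured without iteration: va = 0 gives Tg = TMRT
    (no convective exchange) and TMRT = Ta gives Tg = Ta.
    """
    tmrt, ta, va = np.broadcast_arrays(
        np.asarray(tmrt, dtype=float), np.asarray(ta, dtype=float), np.asarray(va, dtype=float)
    )
    c = mean_convection_coefficient(va, consts) / (
        consts.emissivity * consts.globe_diameter**0.4
    )

    lo = np.minimum(ta, tmrt)
    hi = np.maximum(ta, tmrt)
    tg = 0.5 * (lo + hi)

    rhs = tmrt**4 + c * ta
    tol = 1e-8
    for _ in range(100):
        f = tg**4 + c * tg - rhs
        df = 4.0 * tg**3 + c
        step = f / df
        tg_new = tg - step
        # Newton can only leave the bracket through rounding; clamp back.
        tg_new = np.clip(tg_new, lo, hi)
        tg = tg_new
        with np.errstate(invalid="ignore"):
            if not np.any(np.abs(step) > tol):
                break

    # Exact degenerate cases (also fixes va=0 where C=0 decouples Tg from Ta).
    tg = np.where(c == 0.0, tmrt, tg)
    tg = np.where(tmrt == ta, ta, tg)
    return tg if tg.ndim else float(tg)


def wet_bulb_stull(ta_c, rh, mode: Literal["permissive", "strict"] = "permissive"):
    """Natural wet-bulb temperature (deg C) by Stull's empirical fit.

    Parameters
    ----------
    ta_c : array-like
        Air temperature in deg C.
    rh : array-like
        Relative humidity in percent.
    mode : {"permissive", "strict"}
        The fit is calibrated for Ta in [-20, 50] deg C and RH in
        [5, 99] %. Outside that domain ``permissive`` still evaluates the
        formula and flags the cell invalid (global grids always contain
        polar and arid cells), while ``strict`` returns NaN there.

    Returns
    -------
    (tw, valid) : tuple of arrays
        Wet-bulb temperature and a boolean validity flag.
    """
    ta_c = np.asarray(ta_c, dtype=float)
    rh = np.asarray(rh, dtype=float)
    consts = DEFAULT_CONSTANTS
    t_lo, t_hi = consts.stull_t_range
    rh_lo, rh_hi = consts.stull_rh_range
    with np.errstate(invalid="ignore"):
        valid = (ta_c >= t_lo) & (ta_c <= t_hi) & (rh >= rh_lo) & (rh <= rh_hi)

    with np.errstate(invalid="ignore"):
        tw = (
            ta_c * np.arctan(0.151977 * np.sqrt(rh + 8.313659))
            + np.arctan(ta_c + rh)
            - np.arctan(rh - 1.676331)
            + 0.00391838 * rh**1.5 * np.arctan(0.023101 * rh)
            - 4.686035
        )
    if mode == "strict":
        tw = np.where(valid, tw, np.nan)
    elif mode != "permissive":
        raise ValueError(f"unknown mode {mode!r}")
    if tw.ndim == 0:
        return float(tw), bool(valid)
    return tw, valid


def wbgt_combine(tw_c, tg_c, ta_c, consts: ThermalConstants = DEFAULT_CONSTANTS):
    """ISO combination WBGT = 0.7*Tw + 0.2*Tg + 0.1*Ta (all deg C)."""
    w_tw, w_tg, w_ta = consts.wbgt_weights
    return (
        w_tw * np.asarray(tw_c, dtype=float)
        + w_tg * np.asarray(tg_c, dtype=float)
        + w_ta * np.asarray(ta_c, dtype=float)
    )


def wbgt_brimicombe(
    state: AirState,
    consts: ThermalConstants = DEFAULT_CONSTANTS,
    mode: Literal["permissive", "strict"] = "permissive",
) -> WBGTComponents:
    """Full WBGT from an AirState via the mean-radiant-temperature route.

    Globe temperature is solved from TMRT in Kelvin and converted; the
    wet-bulb comes from Stull on (Ta in deg C, RH derived from dew point).
    In permissive mode RH is clamped to at most 99 % before the Stull
    evaluation (saturated cells sit on the fit's upper boundary), but the
    validity flag reflects the unclamped inputs.
    """
    rh_raw = relative_humidity(state.ta, state.td)
    ta_c = np.asarray(state.ta, dtype=float) - KELVIN_OFFSET

    rh_eval = np.minimum(rh_raw, consts.stull_rh_range[1]) if mode == "permissive" else rh_raw
    tw, _ = wet_bulb_stull(ta_c, rh_eval, mode=mode)
    t_lo, t_hi = consts.stull_t_range
    rh_lo, rh_hi = consts.stull_rh_range
    with np.errstate(invalid="ignore"):
        valid = (ta_c >= t_lo) & (ta_c <= t_hi) & (rh_raw >= rh_lo) & (rh_raw <= rh_hi)

    tg = np.asarray(globe_temperature(state.tmrt, state.ta, state.va, consts)) - KELVIN_OFFSET
    wbgt = wbgt_combine(tw, tg, ta_c, consts)
    return WBGTComponents(
        tw=np.asarray(tw), tg=tg, wbgt=np.asarray(wbgt), method="brimicombe",
        valid=np.asarray(valid),
    )


def wbgt_acsm87(ta_c, e_hpa, consts: ThermalConstants = DEFAULT_CONSTANTS):
    """ACSM87 linear WBGT model: 0.567*Ta + 0.393*e + 3.94.

    Ta in deg C, vapour pressure e in hPa. Kept as the historical
    comparator; known to underestimate heat stress.
    """
    a, b, c = consts.acsm_coeffs
    return a * np.asarray(ta_c, dtype=float) + b * np.asarray(e_hpa, dtype=float) + c


def wbgt_acsm87_from_state(
    state: AirState,
    consts: ThermalConstants = DEFAULT_CONSTANTS,
    e_mode: Literal["dewpoint", "saturation"] = "dewpoint",
) -> WBGTComponents:
    """ACSM87 WBGT from an AirState.

    ``e_mode="dewpoint"`` (default) uses the actual vapour pressure, i.e.
    saturation pressure at the dew point, so the index responds to
    humidity; ``"saturation"`` uses saturation pressure at the air
    temperature (the literal reading of the model's nomenclature).
    """
    if e_mode == "dewpoint":
        e = saturation_vapour_pressure(state.td)
    elif e_mode == "saturation":
        e = saturation_vapour_pressure(state.ta)
    else:
        raise ValueError(f"unknown e_mode {e_mode!r}")
    ta_c = np.asarray(state.ta, dtype=float) - KELVIN_OFFSET
    wbgt = wbgt_acsm87(ta_c, e, consts)
    nan = np.full_like(np.asarray(wbgt, dtype=float), np.nan)
    return WBGTComponents(
        tw=nan, tg=nan.copy(), wbgt=np.asarray(wbgt), method="acsm87",
        valid=np.isfinite(np.asarray(wbgt)),
    )
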