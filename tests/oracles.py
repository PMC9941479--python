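"""Independent scalar oracles, deliberately written with the math module
and bisection so they share no code path with the production (vectorized
Newton / numpy) implementations they check."""

import math

from wbgtgrid.constants import DEFAULT_CONSTANTS


def svp_buck_scalar(t_kelvin: float) -> float:
    t = t_kelvin - 273.15
    return 6.1121 * math.exp(17.502 * t / (240.97 + t))


def globe_temperature_bisect(tmrt: float, ta: float, va: float,
                             consts=DEFAULT_CONSTANTS, iters: int = 200) -> float:
    """Bracketed bisection on f(Tg) = Tg^4 + C*Tg - (TMRT^4 + C*Ta)."""
    c = consts.hcg_coeff * va**consts.hcg_exp / (
        consts.emissivity * consts.globe_diameter**0.4
    )
    rhs = tmrt**4 + c * ta
    lo, hi = min(ta, tmrt), max(ta, tmrt)
    for _ in range(iters):
        mid = 0.5 * (lo + hi)
        if mid**4 + c * mid - rhs > 0.0:
            hi = mid
        else:
            lo = mid
    return 0.5 * (lo + hi)


def stull_scalar(ta_c: float, rh: float) -> float:
    """High-precision scalar evaluation of the Stull atan wet-bulb fit."""
    return (
        ta_c * math.atan(0.151977 * math.sqrt(rh + 8.313659))
        + math.atan(ta_c + rh)
        - math.atan(rh - 1.676331)
        + 0.00391838 * rh**1.5 * math.atan(0.023101 * rh)
        - 4.686035
    )
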