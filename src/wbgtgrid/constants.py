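"""Physical constants and tunable parameters for the WBGT approximation.

All temperatures cross the Kelvin/Celsius boundary with the exact offset
273.15; the globe equation is solved in Kelvin, the Stull wet-bulb and the
ACSM87 linear model are evaluated in Celsius.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

KELVIN_OFFSET = 273.15


@dataclasses.dataclass(frozen=True)
class ThermalConstants:
    """Bundle of every tunable constant in the thermal formulas.

    Attributes
    ----------
    globe_diameter : float
        Standard black-globe diameter D in metres (0.15 m globe).
    emissivity : float
        Emissivity used in the globe radiation balance. Default 0.98
        (clothed human body); 0.95 (the globe instrument itself) is the
        common alternative.
    hcg_coeff, hcg_exp : float
        Mean convection coefficient hcg = hcg_coeff * va**hcg_exp, which
        damps the influence of high wind speeds on globe temperature.
    wbgt_weights : tuple
        ISO weights (wet-bulb, globe, dry-bulb) — 0.7/0.2/0.1.
    acsm_coeffs : tuple
        (air-temperature coefficient, vapour-pressure coefficient,
        intercept) of the ACSM87 linear model, all in °C / hPa units.
    stull_t_range, stull_rh_range : tuple
        Validity domain of the Stull wet-bulb fit: air temperature in
        [-20, 50] °C and relative humidity in [5, 99] %.
    """

    globe_diameter: float = 0.15
    emissivity: float = 0.98
    hcg_coeff: float = 1.1e8
    hcg_exp: float = 0.6
    wbgt_weights: tuple[float, float, float] = (0.7, 0.2, 0.1)
    acsm_coeffs: tuple[float, float, float] = (0.567, 0.393, 3.94)
    stull_t_range: tuple[float, float] = (-20.0, 50.0)
    stull_rh_range: tuple[float, float] = (5.0, 99.0)
    kelvin_offset: float = KELVIN_OFFSET

    def __post_init__(self) -> None:
        if self.globe_diameter <= 0:
            raise ValueError("globe diameter must be positive")
        if not (0.0 < self.emissivity <= 1.0):
            raise ValueError("emissivity must lie in (0, 1]")
        if abs(sum(self.wbgt_weights) - 1.0) > 1e-12:
            raise ValueError("WBGT weights must sum to 1")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")

    @classmethod
    def load(cls, path: str | Path) -> "ThermalConstants":
        raw = json.loads(Path(path).read_text())
        for key in ("wbgt_weights", "acsm_coeffs", "stull_t_range", "stull_rh_range"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)


DEFAULT_CONSTANTS = ThermalConstants()
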