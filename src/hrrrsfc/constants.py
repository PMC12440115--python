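"""Physical constants, scenario bounds and plain-text configuration.

The numeric defaults here are the ones the surface-variable derivations are
defined with: dry-air density at 273 K and 101.325 kPa, the specific heat of
air at constant pressure, the von Karman constant, and the upper/lower limits
applied to fluxes and stability parameters in the bounded scenarios.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, fields
from pathlib import Path
from typing import Mapping

#: AERMET missing-value sentinel (used for w* in stable hours and the
#: vertical potential temperature gradient, which has no HRRR proxy).
MISSING = -9.0

#: Monin-Obukhov length emitted for near-neutral hours (|H| below ``h_eps``);
#: coincides with the bounded-scenario cap on |L|.
NEUTRAL_OBUKHOV = 8888.0

#: Sensible-heat magnitude (W/m^2) below which the hour is treated as neutral.
DEFAULT_H_EPS = 1e-6


@dataclass(frozen=True)
class PhysicalConstants:
    """Constants entering the w*, L and wind-direction formulas.

    Attributes
    ----------
    g : float
        Gravitational acceleration, m/s^2.
    rho_air : float
        Dry-air density at 273 K and 101.325 kPa, kg/m^3.
    cp_air : float
        Specific heat of air at constant pressure, J/(kg K).
    von_karman : float
        von Karman constant, dimensionless.
    pi : float
        Circle constant used in the wind-direction conversion.
    """

    g: float = 9.8
    rho_air: float = 1.293
    cp_air: float = 1004.0
    von_karman: float = 0.4
    pi: float = math.pi

    def __post_init__(self) -> None:
        for f in fields(self):
            if getattr(self, f.name) <= 0:
                raise ValueError(f"constant {f.name!r} must be strictly positive")

    @classmethod
    def from_mapping(cls, cfg: Mapping[str, float]) -> "PhysicalConstants":
        known = {f.name for f in fields(cls)}
        return cls(**{k: float(v) for k, v in cfg.items() if k in known})


@dataclass(frozen=True)
class ScenarioBounds:
    """Upper/lower limits applied in the bounded scenarios (2 and 3).

    Each pair is (lower, upper); ``mixing_height_max`` is a cap only.
    """

    sensible_heat: tuple[float, float] = (-64.0, 800.0)
    latent_heat: tuple[float, float] = (-100.0, 800.0)
    friction_velocity: tuple[float, float] = (0.0, 2.0)
    surface_roughness: tuple[float, float] = (0.0, 2.0)
    mixing_height_max: float = 4000.0
    w_star: tuple[float, float] = (0.0, 2.0)
    obukhov_length: tuple[float, float] = (-8888.0, 8888.0)
    bowen: tuple[float, float] = (-10.0, 10.0)

    def __post_init__(self) -> None:
        for f in fields(self):
            val = getattr(self, f.name)
            if isinstance(val, tuple) and not val[0] < val[1]:
                raise ValueError(f"bounds for {f.name!r} must satisfy lower < upper")
        if self.mixing_height_max <= 0:
            raise ValueError("mixing_height_max must be positive")

    @classmethod
    def from_mapping(cls, cfg: Mapping[str, float]) -> "ScenarioBounds":
        """Build bounds from flat keys like ``sensible_heat_min``/``_max``."""
        defaults = cls()
        kwargs: dict[str, object] = {}
        for f in fields(cls):
            if f.name == "mixing_height_max":
                if f.name in cfg:
                    kwargs[f.name] = float(cfg[f.name])
                continue
            if (f"{f.name}_min" in cfg) or (f"{f.name}_max" in cfg):
                lo, hi = getattr(defaults, f.name)
                kwargs[f.name] = (
                    float(cfg.get(f"{f.name}_min", lo)),
                    float(cfg.get(f"{f.name}_max", hi)),
                )
        return cls(**kwargs)  # type: ignore[arg-type]


DEFAULT_CONSTANTS = PhysicalConstants()
DEFAULT_BOUNDS = ScenarioBounds()


def load_config(path: str | Path) -> dict[str, float | str]:
    """Read a plain-text ``key = value`` configuration file.

    Lines starting with ``#`` and blank lines are ignored. Values are parsed
    as floats when possible, otherwise kept as strings. Recognised keys
    include the :class:`PhysicalConstants` field names, ``<bound>_min`` /
    ``<bound>_max`` pairs, ``mixing_height_max``, ``h_eps``, ``tz_offset``
    and ``max_backtrack``.
    """
    out: dict[str, float | str] = {}
    for raw in Path(path).read_text().splitlines():
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ValueError(f"malformed config line (expected 'key = value'): {raw!r}")
        key, val = (part.strip() for part in line.split("=", 1))
        try:
            out[key] = float(val)
        except ValueError:
            out[key] = val
    return out
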