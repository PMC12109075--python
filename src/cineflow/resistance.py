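"""Poiseuille resistance of alternative venous drainage configurations.

For laminar flow in a straight cylindrical vessel of length l and radius r,
the hydraulic resistance is

    R = 8 * eta * l / (pi * r^4)

with eta the dynamic viscosity of blood (~3.5e-3 Pa*s).  Parallel vessels
add conductances: 1/R_eq = sum_i N_i / R(r_i).  The fourth-power law means
16 vessels of radius r/2 drain exactly like one vessel of radius r — the
arithmetic behind comparing a few large jugular trunks with a network of
small peripheral veins.  All quantities are SI (Pa*s, m, Pa*s/m^3).
"""

from __future__ import annotations

import dataclasses
import math
from typing import Sequence

__all__ = ["VesselConfig", "poiseuille_resistance", "equivalent_resistance"]


@dataclasses.dataclass(frozen=True)
class VesselConfig:
    """A parallel bundle of vessel branches sharing viscosity and length.

    ``branches`` is a sequence of ``(radius_m, count)`` pairs.
    """

    eta: float  # Pa*s
    length: float  # m
    branches: Sequence[tuple[float, int]]

    def __post_init__(self) -> None:
        if not self.eta > 0:
            raise ValueError(f"eta must be > 0, got {self.eta}")
        if not self.length > 0:
            raise ValueError(f"length must be > 0, got {self.length}")
        if not self.branches:
            raise ValueError("at least one branch is required")
        for radius, count in self.branches:
            if not radius > 0:
                raise ValueError(f"radius must be > 0, got {radius}")
            if not (isinstance(count, int) and count > 0):
                raise ValueError(f"count must be a positive integer, got {count}")


def poiseuille_resistance(eta: float, length: float, radius: float) -> float:
    """R = 8 * eta * l / (pi * r^4), in Pa*s/m^3."""
    if not (eta > 0 and length > 0 and radius > 0):
        raise ValueError("eta, length and radius must all be > 0")
    return 8.0 * eta * length / (math.pi * radius ** 4)


def equivalent_resistance(config: VesselConfig) -> float:
    """Parallel combination of all branches: 1/R_eq = sum N_i / R(r_i)."""
    conductance = sum(
        count / poiseuille_resistance(config.eta, config.length, radius)
        for radius, count in config.branches
    )
    return 1.0 / conductance
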