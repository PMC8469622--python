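"""Magnetic material constants.

Defaults are room-temperature magnetite (Fe3O4): saturation magnetization
Ms = 410 kA/m, exchange constant k_ex = 12 pJ/m and cubic magnetocrystalline
anisotropy with K1 = -13.5 kJ/m^3, K2 = -4.4 kJ/m^3 (negative K1: <111> easy,
<100> hard).  The Gilbert damping used for quasi-static loops is 0.1; with
the stochastic thermal field switched on it drops to 0.02.

Internally all quantities are SI: A/m, J/m^3, J/m, H/m.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

MU0 = 4.0e-7 * np.pi  # vacuum permeability (H/m)
K_B = 1.380649e-23  # Boltzmann constant (J/K)

__all__ = ["MU0", "K_B", "MagneticMaterial", "magnetite"]


@dataclass(frozen=True)
class MagneticMaterial:
    """Material constants for the LLG model (SI units).

    Parameters
    ----------
    Ms : saturation magnetization (A/m).
    k_ex : exchange constant (J/m).
    K1, K2 : first/second cubic anisotropy constants (J/m^3).
    alpha : Gilbert damping (dimensionless).
    gamma : gyromagnetic ratio magnitude (m A^-1 s^-1).
    Ku : optional uniaxial anisotropy constant (J/m^3), 0 disables it.
    easy_axis : uniaxial easy axis (unit vector) when Ku != 0.
    """

    Ms: float = 410e3
    k_ex: float = 12e-12
    K1: float = -13.5e3
    K2: float = -4.4e3
    alpha: float = 0.1
    gamma: float = 2.21e5
    Ku: float = 0.0
    easy_axis: tuple[float, float, float] = (0.0, 0.0, 1.0)

    def __post_init__(self):
        if self.Ms <= 0:
            raise ValueError("Ms must be positive")
        if self.alpha <= 0:
            raise ValueError("damping alpha must be positive")

    @property
    def exchange_length(self) -> float:
        """sqrt(2 k_ex / (mu0 Ms^2)) in metres."""
        return float(np.sqrt(2 * self.k_ex / (MU0 * self.Ms**2)))

    def with_(self, **kw) -> "MagneticMaterial":
        return replace(self, **kw)


def magnetite(thermal: bool = False, **overrides) -> MagneticMaterial:
    """Magnetite defaults; ``thermal=True`` selects the low-damping variant."""
    mat = MagneticMaterial(alpha=0.02 if thermal else 0.1)
    return mat.with_(**overrides) if overrides else mat
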