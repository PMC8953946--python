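"""Power-law blood flow in a single tortuous fractal capillary.

Blood is treated as a power-law (Ostwald–de Waele) fluid with index ``n``
(``n = 1`` Newtonian, ``n < 1`` shear-thinning, blood ~ 0.6) and consistency
``m`` (Pa·s^n).  Fully developed laminar flow in a tube of diameter ``lam``
and tortuous length ``L(lam) = L0**DT * lam**(1-DT)`` driven by a pressure
gradient ``G = dp/dL0`` gives the mean velocity

    u = n/(3n+1) * (lam/2) * [G * lam**DT / (4 m L0**(DT-1))]**(1/n),

which recovers the classical Poiseuille mean velocity ``G lam^2 / (32 m)``
for ``n = 1, DT = 1``.  The thermal strength of a capillary is its Peclet
number ``Pe = rho_b C_b lam u / k_b``.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .fractal import tortuous_length

__all__ = [
    "BloodRheology",
    "mean_velocity",
    "capillary_flow_rate",
    "peclet",
    "calibrate_pressure_gradient",
]

#: Blood thermophysical defaults: density (kg/m^3), specific heat
#: (J/kg·°C) and conductivity (W/m·°C) of whole blood.
BLOOD_DENSITY = 1052.0
BLOOD_SPECIFIC_HEAT = 3800.0
BLOOD_CONDUCTIVITY = 0.582


@dataclass(frozen=True)
class BloodRheology:
    """Power-law rheology and thermal properties of blood.

    ``consistency`` has units Pa·s^n (it equals the dynamic viscosity only
    when ``n = 1``); no unit conversion is attempted across ``n``.
    ``pressure_gradient`` is the driving pressure drop per unit straight REV
    length, ``G = dp/dL0`` (Pa/m).
    """

    power_law_index: float = 1.0
    consistency: float = 0.0035
    pressure_gradient: float = 0.0
    density: float = BLOOD_DENSITY
    specific_heat: float = BLOOD_SPECIFIC_HEAT
    conductivity: float = BLOOD_CONDUCTIVITY

    def __post_init__(self) -> None:
        if self.power_law_index <= 0:
            raise ValueError("power-law index must be positive")
        if self.consistency <= 0:
            raise ValueError("consistency must be positive")
        if self.pressure_gradient < 0:
            raise ValueError("pressure gradient must be non-negative")
        if min(self.density, self.specific_heat, self.conductivity) <= 0:
            raise ValueError("blood thermal properties must be positive")

    def with_pressure_gradient(self, G: float) -> "BloodRheology":
        return replace(self, pressure_gradient=G)


def mean_velocity(lam, rheology: BloodRheology, L0: float, DT: float):
    """Mean blood velocity (m/s) in a tortuous capillary of diameter ``lam``.

    Generalized power-law Hagen–Poiseuille flow over the tortuous length
    ``L(lam)``; scales as ``lam**(1 + DT/n)``, so wide capillaries dominate
    perfusion, the more strongly the more shear-thinning the blood.
    """
    lam = np.asarray(lam, dtype=float)
    if np.any(lam <= 0):
        raise ValueError("capillary diameter must be positive")
    n = rheology.power_law_index
    m = rheology.consistency
    G = rheology.pressure_gradient
    length = tortuous_length(lam, L0, DT)
    # wall shear stress scale: total pressure drop G*L0 over tortuous length
    stress = G * L0 * (lam / 2.0) / (2.0 * length)
    out = n / (3.0 * n + 1.0) * (lam / 2.0) * (stress / m) ** (1.0 / n)
    return out if out.ndim else float(out)


def capillary_flow_rate(lam, rheology: BloodRheology, L0: float, DT: float):
    """Volumetric flow rate ``q = u * pi lam^2 / 4`` (m^3/s)."""
    lam = np.asarray(lam, dtype=float)
    u = mean_velocity(lam, rheology, L0, DT)
    out = u * np.pi * lam**2 / 4.0
    return out if np.ndim(out) else float(out)


def peclet(lam, u, rheology: BloodRheology):
    """Capillary Peclet number ``Pe = rho_b C_b lam u / k_b``."""
    lam = np.asarray(lam, dtype=float)
    u = np.asarray(u, dtype=float)
    if np.any(lam < 0) or np.any(u < 0):
        raise ValueError("diameter and velocity must be non-negative")
    out = rheology.density * rheology.specific_heat * lam * u / rheology.conductivity
    return out if out.ndim else float(out)


def calibrate_pressure_gradient(
    target_pe: float,
    lam_ref: float,
    rheology: BloodRheology,
    L0: float,
    DT: float,
) -> float:
    """Pressure gradient ``G`` giving ``Pe(lam_ref) == target_pe``.

    Inverts the flow law in closed form (``u`` is proportional to
    ``G**(1/n)``).  Used to pin the one perfusion number the model needs when
    no pressure data are given: e.g. Pe = 16.3 at the largest pore under the
    Newtonian validation settings yields G ≈ 2.13e3 Pa/m.
    """
    if target_pe < 0:
        raise ValueError("target Peclet number must be non-negative")
    if target_pe == 0.0:
        return 0.0
    n = rheology.power_law_index
    u_target = (
        target_pe
        * rheology.conductivity
        / (rheology.density * rheology.specific_heat * lam_ref)
    )
    length = tortuous_length(lam_ref, L0, DT)
    # invert u = n/(3n+1) * (lam/2) * (G*L0*lam / (4 m L(lam)))**(1/n)
    bracket = (u_target * (3.0 * n + 1.0) / (n * lam_ref / 2.0)) ** n
    G = bracket * 4.0 * rheology.consistency * length / (L0 * lam_ref)
    return float(G)
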