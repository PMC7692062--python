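"""Thermophysical property laws for water, moist plant tissue and its vapor.

This module collects the pure property functions that the moving-boundary
drying solver evaluates at every right-hand-side call: saturated vapor
pressure and latent heat of water, the effective-moisture-diffusivity laws
(Arrhenius in temperature, optionally exponential in the water volume
fraction), the Henderson desorption isotherm linking surface moisture to
equilibrium relative humidity, and two-component (water + dry solid) mixing
rules for the product density, heat capacity and thermal conductivity.

All temperatures are kelvin, pressures Pa, diffusivities m²/s.  Moisture is
carried either as dry-basis content ``X`` [kg water / kg dry solid] or as
water volume fraction ``phi`` [-]; :func:`phi_from_moisture` and
:func:`moisture_from_phi` convert between the two.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Union

import numpy as np

__all__ = [
    "RG",
    "MW_WATER",
    "ArrheniusLaw",
    "PhiDependentLaw",
    "DiffusivityLaw",
    "HendersonIsotherm",
    "ProductComposition",
    "saturation_pressure",
    "latent_heat",
    "effective_diffusivity",
    "equilibrium_rh",
    "moisture_from_rh",
    "product_properties",
    "volumetric_heat_capacity",
    "phi_from_moisture",
    "moisture_from_phi",
]

#: Universal gas constant [J/(mol K)].
RG = 8.314462618
#: Molar mass of water [kg/mol].
MW_WATER = 0.018015

_T_MIN = 250.0
_T_MAX = 400.0


def _check_temperature(T) -> None:
    T = np.asarray(T, dtype=float)
    if np.any(T <= _T_MIN) or np.any(T >= _T_MAX):
        raise ValueError(
            f"temperature {T} K outside the validity range "
            f"({_T_MIN} K, {_T_MAX} K) of the water property fits"
        )


def saturation_pressure(T):
    """Saturated vapor pressure of water [Pa] at temperature ``T`` [K].

    Buck correlation over liquid water; matches steam tables to better than
    1% between 0 and 100 °C.  Raises ``ValueError`` outside (250, 400) K.
    """
    _check_temperature(T)
    t = np.asarray(T, dtype=float) - 273.15
    p = 611.21 * np.exp((18.678 - t / 234.5) * (t / (257.14 + t)))
    return p if p.ndim else float(p)


def latent_heat(T):
    """Specific enthalpy of water evaporation [J/kg] at ``T`` [K].

    Linear steam-table fit lambda[kJ/kg] = 2501 - 2.361 (T - 273.15 K),
    accurate to <1% over 0-60 °C.
    """
    _check_temperature(T)
    lam = (2501.0 - 2.361 * (np.asarray(T, dtype=float) - 273.15)) * 1.0e3
    return lam if lam.ndim else float(lam)


@dataclass(frozen=True)
class ArrheniusLaw:
    """Temperature-activated effective diffusivity D(T) = D0 exp((E/Rg)/T).

    ``E_over_Rg`` is the activation temperature E/Rg [K].  The exponent
    convention is ``(E/Rg)/T`` (not ``-(E/Rg)/T``): with the calibrated
    constants D0 = 4.00012e-5 m²/s and E/Rg = -3872.63 K this evaluates to
    1.703e-10 m²/s at 40 °C and 2.50e-10 m²/s at 50 °C, i.e. a negative
    activation temperature yields the physically expected increase with T.
    """

    D0: float
    E_over_Rg: float

    def __post_init__(self):
        if self.D0 <= 0:
            raise ValueError("pre-exponential diffusivity D0 must be > 0")

    def __call__(self, T, phi=None):
        return self.D0 * np.exp(self.E_over_Rg / np.asarray(T, dtype=float))


@dataclass(frozen=True)
class PhiDependentLaw:
    """Moisture-dependent diffusivity D(phi,T) = D_phi0(T) exp(-beta s(phi)).

    ``s(phi) = (phi0 - phi)/(phi0 - phi_inf)`` is the rescaled drying
    progress, clipped to [0, 1]: the law interpolates between ``D_phi0`` at
    the initial water volume fraction and ``D_phi0 exp(-beta)`` at the final
    one.  ``D_phi0`` may be a constant [m²/s] or itself an
    :class:`ArrheniusLaw`.  ``beta = 0`` reduces to ``D_phi0``.
    """

    D_phi0: Union[float, ArrheniusLaw]
    beta: float
    phi0: float
    phi_inf: float = 0.0

    def __post_init__(self):
        if self.beta < 0:
            raise ValueError("beta must be >= 0")
        if not (0.0 <= self.phi_inf < self.phi0 <= 1.0):
            raise ValueError("need 0 <= phi_inf < phi0 <= 1")

    def _d0(self, T):
        if isinstance(self.D_phi0, ArrheniusLaw):
            return self.D_phi0(T)
        return self.D_phi0

    def __call__(self, T, phi=None):
        if phi is None:
            phi = self.phi0
        s = (self.phi0 - np.asarray(phi, dtype=float)) / (self.phi0 - self.phi_inf)
        return self._d0(T) * np.exp(-self.beta * np.clip(s, 0.0, 1.0))


DiffusivityLaw = Union[ArrheniusLaw, PhiDependentLaw]


def effective_diffusivity(T, phi, law: DiffusivityLaw):
    """Effective water diffusivity [m²/s] at temperature ``T`` and water
    volume fraction ``phi`` under the given law."""
    return law(T, phi)


@dataclass(frozen=True)
class HendersonIsotherm:
    """Henderson desorption isotherm  RH = 1 - exp(-a T X^b).

    ``X`` is dry-basis moisture [kg/kg], ``T`` kelvin.  ``a`` has units
    1/(K (kg/kg)^b); ``b`` is dimensionless.  The default constants packaged
    with the configs are synthetic (chosen to reproduce typical fruit
    desorption magnitudes), not a published fit, and are config-overridable.
    """

    a: float = 0.033
    b: float = 1.29

    def __post_init__(self):
        if self.a <= 0 or self.b <= 0:
            raise ValueError("Henderson parameters a, b must be > 0")

    def rh(self, X, T):
        """Equilibrium relative humidity [-] for moisture ``X`` at ``T`` [K]."""
        X = np.asarray(X, dtype=float)
        if np.any(X < 0):
            raise ValueError("dry-basis moisture must be >= 0")
        out = 1.0 - np.exp(-self.a * np.asarray(T, dtype=float) * X**self.b)
        return out if out.ndim else float(out)

    def moisture(self, rh, T):
        """Inverse isotherm: dry-basis moisture for a given RH in [0, 1)."""
        rh = np.asarray(rh, dtype=float)
        if np.any(rh < 0) or np.any(rh >= 1.0):
            raise ValueError("relative humidity must lie in [0, 1)")
        X = (-np.log1p(-rh) / (self.a * np.asarray(T, dtype=float))) ** (1.0 / self.b)
        return X if X.ndim else float(X)


def equilibrium_rh(X_b, T, iso: HendersonIsotherm):
    """Equilibrium RH at the sample surface for local moisture ``X_b`` [kg/kg]."""
    return iso.rh(X_b, T)


def moisture_from_rh(rh, T, iso: HendersonIsotherm):
    """Dry-basis moisture in equilibrium with ``rh`` at ``T`` (inverse isotherm)."""
    return iso.moisture(rh, T)


@dataclass(frozen=True)
class ProductComposition:
    """Two-component (water + generic dry solid) product composition.

    Defaults are pure-water constants plus a generic plant dry solid
    (rho_s = 1500 kg/m³, Cp_s = 1600 J/(kg K), k_s = 0.21 W/(m K)); at
    phi = 1 the mixing rules recover pure-water properties exactly.
    """

    rho_w: float = 1000.0
    rho_s: float = 1500.0
    Cp_w: float = 4186.0
    Cp_s: float = 1600.0
    k_w: float = 0.63
    k_s: float = 0.21

    def __post_init__(self):
        for name in ("rho_w", "rho_s", "Cp_w", "Cp_s", "k_w", "k_s"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")


def product_properties(phi, comp: ProductComposition):
    """Density, specific heat and thermal conductivity of the moist product.

    Volume-additive density, mass-fraction-weighted heat capacity and
    volume-fraction-weighted (parallel) conductivity:

    ``rho_p = phi rho_w + (1-phi) rho_s``
    ``Cp_p  = x_w Cp_w + (1-x_w) Cp_s``  with  ``x_w = phi rho_w / rho_p``
    ``k_p   = phi k_w + (1-phi) k_s``

    Returns ``(rho_p [kg/m³], Cp_p [J/(kg K)], k_p [W/(m K)])``.
    """
    phi = np.asarray(phi, dtype=float)
    if np.any(phi < 0) or np.any(phi > 1):
        raise ValueError("water volume fraction must lie in [0, 1]")
    rho_p = phi * comp.rho_w + (1.0 - phi) * comp.rho_s
    x_w = phi * comp.rho_w / rho_p
    cp_p = x_w * comp.Cp_w + (1.0 - x_w) * comp.Cp_s
    k_p = phi * comp.k_w + (1.0 - phi) * comp.k_s
    if phi.ndim:
        return rho_p, cp_p, k_p
    return float(rho_p), float(cp_p), float(k_p)


def volumetric_heat_capacity(phi, comp: ProductComposition):
    """rho_p * Cp_p [J/(m³ K)] — the thermal inertia entering the heat equation.

    Mass-fraction weighting of Cp makes this simply additive in volume:
    ``rho_p Cp_p = phi rho_w Cp_w + (1-phi) rho_s Cp_s``.
    """
    phi = np.asarray(phi, dtype=float)
    out = phi * comp.rho_w * comp.Cp_w + (1.0 - phi) * comp.rho_s * comp.Cp_s
    return out if out.ndim else float(out)


def phi_from_moisture(X, comp: ProductComposition):
    """Water volume fraction from dry-basis moisture ``X`` [kg/kg].

    phi = (X/rho_w) / (X/rho_w + 1/rho_s).
    """
    X = np.asarray(X, dtype=float)
    if np.any(X < 0):
        raise ValueError("dry-basis moisture must be >= 0")
    phi = (X / comp.rho_w) / (X / comp.rho_w + 1.0 / comp.rho_s)
    return phi if phi.ndim else float(phi)


def moisture_from_phi(phi, comp: ProductComposition):
    """Dry-basis moisture [kg/kg] from water volume fraction (inverse of
    :func:`phi_from_moisture`)."""
    phi = np.asarray(phi, dtype=float)
    if np.any(phi < 0) or np.any(phi >= 1):
        raise ValueError("water volume fraction must lie in [0, 1)")
    X = comp.rho_w * phi / (comp.rho_s * (1.0 - phi))
    return X if X.ndim else float(X)
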