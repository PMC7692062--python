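"""Forced-convection heat and mass transfer coefficients for a sphere.

Film-temperature evaluation of the Ranz-Marshall correlations

    Sh = 2 + 0.6 Re^(1/2) Sc^(1/3),    Nu = 2 + 0.6 Re^(1/2) Pr^(1/3)

with dry-air properties from standard fits (Sutherland viscosity, power-law
conductivity, Marrero-Mason-type vapor diffusivity).  The resulting
coefficients h_T = Nu k_a/d and h_m = Sh D_va/d inherit the d^(-1/2)
dependence on sample diameter in the forced regime and the pure-diffusion
limit Sh = Nu = 2 at zero air speed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "AirState",
    "TransferCoefficients",
    "film_temperature",
    "air_state",
    "transfer_coefficients",
]

_P_ATM = 101325.0  # Pa
_R_AIR = 287.05  # J/(kg K)
_CP_AIR = 1006.0  # J/(kg K), nearly constant over 250-400 K


@dataclass(frozen=True)
class AirState:
    """Dry-air transport properties evaluated at a single temperature."""

    T: float  # K
    nu: float  # kinematic viscosity [m²/s]
    k_a: float  # thermal conductivity [W/(m K)]
    D_va: float  # water vapor in air diffusivity [m²/s]
    Pr: float  # Prandtl number [-]
    Sc: float  # Schmidt number [-]


@dataclass(frozen=True)
class TransferCoefficients:
    h_m: float  # mass transfer coefficient [m/s]
    h_T: float  # heat transfer coefficient [W/(m² K)]
    Re: float
    Sh: float
    Nu: float


def film_temperature(T_b: float, T_inf: float) -> float:
    """Average film temperature (T_b + T_inf)/2 [K]."""
    if T_b <= 0 or T_inf <= 0:
        raise ValueError("temperatures must be positive (kelvin)")
    return 0.5 * (T_b + T_inf)


def air_state(T: float) -> AirState:
    """Dry-air properties at ``T`` [K] from smooth standard fits.

    Sutherland viscosity, ideal-gas density at 1 atm, k_a power-law fit
    anchored at 300 K, and D_va = 2.26e-5 (T/273.15)^1.81 m²/s.  Valid
    (and enforced) for 250 K < T < 400 K.
    """
    if not (250.0 < T < 400.0):
        raise ValueError(f"air temperature {T} K outside (250, 400) K")
    mu = 1.458e-6 * T**1.5 / (T + 110.4)  # Pa s
    rho = _P_ATM / (_R_AIR * T)
    nu = mu / rho
    k_a = 0.02624 * (T / 300.0) ** 0.8646
    D_va = 2.26e-5 * (T / 273.15) ** 1.81
    Pr = mu * _CP_AIR / k_a
    Sc = nu / D_va
    return AirState(T=T, nu=nu, k_a=k_a, D_va=D_va, Pr=Pr, Sc=Sc)


def transfer_coefficients(
    d: float,
    U_inf: float,
    T_b: float,
    T_inf: float,
    coeff: float = 0.6,
    exp_re: float = 0.5,
    exp_pr: float = 1.0 / 3.0,
) -> TransferCoefficients:
    """Heat and mass transfer coefficients for a sphere of diameter ``d`` [m]
    in an air stream of speed ``U_inf`` [m/s].

    Air properties are evaluated at the film temperature (T_b + T_inf)/2.
    The correlation coefficient and exponents default to Ranz-Marshall and
    are exposed for sensitivity studies.
    """
    if d <= 0:
        raise ValueError("diameter must be > 0")
    if U_inf < 0:
        raise ValueError("air speed must be >= 0")
    air = air_state(film_temperature(T_b, T_inf))
    Re = U_inf * d / air.nu
    Sh = 2.0 + coeff * Re**exp_re * air.Sc**exp_pr
    Nu = 2.0 + coeff * Re**exp_re * air.Pr**exp_pr
    return TransferCoefficients(
        h_m=Sh * air.D_va / d,
        h_T=Nu * air.k_a / d,
        Re=Re,
        Sh=Sh,
        Nu=Nu,
    )
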