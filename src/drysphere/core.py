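"""Moving-boundary solver for coupled water and heat transport in a
shrinking sphere.

Model
-----
Water volume fraction phi(r,t) and temperature T(r,t) obey advection-
diffusion equations on 0 < r < R(t), where the advection velocity is the
pointwise shrinkage velocity

    v_s(r) = alpha0 * Deff(T) * dphi/dr,

proportional (and opposite in sign) to the diffusive volumetric water flux;
alpha0 = 1 is ideal shrinkage (volume loss equals the volume of evaporated
water), alpha0 = 0 a rigid solid.  The boundary moves with the material,
dR/dt = v_s(R).  At the surface an evaporative (Robin) condition balances
internal diffusion against convective vapor transfer driven by the
vapor-concentration difference between the surface (at T_b, with RH from
the desorption isotherm) and the chamber air; the heat condition balances
conduction against convective heating minus the latent heat of the
evaporated water.

Numerics
--------
Front-fixing (Landau) transform sigma = r/R(t) onto the fixed reference
grid, cell-centered finite volumes geometrically refined toward sigma = 1,
and stiff BDF time integration (scipy ``solve_ivp``) with an analytically
sparse Jacobian.  The integrated variables are u_i = (R/R0)^3 phi_i and
(for the ``full`` variant) w_i = (R/R0)^3 rho_p Cp_p T_i / (rho_w Cp_w),
plus R/R0 and the cumulative evaporated volume.  In these variables total
water is a *linear* invariant of the semi-discrete system, so the water
balance holds to integrator roundoff and the drying rate seen by the
trajectory is exactly the surface evaporation flux.

Three variants are available: ``full`` (water + temperature PDEs),
``lumped`` (water PDE + single energy balance for a spatially uniform
temperature, valid when the thermal diffusivity far exceeds Deff), and
``isothermal`` (T = T_inf(t) everywhere).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import brentq
from scipy.sparse import lil_matrix

from . import thermophysical as tp
from .grid import RadialGrid
from .observables import Trajectory
from .schedule import AmbientConditions, CycleProgram, ambient_at

__all__ = [
    "MaterialParams",
    "SolverSettings",
    "DryingState",
    "SimulationError",
    "shrinkage_velocity",
    "boundary_mass_flux",
    "boundary_heat_flux",
    "Simulator",
    "simulate",
]

_VARIANTS = ("isothermal", "full", "lumped")


class SimulationError(RuntimeError):
    """Solver failure carrying a diagnostic dump of the last state."""

    def __init__(self, message: str, state: Optional[dict] = None):
        super().__init__(message)
        self.state = state or {}


@dataclass(frozen=True)
class MaterialParams:
    """Sample material, geometry and initial state.

    ``X0`` is the initial dry-basis moisture [kg/kg], ``d0`` the initial
    diameter [m], ``T0`` the initial uniform temperature [K].  The initial
    water volume fraction phi0 follows from X0 and the composition.
    """

    X0: float
    d0: float
    T0: float = 288.15
    alpha0: float = 1.0
    composition: tp.ProductComposition = field(default_factory=tp.ProductComposition)
    isotherm: tp.HendersonIsotherm = field(default_factory=tp.HendersonIsotherm)
    diffusivity: tp.DiffusivityLaw = field(
        default_factory=lambda: tp.ArrheniusLaw(D0=4.00012e-5, E_over_Rg=-3872.63)
    )

    def __post_init__(self):
        if self.X0 <= 0 or self.d0 <= 0:
            raise ValueError("X0 and d0 must be > 0")
        if self.alpha0 < 0:
            raise ValueError("alpha0 must be >= 0")

    @property
    def phi0(self) -> float:
        return tp.phi_from_moisture(self.X0, self.composition)

    @property
    def R0(self) -> float:
        return 0.5 * self.d0


@dataclass(frozen=True)
class SolverSettings:
    """Discretization and integrator controls.

    Defaults: 200 cells refined toward the boundary (stretch 0.05 = ratio of
    boundary to center cell width), BDF with rtol 1e-4 / atol 1e-7, outputs
    every 0.25 h refined to 0.05 h within +-0.5 h of every stage switch.
    ``hm_override``/``hT_override`` replace the sphere correlations with
    fixed coefficients (used e.g. for analytic-oracle comparisons).
    """

    variant: str = "full"
    n_nodes: int = 200
    grid_stretch: float = 0.05
    rtol: float = 1e-4
    atol: float = 1e-7
    t_end_h: Optional[float] = None
    output_dt_h: float = 0.25
    switch_output_dt_h: float = 0.05
    r_floor_frac: float = 1e-2
    phi_floor: float = 1e-6
    hm_override: Optional[float] = None
    hT_override: Optional[float] = None

    def __post_init__(self):
        if self.variant not in _VARIANTS:
            raise ValueError(f"variant must be one of {_VARIANTS}")
        if self.n_nodes < 16:
            raise ValueError("n_nodes must be >= 16")
        if self.rtol <= 0 or self.atol <= 0:
            raise ValueError("integrator tolerances must be > 0")


@dataclass
class DryingState:
    """Instantaneous fields on the reference grid."""

    phi: np.ndarray
    T: np.ndarray  # per-cell temperatures (uniform for lumped/isothermal)
    R: float
    grid: RadialGrid


def shrinkage_velocity(phi, deff, sigma, R: float, alpha0: float) -> np.ndarray:
    """Pointwise radial shrinkage velocity v_s = alpha0 Deff dphi/dr [m/s]
    evaluated at the nodes ``sigma`` (central differences, one-sided ends).

    Identically zero for a uniform profile or for a rigid solid
    (alpha0 = 0); negative wherever moisture decreases outward.  For the
    physically even profiles of the sphere it vanishes at the center by
    symmetry.
    """
    phi = np.asarray(phi, dtype=float)
    sigma = np.asarray(sigma, dtype=float)
    deff = np.broadcast_to(np.asarray(deff, dtype=float), phi.shape)
    if alpha0 == 0.0:
        return np.zeros_like(phi)
    grad = np.gradient(phi, sigma) / R
    return alpha0 * deff * grad


def boundary_mass_flux(
    phi_b: float,
    T_b: float,
    ambient: AmbientConditions,
    h_m: float,
    isotherm: tp.HendersonIsotherm,
    comp: tp.ProductComposition,
    phi_floor: float = 1e-6,
) -> float:
    """Outward evaporative water flux [m/s, water-volume basis] at the surface.

    F = (h_m Mw / rho_w) [ pv(T_b) RH_b / (Rg T_b) - pv(T_inf) RH_inf / (Rg T_inf) ]

    with RH_b from the desorption isotherm at the surface moisture.  Positive
    means drying; zero at vapor-pressure equilibrium; negative values model
    condensation (rehydration) in cold-humid stages.
    """
    phi_eff = 0.5 * (phi_b + math.sqrt(phi_b * phi_b + 4.0 * phi_floor**2))
    phi_eff = min(phi_eff, 0.9999)
    X_b = tp.moisture_from_phi(phi_eff, comp)
    rh_b = isotherm.rh(X_b, T_b)
    c_b = tp.saturation_pressure(T_b) * rh_b / (tp.RG * T_b)
    c_inf = tp.saturation_pressure(ambient.T_inf) * ambient.RH_inf / (tp.RG * ambient.T_inf)
    return h_m * tp.MW_WATER / comp.rho_w * (c_b - c_inf)


def boundary_heat_flux(
    T_b: float,
    ambient: AmbientConditions,
    h_T: float,
    mass_flux: float,
    comp: tp.ProductComposition,
) -> float:
    """Outward conductive heat flux -k_p dT/dr|_R [W/m²] demanded at the surface.

    q = h_T (T_b - T_inf) + lambda_v(T_b) rho_w F: Newton heating/cooling plus
    the latent heat carried away by the evaporated water (which cools the
    surface whenever the mass flux is outward).
    """
    return h_T * (T_b - ambient.T_inf) + tp.latent_heat(T_b) * comp.rho_w * mass_flux


def _scalar_diffusivity(law: tp.DiffusivityLaw):
    """Plain-math scalar evaluator of a diffusivity law for the inner loop."""
    if isinstance(law, tp.ArrheniusLaw):
        D0, ERg = law.D0, law.E_over_Rg
        return lambda T, phi: D0 * math.exp(ERg / T)
    if isinstance(law.D_phi0, tp.ArrheniusLaw):
        D0b, ERgb = law.D_phi0.D0, law.D_phi0.E_over_Rg
        base = lambda T: D0b * math.exp(ERgb / T)
    else:
        val = float(law.D_phi0)
        base = lambda T: val
    beta, phi0, phi_inf = law.beta, law.phi0, law.phi_inf

    def evaluate(T, phi):
        s = min(max((phi0 - phi) / (phi0 - phi_inf), 0.0), 1.0)
        return base(T) * math.exp(-beta * s)

    return evaluate


class Simulator:
    """Method-of-lines integrator for one material/program/settings triple."""

    def __init__(self, params: MaterialParams, program: CycleProgram,
                 settings: SolverSettings = SolverSettings()):
        self.params = params
        self.program = program
        self.settings = settings
        self.grid = RadialGrid(settings.n_nodes, settings.grid_stretch)
        g = self.grid
        self._lam = g.face_lambda
        self._dsig = g.center_spacing
        self._sf = g.interior_faces
        self._bw = g.boundary_gradient_weights()  # (c1, c2, cb) at sigma = 1
        self._eref = params.composition.rho_w * params.composition.Cp_w
        self._D_s = _scalar_diffusivity(params.diffusivity)
        # warm start for the boundary closure
        self._bcache = [params.phi0, params.T0]
        n = settings.n_nodes
        self.n = n
        if settings.variant == "full":
            self._iT = slice(n, 2 * n)
            self._iR, self._iQ = 2 * n, 2 * n + 1
            self.n_state = 2 * n + 2
        elif settings.variant == "lumped":
            self._iTb = n
            self._iR, self._iQ = n + 1, n + 2
            self.n_state = n + 3
        else:
            self._iR, self._iQ = n, n + 1
            self.n_state = n + 2

    # -- helpers ---------------------------------------------------------

    def _phi_eff(self, phi):
        eps = self.settings.phi_floor
        return np.minimum(0.5 * (phi + np.sqrt(phi * phi + 4.0 * eps**2)), 0.9999)

    # -- boundary closure ------------------------------------------------
    #
    # The Robin conditions are enforced pointwise at sigma = 1 with a small
    # Newton solve per right-hand-side call.  These helpers use plain scalar
    # math (no numpy/array dispatch) because they are the innermost loop of
    # the integration; they mirror boundary_mass_flux / boundary_heat_flux.

    def _phi_eff_s(self, phi_b: float) -> float:
        eps = self.settings.phi_floor
        return min(0.5 * (phi_b + math.sqrt(phi_b * phi_b + 4.0 * eps * eps)), 0.9999)

    def _pv_s(self, T: float) -> float:
        t = T - 273.15
        return 611.21 * math.exp((18.678 - t / 234.5) * (t / (257.14 + t)))

    def _hm_hT_s(self, R: float, T_b: float, amb):
        s = self.settings
        if s.hm_override is not None and s.hT_override is not None:
            return s.hm_override, s.hT_override
        T = 0.5 * (T_b + amb.T_inf)
        mu = 1.458e-6 * T**1.5 / (T + 110.4)
        nu = mu * (287.05 * T) / 101325.0
        k_a = 0.02624 * (T / 300.0) ** 0.8646
        D_va = 2.26e-5 * (T / 273.15) ** 1.81
        d = 2.0 * R
        sq = math.sqrt(amb.U_inf * d / nu)
        h_m = (2.0 + 0.6 * sq * (nu / D_va) ** (1.0 / 3.0)) * D_va / d
        h_T = (2.0 + 0.6 * sq * (mu * 1006.0 / k_a) ** (1.0 / 3.0)) * k_a / d
        if s.hm_override is not None:
            h_m = s.hm_override
        if s.hT_override is not None:
            h_T = s.hT_override
        return h_m, h_T

    def _F_s(self, phi_b: float, T_b: float, c_inf: float, h_m: float) -> float:
        comp = self.params.composition
        iso = self.params.isotherm
        pe = self._phi_eff_s(phi_b)
        X_b = comp.rho_w * pe / (comp.rho_s * (1.0 - pe))
        rh_b = 1.0 - math.exp(-iso.a * T_b * X_b**iso.b)
        c_b = self._pv_s(T_b) * rh_b / (tp.RG * T_b)
        return h_m * tp.MW_WATER / comp.rho_w * (c_b - c_inf)

    def _mass_residual(self, phi_b, T_b, phi_in, R, c_inf, h_m):
        """(Deff/R) dphi/dsigma|_1 + F(phi_b, T_b) — zero enforces the Robin BC."""
        c1, c2, cb = self._bw
        grad = c1 * phi_in[0] + c2 * phi_in[1] + cb * phi_b
        D = self._D_s(T_b, self._phi_eff_s(phi_b))
        F = self._F_s(phi_b, T_b, c_inf, h_m)
        return D / R * grad + F, F

    def _solve_phi_b(self, phi_in, T_b, R, c_inf, h_m):
        """Scalar Newton (bisection fallback) for the surface water fraction."""
        x = min(max(self._bcache[0], 1e-8), 0.999)
        for _ in range(30):
            f, _ = self._mass_residual(x, T_b, phi_in, R, c_inf, h_m)
            h = 1e-7 + 1e-6 * abs(x)
            f2, _ = self._mass_residual(x + h, T_b, phi_in, R, c_inf, h_m)
            dfdx = (f2 - f) / h
            if dfdx == 0.0:
                break
            step = -f / dfdx
            x_new = min(max(x + step, 0.0), 0.9999)
            if abs(x_new - x) < 1e-12 + 1e-9 * abs(x):
                x = x_new
                break
            x = x_new
        else:
            x = brentq(
                lambda z: self._mass_residual(z, T_b, phi_in, R, c_inf, h_m)[0],
                0.0, 0.9999, xtol=1e-13,
            )
        f, F = self._mass_residual(x, T_b, phi_in, R, c_inf, h_m)
        return x, F

    def _heat_residual(self, phi_b, T_b, T_in, R, amb, h_T, F):
        comp = self.params.composition
        c1, c2, cb = self._bw
        gradT = c1 * T_in[0] + c2 * T_in[1] + cb * T_b
        pe = self._phi_eff_s(phi_b)
        k_p = pe * comp.k_w + (1.0 - pe) * comp.k_s
        lam_v = (2501.0 - 2.361 * (T_b - 273.15)) * 1.0e3
        q_c = h_T * (T_b - amb.T_inf) + lam_v * comp.rho_w * F
        return k_p / R * gradT + q_c, q_c

    def _solve_boundary_full(self, phi_in, T_in, R, amb):
        """Coupled 2x2 Newton for (phi_b, T_b) under the Robin conditions."""
        pb, Tb = self._bcache
        pb = min(max(pb, 1e-8), 0.999)
        Tb = min(max(Tb, 250.1), 399.0)
        c_inf = self._pv_s(amb.T_inf) * amb.RH_inf / (tp.RG * amb.T_inf)

        def residuals(pb_, Tb_):
            h_m, h_T = self._hm_hT_s(R, Tb_, amb)
            f1, F = self._mass_residual(pb_, Tb_, phi_in, R, c_inf, h_m)
            f2, q_c = self._heat_residual(pb_, Tb_, T_in, R, amb, h_T, F)
            return f1, f2, F, q_c, h_m, h_T

        ok = False
        for _ in range(40):
            f1, f2, F, q_c, h_m, h_T = residuals(pb, Tb)
            hp = 1e-7 + 1e-6 * abs(pb)
            hT_ = 1e-5 + 1e-7 * abs(Tb)
            f1p, f2p, *_ = residuals(min(pb + hp, 0.99995), Tb)
            f1t, f2t, *_ = residuals(pb, Tb + hT_)
            j11 = (f1p - f1) / hp
            j12 = (f1t - f1) / hT_
            j21 = (f2p - f2) / hp
            j22 = (f2t - f2) / hT_
            det = j11 * j22 - j12 * j21
            if det == 0.0 or not math.isfinite(det):
                break
            dp = -(f1 * j22 - f2 * j12) / det
            dT = -(j11 * f2 - j21 * f1) / det
            dT = min(max(dT, -25.0), 25.0)
            pb_new = min(max(pb + dp, 0.0), 0.9999)
            Tb_new = min(max(Tb + dT, 250.1), 399.0)
            if abs(pb_new - pb) < 1e-12 + 1e-9 * abs(pb) and abs(Tb_new - Tb) < 1e-9:
                pb, Tb = pb_new, Tb_new
                ok = True
                break
            pb, Tb = pb_new, Tb_new
        if not ok:
            # nested-bisection fallback: T_b outer, phi_b inner
            def outer(Tb_):
                h_m, h_T = self._hm_hT_s(R, Tb_, amb)
                pb_, F = self._solve_phi_b(phi_in, Tb_, R, c_inf, h_m)
                f2, _ = self._heat_residual(pb_, Tb_, T_in, R, amb, h_T, F)
                return f2

            lo = max(250.2, min(amb.T_inf, float(np.min(T_in))) - 40.0)
            hi = min(398.9, max(amb.T_inf, float(np.max(T_in))) + 40.0)
            flo, fhi = outer(lo), outer(hi)
            if flo * fhi > 0:
                raise SimulationError(
                    "boundary closure failed to bracket the surface temperature",
                    {"T_range": (lo, hi), "residuals": (flo, fhi)},
                )
            Tb = brentq(outer, lo, hi, xtol=1e-10)
            h_m, h_T = self._hm_hT_s(R, Tb, amb)
            pb, F = self._solve_phi_b(phi_in, Tb, R, c_inf, h_m)
            _, q_c = self._heat_residual(pb, Tb, T_in, R, amb, h_T, F)
        else:
            f1, f2, F, q_c, h_m, h_T = residuals(pb, Tb)
        self._bcache = [pb, Tb]
        return pb, Tb, F, q_c, h_m, h_T

    def _closure(self, t_h, phi, T, R):
        """Surface state (phi_b, T_b, F, q_c, h_m, h_T) for the current fields."""
        amb = ambient_at(t_h, self.program)
        phi_in = phi[-2:]
        variant = self.settings.variant
        if variant == "full":
            return (*self._solve_boundary_full(phi_in, np.asarray(T)[-2:], R, amb), amb)
        T_b = amb.T_inf if variant == "isothermal" else float(np.asarray(T).flat[0])
        h_m, h_T = self._hm_hT_s(R, T_b, amb)
        c_inf = self._pv_s(amb.T_inf) * amb.RH_inf / (tp.RG * amb.T_inf)
        phi_b, F = self._solve_phi_b(phi_in, T_b, R, c_inf, h_m)
        self._bcache[0] = phi_b
        lam_v = (2501.0 - 2.361 * (T_b - 273.15)) * 1.0e3
        q_c = h_T * (T_b - amb.T_inf) + lam_v * self.params.composition.rho_w * F
        return phi_b, T_b, F, q_c, h_m, h_T, amb

    # -- right-hand side -------------------------------------------------

    def _rhs(self, t, y):
        p, s, g = self.params, self.settings, self.grid
        n = self.n
        R0 = p.R0
        rho = max(float(y[self._iR]), 1e-4)
        R = rho * R0
        u = y[:n]
        phi = u / rho**3
        phic = self._phi_eff(phi)
        if s.variant == "full":
            e = y[self._iT] * self._eref / rho**3
            T = e / tp.volumetric_heat_capacity(phic, p.composition)
        elif s.variant == "lumped":
            T = np.full(n, float(y[self._iTb]))
        else:
            T = None  # set after ambient lookup

        t_h = t / 3600.0
        if s.variant == "isothermal":
            amb0 = ambient_at(t_h, self.program)
            T = np.full(n, amb0.T_inf)

        phi_b, T_b, F, q_c, h_m, h_T, amb = self._closure(t_h, phi, T, R)
        Rdot = -p.alpha0 * F

        D = np.asarray(p.diffusivity(T, phic), dtype=float)
        if D.ndim == 0:
            D = np.full(n, float(D))

        lam, dsig, sf = self._lam, self._dsig, self._sf
        dphi_f = np.diff(phi) / dsig
        phi_f = phi[:-1] + lam * np.diff(phi)
        D_f = 0.5 * (D[:-1] + D[1:])
        v_f = p.alpha0 * D_f * dphi_f / R
        q_f = -(D_f / R) * dphi_f + v_f * phi_f

        Gu = np.empty(n + 1)
        Gu[0] = 0.0
        Gu[1:-1] = (rho**2 / R0) * (sf**3 * Rdot * phi_f - sf**2 * q_f)
        Gu[-1] = -(rho**2 / R0) * F
        du = np.diff(Gu) / g.weights

        dy = np.empty_like(y)
        dy[:n] = du
        dy[self._iR] = Rdot / R0
        dy[self._iQ] = rho**2 * F / R0

        if s.variant == "full":
            _, _, k_p = tp.product_properties(phic, p.composition)
            e_f = e[:-1] + lam * np.diff(e)
            dT_f = np.diff(T) / dsig
            k_f = 0.5 * (k_p[:-1] + k_p[1:])
            qe_f = -(k_f / R) * dT_f + v_f * e_f
            Ge = np.empty(n + 1)
            Ge[0] = 0.0
            Ge[1:-1] = (rho**2 / (R0 * self._eref)) * (sf**3 * Rdot * e_f - sf**2 * qe_f)
            Ge[-1] = -(rho**2 / (R0 * self._eref)) * q_c
            dy[self._iT] = np.diff(Ge) / g.weights
        elif s.variant == "lumped":
            # d/dt [T_b * C(t)] = -4 pi R^2 q_c  with  C = 4 pi R^3 sum(w rho_cp)
            rho_cp = tp.volumetric_heat_capacity(phic, p.composition)
            C_hat = rho**3 * np.sum(g.weights * rho_cp)  # / (R0^3 4 pi)
            dphi_dt = du / rho**3 - 3.0 * phi * (Rdot / R)
            drho_cp = p.composition.rho_w * p.composition.Cp_w - \
                p.composition.rho_s * p.composition.Cp_s
            dC_hat = 3.0 * rho**2 * (Rdot / R0) * np.sum(g.weights * rho_cp) + \
                rho**3 * np.sum(g.weights * drho_cp * dphi_dt)
            dE = -(rho**2 / R0) * q_c
            dy[self._iTb] = (dE - float(y[self._iTb]) * dC_hat) / C_hat
        return dy

    # -- sparsity --------------------------------------------------------

    def _jac_sparsity(self):
        n, s = self.n, self.settings
        m = self.n_state
        S = lil_matrix((m, m), dtype=np.int8)
        band = np.arange(n)
        for off in (-1, 0, 1):
            j = band + off
            ok = (j >= 0) & (j < n)
            S[band[ok], j[ok]] = 1
            if s.variant == "full":
                S[band[ok], n + j[ok]] = 1
                S[n + band[ok], j[ok]] = 1
                S[n + band[ok], n + j[ok]] = 1
        # columns every row depends on: boundary closure inputs + radius (+ lumped T_b)
        dense_cols = [n - 2, n - 1, self._iR]
        if s.variant == "full":
            dense_cols += [2 * n - 2, 2 * n - 1]
        elif s.variant == "lumped":
            dense_cols += [self._iTb]
        S[:, dense_cols] = 1
        if s.variant == "lumped":
            S[self._iTb, :] = 1  # energy balance sees every cell's heat capacity
        return S.tocsr()

    # -- driver ----------------------------------------------------------

    def _output_times(self, t_end_h: float) -> np.ndarray:
        s = self.settings
        t = np.arange(0.0, t_end_h + 1e-12, s.output_dt_h)
        pieces = [t, np.array([t_end_h])]
        for t_k in self.program.switch_times_h:
            if t_k > t_end_h:
                continue
            lo, hi = max(0.0, t_k - 0.5), min(t_end_h, t_k + 0.5)
            pieces.append(np.arange(lo, hi + 1e-12, s.switch_output_dt_h))
        out = np.unique(np.concatenate(pieces))
        return out[(out >= 0.0) & (out <= t_end_h)]

    def initial_state(self) -> np.ndarray:
        p, s = self.params, self.settings
        y0 = np.empty(self.n_state)
        y0[: self.n] = p.phi0
        if s.variant == "full":
            y0[self._iT] = tp.volumetric_heat_capacity(p.phi0, p.composition) * p.T0 / self._eref
        elif s.variant == "lumped":
            y0[self._iTb] = p.T0
        y0[self._iR] = 1.0
        y0[self._iQ] = 0.0
        return y0

    def run(self) -> Trajectory:
        p, s = self.params, self.settings
        t_end_h = s.t_end_h if s.t_end_h is not None else self.program.total_duration_h
        if not math.isfinite(t_end_h):
            raise ValueError("open-ended program: provide SolverSettings.t_end_h")
        t_eval = self._output_times(t_end_h)
        y0 = self.initial_state()

        def r_floor(t, y):
            return float(y[self._iR]) - s.r_floor_frac

        r_floor.terminal = True
        r_floor.direction = -1

        # errstate: scipy's grouped finite-difference Jacobian inflates its
        # step factors without bound on columns the RHS provably ignores
        # (the cumulative-outflow state); the resulting overflow is benign.
        with np.errstate(over="ignore", invalid="ignore"):
            sol = solve_ivp(
                self._rhs,
                (0.0, t_end_h * 3600.0),
                y0,
                method="BDF",
                t_eval=t_eval * 3600.0,
                rtol=s.rtol,
                atol=s.atol,
                jac_sparsity=self._jac_sparsity(),
                events=[r_floor],
            )
        if not sol.success or sol.status == 1:
            reason = "radius collapsed below the floor" if sol.status == 1 else sol.message
            raise SimulationError(
                f"time integration failed: {reason}",
                {
                    "t_last_h": sol.t[-1] / 3600.0 if len(sol.t) else 0.0,
                    "y_last": sol.y[:, -1] if sol.y.size else None,
                },
            )
        phi_all = sol.y[: self.n] / sol.y[self._iR] ** 3
        if float(phi_all.min()) < -10.0 * s.atol:
            raise SimulationError(
                "negative water volume fraction beyond tolerance",
                {"phi_min": float(phi_all.min())},
            )
        return self._assemble(sol)

    def _assemble(self, sol) -> Trajectory:
        p, s, g = self.params, self.settings, self.grid
        n = self.n
        nt = sol.t.size
        times_h = sol.t / 3600.0
        X = np.empty(nt)
        Tb = np.empty(nt)
        Tc = np.empty(nt)
        hm = np.empty(nt)
        hT = np.empty(nt)
        Davg = np.empty(nt)
        phib = np.empty(nt)
        prof_phi = np.empty((nt, n))
        prof_T = np.empty((nt, n))
        rho_series = sol.y[self._iR]
        self._bcache = [p.phi0, p.T0]
        for k in range(nt):
            y = sol.y[:, k]
            rho = float(y[self._iR])
            R = rho * p.R0
            phi = y[:n] / rho**3
            phic = self._phi_eff(phi)
            if s.variant == "full":
                e = y[self._iT] * self._eref / rho**3
                T = e / tp.volumetric_heat_capacity(phic, p.composition)
            elif s.variant == "lumped":
                T = np.full(n, float(y[self._iTb]))
            else:
                T = np.full(n, ambient_at(times_h[k], self.program).T_inf)
            pb, tb, F, q_c, h_m, h_T_ = self._closure(times_h[k], phi, T, R)[:6]
            X[k] = np.sum(g.weights * phi) * rho**3 / (p.phi0 / 3.0)
            Tb[k], Tc[k] = tb, float(T[0])
            hm[k], hT[k] = h_m, h_T_
            Davg[k] = g.volume_average(np.broadcast_to(p.diffusivity(T, phic), (n,)))
            phib[k] = pb
            prof_phi[k] = phi
            prof_T[k] = T
        evaporated = sol.y[self._iQ] * 3.0 / p.phi0  # / (phi0/3) = fraction of initial water
        return Trajectory(
            times_h=times_h,
            X_ratio=X,
            V_ratio=rho_series**3,
            R_ratio=rho_series.copy(),
            T_b=Tb,
            T_center=Tc,
            h_m=hm,
            h_T=hT,
            D_avg=Davg,
            phi_b=phib,
            evaporated_ratio=evaporated,
            sigma=g.centers.copy(),
            profiles_phi=prof_phi,
            profiles_T=prof_T,
            R0=p.R0,
            phi0=p.phi0,
            variant=s.variant,
        )


def simulate(
    params: MaterialParams,
    program: CycleProgram,
    settings: SolverSettings = SolverSettings(),
) -> Trajectory:
    """Run the moving-boundary drying model and return its trajectory."""
    return Simulator(params, program, settings).run()
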