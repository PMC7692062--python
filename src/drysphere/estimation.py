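"""Effective-diffusivity estimation from dehydration curves.

The experimental pipeline works on the rescaled moisture curve X(t)/X0:

1. best-fit with a constrained sum of exponentials
   X/X0 = a0 + a1 e^{-b1 t} + a2 e^{-b2 t} + (1-a0-a1-a2) e^{-b3 t},
   which passes through 1 at t = 0 by construction and decays to a0;
2. evaluate the dimensionless dehydration rate J = -dXr/dt analytically
   from the fit, with Xr = (X/X0 - a0)/(1 - a0);
3. in the asymptotic window (small Xr) J is linear in Xr with slope
   Deff pi²/R0² (V_inf/V0)^{-2/3}; invert the through-origin slope for Deff;
4. regress ln Deff on 1/T across temperatures for the Arrhenius constants.

Sums of exponentials are notoriously ill-conditioned, so the fit is
multi-started from log-spaced rate triplets with a seeded generator.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence, Union

import numpy as np
from scipy.optimize import least_squares

from .thermophysical import ArrheniusLaw

__all__ = [
    "RateCurveFit",
    "DiffusivityEstimate",
    "FitError",
    "fit_dehydration_curve",
    "dehydration_rate",
    "asymptotic_deff",
    "fit_arrhenius",
    "generate_synthetic_curve",
]


class FitError(RuntimeError):
    """Non-convergent or degenerate fit; carries the best candidate found."""

    def __init__(self, message: str, best: Optional["RateCurveFit"] = None):
        super().__init__(message)
        self.best = best


@dataclass(frozen=True)
class RateCurveFit:
    """Constrained multi-exponential fit of a dehydration curve.

    ``a3 = 1 - a0 - a1 - a2`` is implied, so X(0)/X0 = 1 exactly; ``a0`` is
    the asymptote X_inf/X0.  Rates ``b`` are 1/h.  ``rms`` is the residual
    root mean square of the fit.
    """

    a0: float
    a1: float
    a2: float
    b1: float
    b2: float
    b3: float
    rms: float = float("nan")

    def __post_init__(self):
        if not (0.0 <= self.a0 < 1.0):
            raise ValueError("a0 must lie in [0, 1)")
        if min(self.b1, self.b2, self.b3) <= 0:
            raise ValueError("decay rates b_i must be > 0")

    @property
    def a3(self) -> float:
        return 1.0 - self.a0 - self.a1 - self.a2

    def __call__(self, t):
        t = np.asarray(t, dtype=float)
        out = (
            self.a0
            + self.a1 * np.exp(-self.b1 * t)
            + self.a2 * np.exp(-self.b2 * t)
            + self.a3 * np.exp(-self.b3 * t)
        )
        return out if out.ndim else float(out)


@dataclass(frozen=True)
class DiffusivityEstimate:
    """Asymptotic-slope diffusivity estimate from one dehydration curve."""

    D_eff: float  # m²/s
    T: Optional[float]  # K, the temperature the curve was measured at
    slope: float  # 1/h, through-origin slope of J vs Xr
    R0: float  # m
    V_ratio_inf: float  # [-]
    n_points: int = 0


def _model(params, t):
    a0, a1, a2, b1, b2, b3 = params
    a3 = 1.0 - a0 - a1 - a2
    return (
        a0
        + a1 * np.exp(-b1 * t)
        + a2 * np.exp(-b2 * t)
        + a3 * np.exp(-b3 * t)
    )


def fit_dehydration_curve(
    times_h,
    X_ratio,
    n_starts: int = 20,
    seed: int = 0,
    rms_threshold: float = 0.05,
) -> RateCurveFit:
    """Constrained nonlinear least squares of the multi-exponential curve.

    Multi-start initialization: decay-rate triplets log-spaced over
    [1e-3, 1] h^-1 with seeded jitter, amplitude starts from the data.
    Raises :class:`FitError` (carrying the best candidate) if no start
    reaches an RMS below ``rms_threshold`` times the data range, or if the
    series shows no decay at all.
    """
    t = np.asarray(times_h, dtype=float)
    x = np.asarray(X_ratio, dtype=float)
    if t.size < 12:
        raise ValueError("need at least 12 samples")
    if abs(x[0] - 1.0) > 0.1:
        raise ValueError("X_ratio must start near 1")
    data_range = float(x.max() - x.min())
    if data_range < 1e-3:
        raise FitError("degenerate series: no decay to fit")

    rng = np.random.default_rng(seed)
    lo = np.array([0.0, -2.0, -2.0, 1e-6, 1e-6, 1e-6])
    hi = np.array([0.999, 2.0, 2.0, 1e3, 1e3, 1e3])

    a0_guess = max(min(float(x[-1]), 0.99), 0.0)
    base_b = np.geomspace(1e-3, 1.0, 12)
    best = None
    best_cost = np.inf
    for k in range(n_starts):
        b = np.sort(rng.choice(base_b, size=3, replace=False) *
                    np.exp(rng.normal(0.0, 0.3, size=3)))[::-1]
        b = np.clip(b, 1e-6, 1e3)
        rem = 1.0 - a0_guess
        a1 = rem * rng.uniform(0.2, 0.6)
        a2 = rem * rng.uniform(0.1, 0.4)
        p0 = np.clip(np.array([a0_guess, a1, a2, b[0], b[1], b[2]]), lo, hi)
        try:
            res = least_squares(
                lambda p: _model(p, t) - x,
                p0,
                bounds=(lo, hi),
                xtol=1e-14,
                ftol=1e-14,
                gtol=1e-14,
                max_nfev=4000,
            )
        except Exception:
            continue
        if res.cost < best_cost:
            best_cost = res.cost
            best = res.x
    if best is None:
        raise FitError("all fit starts failed")
    rms = float(np.sqrt(np.mean((_model(best, t) - x) ** 2)))
    fit = RateCurveFit(*best, rms=rms)
    if rms > rms_threshold * data_range:
        raise FitError(
            f"fit did not converge: residual RMS {rms:.3g} exceeds "
            f"{rms_threshold:.0%} of the data range {data_range:.3g}",
            best=fit,
        )
    return fit


def dehydration_rate(fit: RateCurveFit, t):
    """Moisture ratio Xr and dimensionless dehydration rate J = -dXr/dt [1/h].

    Both follow analytically from the fitted curve:
    Xr = (X/X0 - a0)/(1 - a0) and
    J = (a1 b1 e^{-b1 t} + a2 b2 e^{-b2 t} + a3 b3 e^{-b3 t})/(1 - a0).
    """
    t = np.asarray(t, dtype=float)
    one = 1.0 - fit.a0
    Xr = (fit(t) - fit.a0) / one
    J = (
        fit.a1 * fit.b1 * np.exp(-fit.b1 * t)
        + fit.a2 * fit.b2 * np.exp(-fit.b2 * t)
        + fit.a3 * fit.b3 * np.exp(-fit.b3 * t)
    ) / one
    if t.ndim:
        return Xr, J
    return float(Xr), float(J)


def asymptotic_deff(
    source: Union[RateCurveFit, tuple],
    R0: float,
    V_ratio_inf: float = 1.0,
    xr_window: float = 0.2,
    T: Optional[float] = None,
) -> DiffusivityEstimate:
    """Effective diffusivity from the asymptotic linearity of J vs Xr.

    In the late-drying regime the rate curve is a straight line through the
    origin with slope Deff pi²/R0² (V_inf/V0)^{-2/3}; the through-origin
    least-squares slope over the window Xr < ``xr_window`` is inverted:

        Deff = slope * R0² * (V_inf/V0)^{2/3} / pi²   (slope in 1/s).

    ``source`` is either a :class:`RateCurveFit` (sampled densely in time)
    or a pair of arrays ``(Xr, J)`` with J in 1/h.
    """
    if not (0.0 < V_ratio_inf <= 1.0):
        raise ValueError("V_ratio_inf must lie in (0, 1]")
    if isinstance(source, RateCurveFit):
        b_min = min(source.b1, source.b2, source.b3)
        t = np.linspace(0.0, 12.0 / b_min, 4000)
        Xr, J = dehydration_rate(source, t)
    else:
        Xr, J = (np.asarray(a, dtype=float) for a in source)
    mask = (Xr > 0) & (Xr < xr_window) & np.isfinite(J)
    if int(mask.sum()) < 4:
        raise ValueError(
            f"only {int(mask.sum())} points with Xr < {xr_window}; need >= 4"
        )
    xr, j = Xr[mask], J[mask]
    slope_h = float(np.sum(j * xr) / np.sum(xr * xr))  # 1/h, through origin
    D = slope_h / 3600.0 * R0**2 * V_ratio_inf ** (2.0 / 3.0) / np.pi**2
    return DiffusivityEstimate(
        D_eff=D, T=T, slope=slope_h, R0=R0, V_ratio_inf=V_ratio_inf,
        n_points=int(mask.sum()),
    )


def fit_arrhenius(points: Sequence[tuple]) -> ArrheniusLaw:
    """Arrhenius constants from (T [K], Deff [m²/s]) pairs.

    Linear regression of ln D on 1/T: the slope is the activation
    temperature E/Rg [K] (negative when D increases with T under the
    D = D0 exp((E/Rg)/T) convention) and exp(intercept) is D0.  Two points
    give the exact line through them.
    """
    pts = [(float(T), float(D)) for T, D in points]
    if len(pts) < 2:
        raise ValueError("need at least two (T, D) points")
    T = np.array([p[0] for p in pts])
    D = np.array([p[1] for p in pts])
    if np.any(D <= 0) or np.any(T <= 0):
        raise ValueError("temperatures and diffusivities must be positive")
    if np.ptp(T) < 1e-9:
        raise ValueError("temperatures must be distinct")
    x = 1.0 / T
    y = np.log(D)
    slope, intercept = np.polyfit(x, y, 1)
    return ArrheniusLaw(D0=float(np.exp(intercept)), E_over_Rg=float(slope))


def generate_synthetic_curve(
    source,
    times_h=None,
    noise_sd: float = 0.005,
    seed: Optional[int] = None,
):
    """Synthetic (possibly noisy) dehydration curve for estimator testing.

    ``source`` may be a :class:`RateCurveFit`, a callable t -> X/X0, or an
    object with ``times_h`` and ``X_ratio`` attributes (a simulator
    trajectory).  Gaussian noise of standard deviation ``noise_sd`` is added
    with a seeded generator; ``noise_sd = 0`` returns the exact curve and a
    fixed seed gives bitwise-identical replicates.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    if hasattr(source, "times_h") and hasattr(source, "X_ratio"):
        t = np.asarray(source.times_h, dtype=float)
        x = np.asarray(source.X_ratio, dtype=float)
        if times_h is not None:
            t_new = np.asarray(times_h, dtype=float)
            x = np.interp(t_new, t, x)
            t = t_new
    else:
        if times_h is None:
            raise ValueError("times_h required when source is a curve law")
        t = np.asarray(times_h, dtype=float)
        x = np.asarray(source(t), dtype=float)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        x = x + rng.normal(0.0, noise_sd, size=t.shape)
    return t, x
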