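"""Derived scalar observables and the trajectory container.

The solver reports everything the experiments measure: rescaled total
moisture X(t)/X0 (a spherical quadrature of the water-volume-fraction
profile), rescaled volume V(t)/V0 = (R/R0)^3, boundary and center
temperatures, the heat/mass transfer coefficients, and the volume-averaged
effective diffusivity <Deff>.  Quadratures use the same finite-volume cell
weights as the solver, so the conservation statements checked in the test
suite are exact at the discrete level.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .grid import RadialGrid
from .thermophysical import DiffusivityLaw

__all__ = [
    "Trajectory",
    "moisture_ratio",
    "volume_ratio",
    "asymptotic_volume_ratio",
    "average_diffusivity",
]


def moisture_ratio(phi: np.ndarray, R: float, grid: RadialGrid, phi0: float, R0: float) -> float:
    """Rescaled total moisture X(t)/X0 = integral(phi dV) / (phi0 V0).

    The dry-solid mass is constant, so the ratio of water volumes equals the
    ratio of dry-basis moisture contents.
    """
    return float((R / R0) ** 3 * np.sum(grid.weights * phi) / (phi0 / 3.0))


def volume_ratio(R: float, R0: float) -> float:
    """Rescaled sample volume V/V0 = (R/R0)^3."""
    if R <= 0:
        raise ValueError("radius must be > 0")
    return float((R / R0) ** 3)


def asymptotic_volume_ratio(phi0: float, X_ratio_inf: float = 0.0) -> float:
    """Ideal-shrinkage volume asymptote V_inf/V0 = 1 - phi0 (1 - X_inf/X0).

    Under ideal shrinkage the volume lost equals the volume of water removed,
    so V/V0 is linear in X/X0 with slope phi0.  For a high-moisture sample
    (phi0 ~ 0.9) dried to completion the sample retains only ~10% of its
    initial volume.
    """
    if not (0.0 < phi0 <= 1.0):
        raise ValueError("phi0 must lie in (0, 1]")
    if not (0.0 <= X_ratio_inf <= 1.0):
        raise ValueError("X_ratio_inf must lie in [0, 1]")
    return 1.0 - phi0 * (1.0 - X_ratio_inf)


def average_diffusivity(
    T, phi, law: DiffusivityLaw, grid: RadialGrid
) -> float:
    """Volume-averaged effective diffusivity <Deff> over the current sphere.

    <Deff> = (3/R^3) * integral_0^R Deff(T(r)) r^2 dr, evaluated with the
    solver's cell weights; lies between min and max of Deff(T(.)).
    """
    T = np.broadcast_to(np.asarray(T, dtype=float), grid.centers.shape)
    phi = np.broadcast_to(np.asarray(phi, dtype=float), grid.centers.shape)
    return grid.volume_average(law(T, phi))


@dataclass
class Trajectory:
    """Time series and profile snapshots from one simulation run.

    Times are hours; temperatures kelvin internally (the CSV writer reports
    Celsius).  ``profiles_*`` are (n_times, n_cells) arrays on the reference
    grid; the physical radius of cell i at output k is sigma_i * R(t_k).
    """

    times_h: np.ndarray
    X_ratio: np.ndarray
    V_ratio: np.ndarray
    R_ratio: np.ndarray
    T_b: np.ndarray
    T_center: np.ndarray
    h_m: np.ndarray
    h_T: np.ndarray
    D_avg: np.ndarray
    phi_b: np.ndarray
    evaporated_ratio: np.ndarray  # cumulative water outflow / initial water volume
    sigma: np.ndarray
    profiles_phi: np.ndarray
    profiles_T: np.ndarray
    R0: float
    phi0: float
    variant: str = "full"

    def __post_init__(self):
        n = len(self.times_h)
        for name in ("X_ratio", "V_ratio", "R_ratio", "T_b", "T_center",
                     "h_m", "h_T", "D_avg", "phi_b", "evaporated_ratio"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"series {name} length mismatch with times")

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "t_h": self.times_h,
                "X_ratio": self.X_ratio,
                "V_ratio": self.V_ratio,
                "R_ratio": self.R_ratio,
                "T_b_C": self.T_b - 273.15,
                "T_center_C": self.T_center - 273.15,
                "h_m_m_s": self.h_m,
                "h_T_W_m2K": self.h_T,
                "D_avg_m2_s": self.D_avg,
                "phi_b": self.phi_b,
            }
        )

    def write_csv(self, path) -> None:
        """Trajectory CSV with '#' header comments carrying units."""
        df = self.to_dataframe()
        with open(path, "w") as fh:
            fh.write("# drying trajectory\n")
            fh.write(f"# variant: {self.variant}; R0 = {self.R0} m; phi0 = {self.phi0}\n")
            fh.write("# t_h [h], X_ratio [-], V_ratio [-], R_ratio [-], "
                     "T_b_C [degC], T_center_C [degC], h_m_m_s [m/s], "
                     "h_T_W_m2K [W/(m2 K)], D_avg_m2_s [m2/s], phi_b [-]\n")
            df.to_csv(fh, index=False)

    def write_profiles_csv(self, path, times_h: Optional[np.ndarray] = None) -> None:
        """Long-format profile snapshots (t, sigma, r, phi, T)."""
        if times_h is None:
            idx = np.arange(len(self.times_h))
        else:
            idx = [int(np.argmin(np.abs(self.times_h - t))) for t in np.atleast_1d(times_h)]
            idx = sorted(set(idx))
        rows = []
        for k in idx:
            R = self.R_ratio[k] * self.R0
            rows.append(
                pd.DataFrame(
                    {
                        "t_h": self.times_h[k],
                        "sigma": self.sigma,
                        "r_m": self.sigma * R,
                        "phi": self.profiles_phi[k],
                        "T_C": np.broadcast_to(self.profiles_T[k], self.sigma.shape) - 273.15,
                    }
                )
            )
        out = pd.concat(rows, ignore_index=True)
        with open(path, "w") as fh:
            fh.write("# water volume fraction and temperature profiles on the reference grid\n")
            fh.write("# t_h [h], sigma [-], r_m [m], phi [-], T_C [degC]\n")
            out.to_csv(fh, index=False)

    def at_time(self, t_h: float) -> int:
        """Index of the stored output closest to ``t_h``."""
        return int(np.argmin(np.abs(self.times_h - t_h)))
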