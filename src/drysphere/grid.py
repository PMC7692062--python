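"""Fixed reference grid for the front-fixing (Landau) formulation.

The moving domain r in [0, R(t)] is mapped onto sigma = r/R(t) in [0, 1].
The solver uses cell-centered finite volumes on a grid whose cells shrink
geometrically toward the moving boundary sigma = 1, where concentration and
temperature gradients are steepest.  Cell "volumes" are the spherical-shell
weights w_i = (s_i^3 - s_{i-1}^3)/3, so sum(w) = 1/3 and a volume integral
over the sphere is 4 pi R^3 sum(w_i f_i).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["RadialGrid"]


def _one_sided_weights(x1: float, x2: float, x3: float) -> np.ndarray:
    """Weights (c1, c2, c3) of the derivative at x3 of the quadratic through
    (x1, f1), (x2, f2), (x3, f3)."""
    c1 = (x3 - x2) / ((x1 - x2) * (x1 - x3))
    c2 = (x3 - x1) / ((x2 - x1) * (x2 - x3))
    c3 = (2.0 * x3 - x1 - x2) / ((x3 - x1) * (x3 - x2))
    return np.array([c1, c2, c3])


@dataclass(frozen=True)
class RadialGrid:
    """Cell-centered finite-volume grid on sigma in [0, 1].

    ``stretch`` is the ratio of the boundary-adjacent cell width to the
    center cell width (< 1 refines toward sigma = 1; 1 gives a uniform
    grid).
    """

    n: int
    stretch: float = 0.05
    faces: np.ndarray = field(init=False, repr=False)
    centers: np.ndarray = field(init=False, repr=False)
    weights: np.ndarray = field(init=False, repr=False)

    def __post_init__(self):
        if self.n < 16:
            raise ValueError("need at least 16 cells")
        if not (0 < self.stretch <= 1):
            raise ValueError("stretch must lie in (0, 1]")
        n = self.n
        if self.stretch == 1.0:
            widths = np.full(n, 1.0 / n)
        else:
            q = self.stretch ** (1.0 / (n - 1))
            widths = q ** np.arange(n)
            widths /= widths.sum()
        faces = np.concatenate([[0.0], np.cumsum(widths)])
        faces[-1] = 1.0
        object.__setattr__(self, "faces", faces)
        object.__setattr__(self, "centers", 0.5 * (faces[:-1] + faces[1:]))
        object.__setattr__(self, "weights", np.diff(faces**3) / 3.0)

    @property
    def interior_faces(self) -> np.ndarray:
        return self.faces[1:-1]

    @property
    def face_lambda(self) -> np.ndarray:
        """Linear-interpolation weight of the right cell at each interior face."""
        c = self.centers
        return (self.interior_faces - c[:-1]) / (c[1:] - c[:-1])

    @property
    def center_spacing(self) -> np.ndarray:
        return np.diff(self.centers)

    def boundary_gradient_weights(self) -> np.ndarray:
        """Second-order one-sided d/dsigma weights at sigma = 1 using the last
        two cell centers and the boundary value: g = c1 f[n-2] + c2 f[n-1] + cb f_b."""
        return _one_sided_weights(self.centers[-2], self.centers[-1], 1.0)

    def volume_average(self, f: np.ndarray) -> float:
        """Volume-weighted average of a cell field over the sphere."""
        return float(3.0 * np.sum(self.weights * f))
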