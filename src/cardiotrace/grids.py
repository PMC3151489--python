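"""Pseudo-polar and polar frequency grids.

The pseudo-polar grid samples the 2-D frequency square ``[-pi, pi]^2`` on
concentric squares crossed by slope-equispaced rays.  It splits into two
subnets: the *basically vertical* (BV) points, whose rays are closer to the
vertical axis,

    ``xi_y = pi*l/N``,  ``xi_x = 2*pi*m*l/N**2``,
    ``l in [-N, N)``,  ``m in [-N/2, N/2)``,

and the *basically horizontal* (BH) points with the roles of ``xi_x`` and
``xi_y`` exchanged and ``m in (-N/2, N/2]``.  Every point factors as
(radial level ``l``) x (slope ``2*m/N``), which is what makes the transform
computable with 1-D FFTs.

The polar grid is obtained from the pseudo-polar one by two 1-D resampling
stages: *rotate the rays* (slope-equispaced -> angle-equispaced, replacing
the slope ``2*m/N`` by ``tan(pi*m/(2*N))``) and *circle the squares*
(dividing each ray by the radial correction ``R(m)`` so the square levels
become concentric circles of radius ``pi*|l|/N``).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import cached_property

import numpy as np

from .errors import InvalidArgumentError

__all__ = [
    "PseudoPolarGrid",
    "PolarGrid",
    "radial_scale",
    "build_pseudopolar_grid",
    "build_polar_grid",
]


def _check_order(N: int) -> int:
    if not isinstance(N, (int, np.integer)):
        raise InvalidArgumentError(f"grid order must be an integer, got {N!r}")
    if N < 2 or N % 2:
        raise InvalidArgumentError(f"grid order must be even and >= 2, got {N}")
    return int(N)


def radial_scale(m, N: int):
    """Radial correction factor ``R(m) = sqrt(1 + tan(pi*m/(2*N))**2)``.

    ``R(m)`` is the factor by which a point on the concentric *square* at
    angular index ``m`` is farther from the origin than the concentric
    *circle* through the axis crossings; dividing by it "circles the
    squares".  Always in ``[1, sqrt(2)]``; ``R(0) == 1``.

    Accepts a scalar or array ``m`` with ``|m| <= N/2``.
    """
    N = _check_order(N)
    m_arr = np.asarray(m)
    if np.any(np.abs(m_arr) > N // 2):
        raise InvalidArgumentError(
            f"angular index out of range: need |m| <= {N // 2}, got {m!r}"
        )
    out = np.sqrt(1.0 + np.tan(np.pi * m_arr / (2 * N)) ** 2)
    return float(out) if np.isscalar(m) or m_arr.ndim == 0 else out


@dataclass(frozen=True)
class PseudoPolarGrid:
    """Concentric-square frequency grid of order ``N``.

    ``angular_oversample`` refines the ray set only (``a*N`` slopes per
    subnet instead of ``N``); the default 1 reproduces the textbook grid.
    Frequencies are returned as 2-D arrays indexed ``[l_index, m_index]``
    with ``l = l_index - N`` and the subnet-specific ``m`` offsets below.
    """

    N: int
    angular_oversample: int = 1

    def __post_init__(self) -> None:
        _check_order(self.N)
        if self.angular_oversample < 1:
            raise InvalidArgumentError("angular_oversample must be >= 1")

    @property
    def n_slopes(self) -> int:
        """Number of slopes per subnet (``a*N``)."""
        return self.angular_oversample * self.N

    @cached_property
    def l_values(self) -> np.ndarray:
        """Radial indices, ``[-N, N)`` (shared by both subnets)."""
        return np.arange(-self.N, self.N)

    @cached_property
    def bv_m_values(self) -> np.ndarray:
        """BV slope indices, ``[-a*N/2, a*N/2)``."""
        h = self.n_slopes // 2
        return np.arange(-h, h)

    @cached_property
    def bh_m_values(self) -> np.ndarray:
        """BH slope indices, ``(-a*N/2, a*N/2]``."""
        h = self.n_slopes // 2
        return np.arange(-h + 1, h + 1)

    def bv_frequencies(self) -> tuple[np.ndarray, np.ndarray]:
        """``(xi_x, xi_y)`` of the BV subnet, shape ``(2N, a*N)``."""
        l = self.l_values[:, None].astype(float)
        m = self.bv_m_values[None, :].astype(float)
        xi_y = np.broadcast_to(np.pi * l / self.N, (2 * self.N, self.n_slopes)).copy()
        xi_x = 2 * np.pi * m * l / (self.angular_oversample * self.N**2)
        return xi_x, xi_y

    def bh_frequencies(self) -> tuple[np.ndarray, np.ndarray]:
        """``(xi_x, xi_y)`` of the BH subnet, shape ``(2N, a*N)``."""
        l = self.l_values[:, None].astype(float)
        m = self.bh_m_values[None, :].astype(float)
        xi_x = np.broadcast_to(np.pi * l / self.N, (2 * self.N, self.n_slopes)).copy()
        xi_y = 2 * np.pi * m * l / (self.angular_oversample * self.N**2)
        return xi_x, xi_y

    def all_frequencies(self) -> tuple[np.ndarray, np.ndarray]:
        """Flattened ``(xi_x, xi_y)`` over BV then BH points."""
        bvx, bvy = self.bv_frequencies()
        bhx, bhy = self.bh_frequencies()
        return (
            np.concatenate([bvx.ravel(), bhx.ravel()]),
            np.concatenate([bvy.ravel(), bhy.ravel()]),
        )

    def count_rays(self, tol: float = 1e-9) -> int:
        """Count distinct lines through the origin among the nonzero points.

        Works geometrically (grouping points by direction modulo pi), so it
        is a genuine measurement of the constructed point set rather than a
        formula.
        """
        xx, yy = self.all_frequencies()
        nz = (xx != 0) | (yy != 0)
        ang = np.mod(np.arctan2(yy[nz], xx[nz]), np.pi)
        # collapse pi (from atan2 rounding) onto 0
        ang[np.abs(ang - np.pi) < tol] = 0.0
        return int(np.unique(np.round(ang / tol)).size)

    def count_squares(self, tol: float = 1e-9) -> int:
        """Count distinct concentric square levels (nonzero Chebyshev radii)."""
        xx, yy = self.all_frequencies()
        cheb = np.maximum(np.abs(xx), np.abs(yy))
        cheb = cheb[cheb > tol]
        return int(np.unique(np.round(cheb / tol)).size)


@dataclass(frozen=True)
class PolarGrid:
    """Equiangular, concentric-circle frequency grid of order ``N``.

    The canonical rectangular layout is ``(2N+1) x (2N+1)``: rows are the
    signed radial levels ``l in [-N, N]`` (radius ``pi*|l|/N``), columns are
    ``2N`` rays at angles ``theta_j = -pi/4 + (j+1)*pi/(2N)`` covering a
    half turn, plus one wrap-around column (the first ray advanced by pi)
    so that the layout closes angularly.  The frequency of entry ``(i, j)``
    is ``(pi*l_i/N) * (cos theta_j, sin theta_j)``; with the signed radius
    this covers the full circle.
    """

    N: int

    def __post_init__(self) -> None:
        _check_order(self.N)

    @cached_property
    def radial_levels(self) -> np.ndarray:
        """Signed radial indices for the layout rows, ``[-N, N]``."""
        return np.arange(-self.N, self.N + 1)

    @cached_property
    def ray_angles(self) -> np.ndarray:
        """Angles of the layout columns (2N rays plus the wrap column)."""
        j = np.arange(2 * self.N + 1)
        theta = -np.pi / 4 + (j + 1) * np.pi / (2 * self.N)
        theta[-1] = theta[0] + np.pi
        return theta

    def R(self, m) -> float:
        """Radial correction factor of ray ``m`` (see :func:`radial_scale`)."""
        return radial_scale(m, self.N)

    def frequencies(self) -> tuple[np.ndarray, np.ndarray]:
        """``(xi_x, xi_y)`` arrays for the ``(2N+1, 2N+1)`` layout."""
        radius = np.pi * self.radial_levels[:, None] / self.N
        theta = self.ray_angles[None, :]
        return radius * np.cos(theta), radius * np.sin(theta)

    def index_map(self) -> dict:
        """JSON-serializable description of the layout -> frequency map."""
        return {
            "rows": "signed radial level l, from -N (index 0) to +N (index 2N)",
            "cols": "ray angle theta_j = -pi/4 + (j+1)*pi/(2N); "
            "last column wraps the first ray by pi",
            "frequency": "(pi*l/N*cos(theta_j), pi*l/N*sin(theta_j))",
            "N": self.N,
        }


def build_pseudopolar_grid(N: int, angular_oversample: int = 1) -> PseudoPolarGrid:
    """Construct the pseudo-polar grid of order ``N`` (even, >= 2)."""
    return PseudoPolarGrid(_check_order(N), angular_oversample)


def build_polar_grid(N: int) -> PolarGrid:
    """Construct the equiangular concentric-circle grid of order ``N``."""
    return PolarGrid(_check_order(N))
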