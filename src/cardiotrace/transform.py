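"""Pseudo-polar and polar Fourier transforms of square images.

The transform evaluated here is the nonuniform DFT

    ``F(xi_x, xi_y) = sum_x sum_y f(x, y) * exp(-i*(xi_x*x + xi_y*y))``

with *centered* pixel coordinates ``x, y in [-P/2, P/2)`` (so the value at
the frequency origin is the plain pixel sum and phases are well defined).

On the pseudo-polar grid this factors into a 1-D FFT along one image axis
(the integer frequencies ``pi*l/P`` on a length-``2P`` transform) followed
by a fractional-frequency 1-D transform along the other axis at the
``l``-dependent step ``2*pi*l/(a*P**2)``, evaluated with a Bluestein
(chirp) scheme batched over all ``l`` at once.  Total cost is
``O(P**2 log P)`` and the result is exact to rounding error -- the direct
``O(P**4)`` sum is kept only as a test oracle.

The polar transform then resamples the pseudo-polar spectrum in two 1-D
stages.  Stage 1 ("rotate the rays") interpolates around each closed
concentric-square contour from slope-equispaced to angle-equispaced rays;
because the contour is a closed loop the default interpolant is the
band-limited trigonometric one (FFT of the loop samples evaluated at the
target angles), with a periodic cubic spline as the configurable fallback.
Stage 2 ("circle the squares") interpolates along each full diameter with a
cubic spline, placing samples at the exact circle radii ``pi*|l|/N``.
Accuracy is controlled by radial oversampling (zero-padding the image) and
angular oversampling (extra pseudo-polar rays); both default to 2x.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.fft import fft, ifft, next_fast_len
from scipy.interpolate import CubicSpline

from .errors import InvalidArgumentError, InvalidDataError
from .grids import PolarGrid, PseudoPolarGrid, build_polar_grid, build_pseudopolar_grid

__all__ = [
    "PolarTransformConfig",
    "PseudoPolarSpectrum",
    "PolarSpectrum",
    "pseudopolar_fft",
    "ppfft_direct_oracle",
    "interpolate_to_polar",
    "polar_fft",
    "save_polar_spectrum",
    "load_polar_spectrum",
]

_KERNELS = ("trig", "cubic")


@dataclass(frozen=True)
class PolarTransformConfig:
    """Accuracy/kernel knobs for :func:`polar_fft`.

    radial_oversample
        Integer zero-padding factor of the image before the pseudo-polar
        transform; densifies the radial sampling available to stage 2.
    angular_oversample
        Integer ray-refinement factor of the pseudo-polar grid; densifies
        the samples along each square contour available to stage 1.
    kernel
        Stage-1 contour interpolant: ``"trig"`` (band-limited, default) or
        ``"cubic"`` (periodic cubic spline).
    """

    radial_oversample: int = 2
    angular_oversample: int = 2
    kernel: str = "trig"

    def __post_init__(self) -> None:
        if self.radial_oversample < 1 or self.angular_oversample < 1:
            raise InvalidArgumentError("oversampling factors must be >= 1 integers")
        if self.kernel not in _KERNELS:
            raise InvalidArgumentError(f"kernel must be one of {_KERNELS}")


@dataclass(frozen=True)
class PseudoPolarSpectrum:
    """Transform values on a :class:`PseudoPolarGrid`.

    ``bv``/``bh`` are indexed ``[l_index, m_index]`` exactly like the grid's
    frequency arrays.  All ``l = 0`` entries describe the same frequency
    (the origin); :meth:`origin_value` is the single collapsed sample.
    """

    grid: PseudoPolarGrid
    bv: np.ndarray
    bh: np.ndarray

    def value(self, subnet: str, l: int, m: int) -> complex:
        """Look up one sample by subnet tag and ``(l, m)`` indices."""
        g = self.grid
        if subnet == "bv":
            return complex(self.bv[l + g.N, m + g.n_slopes // 2])
        if subnet == "bh":
            return complex(self.bh[l + g.N, m + g.n_slopes // 2 - 1])
        raise InvalidArgumentError(f"unknown subnet {subnet!r}")

    def origin_value(self) -> complex:
        """The single collapsed sample at the frequency origin."""
        return complex(self.bv[self.grid.N, 0])


@dataclass(frozen=True)
class PolarSpectrum:
    """Transform values on a :class:`PolarGrid` in the rectangular layout.

    ``values`` has shape ``(2N+1, 2N+1)``; see :class:`PolarGrid` for the
    index -> frequency map.  The last column and the ``l = +N`` row are the
    wrap-around/conjugate closures of the layout, and the whole ``l = 0``
    row holds the one origin sample; :meth:`feature_vector` returns each
    distinct non-origin frequency exactly once.
    """

    grid: PolarGrid
    values: np.ndarray

    def magnitude(self) -> np.ndarray:
        return np.abs(self.values)

    def feature_vector(self) -> np.ndarray:
        """Magnitudes at the distinct non-origin frequencies.

        Rows ``l in [-N, N)`` except ``l = 0``, columns ``j in [0, 2N)``:
        every remaining layout entry duplicates one of these (wrap column,
        conjugate ``+N`` row) or is the origin, which is excluded so that
        downstream correlations ignore global intensity offset.
        """
        N = self.grid.N
        mag = np.abs(self.values[:-1, :-1])  # drop +N row and wrap column
        keep = np.ones(2 * N, bool)
        keep[N] = False  # l == 0 row
        return mag[keep].ravel()


def _check_image(image: np.ndarray) -> np.ndarray:
    image = np.asarray(image)
    if np.iscomplexobj(image):
        raise InvalidArgumentError("image must be real-valued")
    if image.ndim != 2 or image.shape[0] != image.shape[1]:
        raise InvalidArgumentError(f"image must be square 2-D, got shape {image.shape}")
    if image.shape[0] < 2 or image.shape[0] % 2:
        raise InvalidArgumentError(f"image side must be even and >= 2, got {image.shape[0]}")
    if not np.all(np.isfinite(image)):
        raise InvalidDataError("image contains non-finite pixel values")
    return image.astype(np.float64, copy=False)


def _frac_dft_batch(G: np.ndarray, alphas: np.ndarray, m0: int, M: int) -> np.ndarray:
    """Rows of ``X[i, k] = sum_p G[i, p] exp(-1j*alphas[i]*(m0 + k)*p)``.

    Bluestein's identity ``k*p = (k**2 + p**2 - (k - p)**2)/2`` turns each
    row into one linear convolution with a chirp; all rows share one padded
    FFT length, so the whole batch is three FFTs.
    """
    n_rows, P = G.shape
    p = np.arange(P)
    A = G * np.exp(-1j * alphas[:, None] * (0.5 * p**2 + m0 * p)[None, :])
    L = next_fast_len(P + M - 1)
    n = np.arange(-(P - 1), M)
    chirp = np.exp(1j * alphas[:, None] * 0.5 * n[None, :] ** 2)
    conv = ifft(fft(A, L, axis=1) * fft(chirp, L, axis=1), axis=1)
    k = np.arange(M)
    X = conv[:, k + P - 1]
    X *= np.exp(-1j * alphas[:, None] * 0.5 * k[None, :] ** 2)
    return X


def _half_transform(img: np.ndarray, a: int, m0: int) -> np.ndarray:
    """One subnet: length-2P FFT along axis 0, fractional transform along axis 1."""
    P = img.shape[0]
    l = np.arange(-P, P)
    F = fft(img, 2 * P, axis=0)[np.mod(l, 2 * P), :]
    F = F * (1j) ** np.mod(l, 4)[:, None]  # centering phase exp(1j*pi*l/2)
    alphas = 2 * np.pi * l / (a * P**2)
    X = _frac_dft_batch(F.astype(complex), alphas, m0, a * P)
    m = m0 + np.arange(a * P)
    X *= np.exp(1j * alphas[:, None] * m[None, :] * (P // 2))  # centering along axis 1
    return X


def pseudopolar_fft(image: np.ndarray, angular_oversample: int = 1) -> PseudoPolarSpectrum:
    """Pseudo-polar Fourier transform of a real square image of even side.

    Exact (to rounding) at every grid point; cost ``O(P**2 log P)``.
    The image is indexed ``image[row, col] = f(x=col, y=row)`` with
    centered coordinates.
    """
    image = _check_image(image)
    P = image.shape[0]
    grid = build_pseudopolar_grid(P, angular_oversample)
    a = angular_oversample
    # BV: xi_y = pi*l/P acts on y (rows), fractional frequencies on x (cols)
    bv = _half_transform(image, a, -a * P // 2)
    # BH: roles of x and y exchanged
    bh = _half_transform(image.T, a, -a * P // 2 + 1)
    return PseudoPolarSpectrum(grid=grid, bv=bv, bh=bh)


def ppfft_direct_oracle(image: np.ndarray, grid) -> "PseudoPolarSpectrum | PolarSpectrum":
    """Brute-force nonuniform DFT at every grid point (test oracle only).

    Evaluates the double sum literally; quadratic in the number of points
    times pixels.  Accepts either grid type and returns the matching
    spectrum container.
    """
    image = _check_image(image)
    P = image.shape[0]
    c = np.arange(P) - P // 2

    def ndft(xx: np.ndarray, xy: np.ndarray) -> np.ndarray:
        Ex = np.exp(-1j * xx.ravel()[:, None] * c[None, :])
        Ey = np.exp(-1j * xy.ravel()[:, None] * c[None, :])
        vals = np.einsum("ky,yx,kx->k", Ey, image.astype(complex), Ex)
        return vals.reshape(xx.shape)

    if isinstance(grid, PseudoPolarGrid):
        return PseudoPolarSpectrum(
            grid=grid,
            bv=ndft(*grid.bv_frequencies()),
            bh=ndft(*grid.bh_frequencies()),
        )
    if isinstance(grid, PolarGrid):
        return PolarSpectrum(grid=grid, values=ndft(*grid.frequencies()))
    raise InvalidArgumentError(f"unsupported grid type {type(grid).__name__}")


class _InterpPlan:
    """Precomputed index arrays / operators for one (P, a, N, kernel) tuple."""

    def __init__(self, P: int, a: int, N: int, kernel: str):
        self.P, self.a, self.N, self.kernel = P, a, N, kernel
        aP = a * P
        self.aP = aP
        self.K = 4 * aP
        # target angles over the full circle, matching the PolarGrid columns
        k4 = np.arange(4 * N)
        self.phi = -np.pi / 4 + (k4 + 1) * np.pi / (2 * N)
        # contour parameter of each target angle (4 edges x aP samples per loop)
        delta = 2.0 / aP
        u = np.empty(4 * N)
        for i, ang in enumerate(self.phi):
            if ang <= np.pi / 4:
                u[i] = (np.tan(ang) + 1) / delta - 1
            elif ang <= 3 * np.pi / 4:
                u[i] = aP + (1 - np.tan(np.pi / 2 - ang)) / delta - 1
            elif ang <= 5 * np.pi / 4:
                u[i] = 2 * aP + (np.tan(ang - np.pi) + 1) / delta - 1
            else:
                u[i] = 3 * aP + (1 - np.tan(3 * np.pi / 2 - ang)) / delta - 1
        self.u = np.mod(u, self.K)
        if kernel == "trig":
            kk = np.fft.fftfreq(self.K) * self.K
            E = np.exp(2j * np.pi * kk[:, None] * self.u[None, :] / self.K) / self.K
            E[self.K // 2, :] = np.cos(np.pi * self.u) / self.K
            self.E = E
        # stage 2: per-column radial evaluation points (in units of the
        # pseudo-polar level spacing) hitting the circle radii pi*l/N exactly
        self.R_ray = 1.0 / np.maximum(np.abs(np.cos(self.phi)), np.abs(np.sin(self.phi)))
        lv = np.arange(-N, N + 1)
        r = P // N
        self.radial_targets = lv[:, None] * (r / self.R_ray[None, : 2 * N])
        self.t_grid = np.arange(-P, P + 1)


_PLANS: dict[tuple, _InterpPlan] = {}


def _get_plan(P: int, a: int, N: int, kernel: str) -> _InterpPlan:
    key = (P, a, N, kernel)
    if key not in _PLANS:
        if len(_PLANS) > 32:
            _PLANS.clear()
        _PLANS[key] = _InterpPlan(P, a, N, kernel)
    return _PLANS[key]


def _build_loops(spec: PseudoPolarSpectrum) -> np.ndarray:
    """Arrange the two subnets into closed square contours.

    Returns shape ``(P+1, 4*a*P)``: row ``lam`` walks the level-``lam``
    square counterclockwise from just past angle -pi/4 (right, top, left,
    bottom edge).  The outermost square's right/top edges are not on the
    grid (``l`` stops at ``P-1``) and are completed by conjugate symmetry
    of the real-image transform.
    """
    g = spec.grid
    P, aP = g.N, g.n_slopes
    rev = slice(None, None, -1)
    loops = np.empty((P + 1, 4 * aP), complex)
    lam = np.arange(1, P)
    loops[1:P, 0 * aP : 1 * aP] = spec.bh[lam + P, :]
    loops[1:P, 1 * aP : 2 * aP] = spec.bv[lam + P, rev]
    loops[1:P, 2 * aP : 3 * aP] = spec.bh[P - lam, :]
    loops[1:P, 3 * aP : 4 * aP] = spec.bv[P - lam, rev]
    loops[P, 2 * aP : 3 * aP] = spec.bh[0, :]
    loops[P, 3 * aP : 4 * aP] = spec.bv[0, rev]
    loops[P, 0 * aP : 1 * aP] = np.conj(spec.bh[0, :])
    loops[P, 1 * aP : 2 * aP] = np.conj(spec.bv[0, rev])
    loops[0, :] = spec.origin_value()
    return loops


def interpolate_to_polar(
    pp_spectrum: PseudoPolarSpectrum,
    target_order: int | None = None,
    kernel: str = "trig",
) -> PolarSpectrum:
    """Resample a pseudo-polar spectrum onto the polar grid of ``target_order``.

    The pseudo-polar grid's order must be an integer multiple of the target
    order (that multiple is the radial oversampling; the grid's own
    ``angular_oversample`` is the angular one).  Both stages are 1-D:
    around closed square contours first, then along full diameters.
    """
    if kernel not in _KERNELS:
        raise InvalidArgumentError(f"kernel must be one of {_KERNELS}")
    g = pp_spectrum.grid
    P, a = g.N, g.angular_oversample
    N = target_order if target_order is not None else P
    if P % N or N % 2 or N < 2:
        raise InvalidArgumentError(
            f"pseudo-polar order {P} is not an integer multiple of target order {N}"
        )
    plan = _get_plan(P, a, N, kernel)
    loops = _build_loops(pp_spectrum)

    # stage 1: rotate the rays (contour interpolation at target angles)
    W = np.empty((P + 1, 4 * N), complex)
    if kernel == "trig":
        W[1:] = fft(loops[1:], axis=1) @ plan.E
    else:
        ug = np.arange(plan.K + 1)
        ext = np.concatenate([loops[1:], loops[1:, :1]], axis=1)
        cs = CubicSpline(ug, ext, axis=1, bc_type="periodic")
        W[1:] = cs(plan.u)
    W[0] = loops[0, 0]

    # stage 2: circle the squares (radial spline along each full diameter)
    out = np.empty((2 * N + 1, 2 * N + 1), complex)
    for j in range(2 * N):
        line = np.empty(2 * P + 1, complex)
        line[P:] = W[:, j]
        line[:P] = W[1:, j + 2 * N][::-1]
        out[:, j] = CubicSpline(plan.t_grid, line)(plan.radial_targets[:, j])
    out[:, 2 * N] = out[::-1, 0]
    return PolarSpectrum(grid=build_polar_grid(N), values=out)


def polar_fft(image: np.ndarray, config: PolarTransformConfig | None = None) -> PolarSpectrum:
    """Polar Fourier transform of an ``N x N`` real image.

    Zero-pads the image by the radial oversampling factor, computes the
    (angularly oversampled) pseudo-polar transform, and resamples onto the
    polar grid; the output layout is ``(2N+1) x (2N+1)``.
    """
    config = config or PolarTransformConfig()
    image = _check_image(image)
    N = image.shape[0]
    P = config.radial_oversample * N
    if P > N:
        pad = (P - N) // 2
        padded = np.zeros((P, P), dtype=np.float64)
        padded[pad : pad + N, pad : pad + N] = image
    else:
        padded = image
    pp = pseudopolar_fft(padded, config.angular_oversample)
    return interpolate_to_polar(pp, target_order=N, kernel=config.kernel)


def save_polar_spectrum(spectrum: PolarSpectrum, path: str | Path, *, config: PolarTransformConfig | None = None) -> None:
    """Debug export: write the layout array (NPY) plus a JSON sidecar."""
    path = Path(path)
    np.save(path, spectrum.values)
    sidecar = path.with_suffix(".json")
    meta = {"index_map": spectrum.grid.index_map()}
    if config is not None:
        meta["oversampling"] = {
            "radial": config.radial_oversample,
            "angular": config.angular_oversample,
            "kernel": config.kernel,
        }
    sidecar.write_text(json.dumps(meta, indent=2))


def load_polar_spectrum(path: str | Path) -> PolarSpectrum:
    """Read back a spectrum written by :func:`save_polar_spectrum`."""
    values = np.load(Path(path).with_suffix(".npy"))
    N = (values.shape[0] - 1) // 2
    return PolarSpectrum(grid=build_polar_grid(N), values=values)
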