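"""Complex spherical harmonics, regularized SH fitting and rotation filters.

Conventions
-----------
Complex orthonormal spherical harmonics :math:`Y_n^m(\\theta, \\phi)` with the
Condon–Shortley phase, physics convention: ``theta`` is the colatitude in
``[0, pi]`` and ``phi`` the azimuth in ``[0, 2*pi)``.  Diffusion-weighted MRI
signals are antipodally symmetric, so only even degrees are represented
anywhere in this package.

The central object linking rotations to SH coefficients is the *rotation
filter*: rotating a signal that is axially symmetric about the z-axis (a
"zonal" signal, coefficients :math:`C_n^0` only) so that its axis points
along a unit vector ``u`` multiplies each degree-``n`` coefficient block by
the unit-norm complex vector

.. math::

    U_u^n[m] = \\alpha_n \\, \\overline{Y_n^m(u)},
    \\qquad \\alpha_n = \\sqrt{4\\pi / (2n+1)}.

By the SH addition theorem these filters have unit l2 norm for every
direction, and the correlation of two filters of the same degree is the
Legendre polynomial of the cosine of the angle between their directions:
``<U_u^n, U_v^n> = P_n(u . v)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numpy.polynomial.legendre import legval
from scipy.special import sph_harm_y

__all__ = [
    "SHCoefficients",
    "alpha_n",
    "axial_profile",
    "cart_to_sph",
    "eval_sh_basis",
    "fit_sh",
    "n_coeffs",
    "rotation_filter",
    "sh_degrees",
    "sph_to_cart",
]

_UNIT_TOL = 1e-8


def cart_to_sph(xyz: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Convert unit vectors (..., 3) to colatitude/azimuth (radians)."""
    xyz = np.asarray(xyz, dtype=float)
    nrm = np.linalg.norm(xyz, axis=-1)
    if not np.allclose(nrm, 1.0, atol=1e-6):
        raise ValueError("directions must be unit vectors")
    theta = np.arccos(np.clip(xyz[..., 2] / nrm, -1.0, 1.0))
    phi = np.mod(np.arctan2(xyz[..., 1], xyz[..., 0]), 2.0 * np.pi)
    return theta, phi


def sph_to_cart(theta: np.ndarray, phi: np.ndarray) -> np.ndarray:
    """Convert colatitude/azimuth to unit vectors, stacked on the last axis."""
    theta = np.asarray(theta, dtype=float)
    phi = np.asarray(phi, dtype=float)
    st = np.sin(theta)
    return np.stack([st * np.cos(phi), st * np.sin(phi), np.cos(theta)], axis=-1)


def sh_degrees(n_max: int) -> list[int]:
    """Even degrees 0, 2, ..., n_max."""
    _check_even(n_max)
    return list(range(0, n_max + 1, 2))


def n_coeffs(n_max: int) -> int:
    """Number of even-degree coefficients up to ``n_max``."""
    return sum(2 * n + 1 for n in sh_degrees(n_max))


def _check_even(n: int) -> None:
    if n < 0 or n % 2 != 0:
        raise ValueError(f"degree must be even and non-negative, got {n}")


def _nm_arrays(n_max: int) -> tuple[np.ndarray, np.ndarray]:
    """Flat (n, m) index arrays: n ascending even, m ascending within n."""
    ns, ms = [], []
    for n in sh_degrees(n_max):
        for m in range(-n, n + 1):
            ns.append(n)
            ms.append(m)
    return np.asarray(ns), np.asarray(ms)


def alpha_n(n: int) -> float:
    """Rotation-filter normalization ``sqrt(4*pi / (2n+1))``."""
    return float(np.sqrt(4.0 * np.pi / (2 * n + 1)))


def eval_sh_basis(directions: np.ndarray, n_max: int) -> np.ndarray:
    """Evaluate the even-degree complex SH basis at unit directions.

    Parameters
    ----------
    directions : (n_dirs, 3) array of unit vectors.
    n_max : even maximum degree.

    Returns
    -------
    (n_dirs, n_coeffs) complex matrix; column (n, m) in the canonical flat
    ordering holds :math:`Y_n^m` at each direction.
    """
    _check_even(n_max)
    directions = np.atleast_2d(np.asarray(directions, dtype=float))
    theta, phi = cart_to_sph(directions)
    ns, ms = _nm_arrays(n_max)
    return sph_harm_y(ns[None, :], ms[None, :], theta[:, None], phi[:, None])


@dataclass
class SHCoefficients:
    """Even-degree complex SH expansion of a spherical signal.

    ``values`` is the flat coefficient vector in the canonical ordering:
    degree ascending (even only), order m ascending from -n to n within each
    degree.  For signals fitted from real-valued samples the coefficients
    obey the conjugate symmetry ``c_{n,-m} = (-1)^m conj(c_{n,m})``.
    """

    n_max: int
    values: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        _check_even(self.n_max)
        self.values = np.asarray(self.values, dtype=complex)
        if self.values.shape != (n_coeffs(self.n_max),):
            raise ValueError(
                f"expected {n_coeffs(self.n_max)} coefficients for n_max="
                f"{self.n_max}, got shape {self.values.shape}"
            )

    @property
    def degrees(self) -> list[int]:
        return sh_degrees(self.n_max)

    def degree_slice(self, n: int) -> slice:
        _check_even(n)
        if n > self.n_max:
            raise ValueError(f"degree {n} exceeds n_max={self.n_max}")
        start = sum(2 * k + 1 for k in range(0, n, 2))
        return slice(start, start + 2 * n + 1)

    def degree_vector(self, n: int) -> np.ndarray:
        """Length ``2n+1`` coefficient vector of degree ``n`` (m ascending)."""
        return self.values[self.degree_slice(n)]

    def set_degree_vector(self, n: int, vec: np.ndarray) -> None:
        vec = np.asarray(vec, dtype=complex)
        if vec.shape != (2 * n + 1,):
            raise ValueError(f"degree-{n} vector must have length {2 * n + 1}")
        self.values[self.degree_slice(n)] = vec


def per_degree_vector(coeffs: SHCoefficients, n: int) -> np.ndarray:
    """Extract the degree-``n`` block ``S^n`` in canonical m-ordering."""
    return coeffs.degree_vector(n)


def fit_sh(
    samples: np.ndarray,
    directions: np.ndarray,
    n_max: int,
    lambda_lb: float = 0.006,
) -> SHCoefficients:
    """Regularized least-squares SH expansion of sampled spherical data.

    Minimizes ``||B c - s||^2 + lambda_lb * sum (n(n+1))^2 |c_{n,m}|^2``:
    ordinary least squares with a Laplace–Beltrami penalty that damps high
    degrees (the degree-0 coefficient is unpenalized since n(n+1) = 0).

    See :func:`sh_design` to precompute the solver for repeated fits on a
    fixed direction set.
    """
    solver = sh_design(directions, n_max, lambda_lb)
    return solver(samples)


def sh_design(
    directions: np.ndarray, n_max: int, lambda_lb: float = 0.006
):
    """Precompute the regularized SH least-squares solver for a direction set.

    Returns a callable mapping a sample vector (or a stack of sample vectors,
    shape (..., n_dirs)) to :class:`SHCoefficients` (or a (..., n_coeffs)
    coefficient array for stacked input).
    """
    if lambda_lb < 0:
        raise ValueError("lambda_lb must be non-negative")
    B = eval_sh_basis(directions, n_max)
    ns, _ = _nm_arrays(n_max)
    penalty = lambda_lb * (ns * (ns + 1.0)) ** 2
    gram = B.conj().T @ B + np.diag(penalty)
    if lambda_lb == 0:
        rank = np.linalg.matrix_rank(gram)
        if rank < gram.shape[0]:
            raise np.linalg.LinAlgError(
                f"SH design matrix is rank deficient (rank {rank} < "
                f"{gram.shape[0]} coefficients) and lambda_lb=0; add "
                "directions or regularize"
            )
    solve = np.linalg.inv(gram) @ B.conj().T

    def solver(samples: np.ndarray):
        samples = np.asarray(samples, dtype=float)
        if samples.shape[-1] != B.shape[0]:
            raise ValueError(
                f"expected {B.shape[0]} samples, got {samples.shape[-1]}"
            )
        if not np.all(np.isfinite(samples)):
            raise ValueError("samples must be finite")
        coeffs = samples @ solve.T
        if samples.ndim == 1:
            return SHCoefficients(n_max, coeffs)
        return coeffs

    return solver


def rotation_filter(u: np.ndarray, n: int) -> np.ndarray:
    """Rotation filter ``U_u^n``: unit-norm complex vector of length 2n+1.

    Entry ``m`` is ``alpha_n * conj(Y_n^m(u))``.  Rotating a zonal signal so
    its symmetry axis points along ``u`` maps its degree-n coefficient
    ``C_n^0`` to the vector ``C_n^0 * U_u^n``.
    """
    _check_even(n)
    u = np.asarray(u, dtype=float)
    theta, phi = cart_to_sph(np.atleast_2d(u))
    ms = np.arange(-n, n + 1)
    Y = sph_harm_y(n, ms[None, :], theta[:, None], phi[:, None])
    out = alpha_n(n) * np.conj(Y)
    return out[0] if u.ndim == 1 else out


def axial_profile(zonal_coeffs: np.ndarray, z_grid: np.ndarray) -> np.ndarray:
    """Reconstruct an axially symmetric profile from zonal coefficients.

    ``R(z) = sum_n c_n * sqrt((2n+1)/(4*pi)) * P_n(z)`` where ``c_n`` are
    given for even degrees 0, 2, ..., in ascending order and ``z`` is the
    cosine of the angle to the symmetry axis.
    """
    z_grid = np.asarray(z_grid, dtype=float)
    if np.any(np.abs(z_grid) > 1 + 1e-12):
        raise ValueError("z_grid values must lie in [-1, 1]")
    zonal_coeffs = np.asarray(zonal_coeffs, dtype=float)
    # Legendre series with zeros at odd degrees; weight by Y_n^0(z) = sqrt((2n+1)/4pi) P_n(z)
    n_deg = zonal_coeffs.shape[0]
    full = np.zeros(2 * n_deg - 1 if n_deg else 1)
    for i, c in enumerate(zonal_coeffs):
        n = 2 * i
        full[n] = c / alpha_n(n)
    return legval(np.clip(z_grid, -1.0, 1.0), full)


def legendre_correlation(n: int, cos_gamma: np.ndarray) -> np.ndarray:
    """``P_n(cos gamma)``: correlation of two degree-n rotation filters."""
    c = np.zeros(n + 1)
    c[n] = 1.0
    return legval(np.asarray(cos_gamma, dtype=float), c)
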