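"""Stage 2: per-voxel per-direction impulse-response estimation.

Given direction estimates ``v_1..v_K`` (from stage 1, or from any external
peak finder), the degree-n block of the signal expansion is modeled as
``S^n = sum_k x_{k,n} U_{v_k}^n`` and, for every even degree n >= 2
independently, the real coefficient vector ``x_n = (nu_k C_{k,n}^0)_k`` is
recovered by Laplace–Beltrami-regularized least squares

    min_x ||S^n - sum_k x_k U_{v_k}^n||^2 + lambda * (n(n+1))^2 * ||x||^2

with x constrained to be real (the unknowns are physically real, so the
real and imaginary parts of the linear system are stacked; solving the
unconstrained complex problem and taking the real part is not equivalent).

The degree-0 coefficient is not identifiable from the mixture (any split of
the voxel mean across fascicles reproduces the signal), so the zero-mean
signal is fitted with degrees >= 2 and each fascicle's degree-0 coefficient
is then set to the opposite of the minimum of its degree>=2 axial profile,
which makes the reconstructed response non-negative with minimum zero.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .sphharm import (
    SHCoefficients,
    alpha_n,
    axial_profile,
    rotation_filter,
    sh_degrees,
    sh_design,
)

__all__ = [
    "FascicleEstimate",
    "fit_direction_coeffs",
    "fit_volume_impulses",
    "resolve_degree0",
]

DEFAULT_LAMBDA = 1e-4
DEFAULT_Z_GRID = 401


@dataclass
class FascicleEstimate:
    """Per-voxel impulse-response estimates for K fascicles.

    ``coeffs[k, i]`` holds ``nu_k * C_{k,n}^0`` for even degree
    ``n = degrees[i]``; only the product of mix coefficient and kernel
    coefficient is identifiable.  ``profiles[k]`` is the axial response
    evaluated on ``z_grid``.
    """

    directions: np.ndarray  # (K, 3)
    degrees: list[int]      # [0, 2, ..., n_max]
    coeffs: np.ndarray      # (K, len(degrees)) real
    z_grid: np.ndarray
    profiles: np.ndarray    # (K, len(z_grid))
    lam: float


def fit_direction_coeffs(
    S: SHCoefficients,
    directions: np.ndarray,
    lam: float = DEFAULT_LAMBDA,
) -> np.ndarray:
    """Recover ``nu_k C_{k,n}^0`` for every even degree n >= 2.

    Returns a real (K, n_degrees) matrix, degree ascending from 2.  Degrees
    decouple: each column solves its own ridge system.  A warning is issued
    when K exceeds the 2n+1 equations available at some degree (the ridge
    solution is still defined).
    """
    directions = np.atleast_2d(np.asarray(directions, dtype=float))
    K = directions.shape[0]
    g = np.abs(directions @ directions.T)
    np.fill_diagonal(g, 0.0)
    if np.any(g > 1.0 - 1e-12):
        raise ValueError("coincident directions (after antipodal folding)")
    degrees = [n for n in S.degrees if n >= 2]
    out = np.empty((K, len(degrees)))
    for i, n in enumerate(degrees):
        if K > 2 * n + 1:
            import warnings

            warnings.warn(
                f"K={K} fascicles exceed the {2 * n + 1} equations at degree "
                f"{n}; the ridge solution is underdetermined",
                stacklevel=2,
            )
        U = rotation_filter(directions, n).T       # (2n+1, K) complex
        Sn = S.degree_vector(n)
        A = np.vstack([U.real, U.imag])            # real-constrained stacking
        b = np.concatenate([Sn.real, Sn.imag])
        ridge = lam * (n * (n + 1.0)) ** 2
        gram = A.T @ A + ridge * np.eye(K)
        out[:, i] = np.linalg.solve(gram, A.T @ b)
    return out


def resolve_degree0(
    coeffs: np.ndarray, z_grid: np.ndarray | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Fill in the unidentifiable degree-0 coefficient per fascicle.

    ``coeffs`` is (K, n_degrees>=2).  For each fascicle the degree>=2 axial
    profile is evaluated on ``z_grid`` and the degree-0 coefficient chosen so
    the constant term equals minus that profile's minimum, making the full
    response non-negative with minimum (numerically) zero.

    Returns ``(full_coeffs, profiles)`` where ``full_coeffs`` is
    (K, n_degrees+1) with the degree-0 column prepended and ``profiles`` the
    full responses on ``z_grid``.
    """
    if z_grid is None:
        z_grid = np.linspace(-1.0, 1.0, DEFAULT_Z_GRID)
    z_grid = np.asarray(z_grid, dtype=float)
    if z_grid.size < 201:
        raise ValueError("z_grid must have at least 201 points")
    coeffs = np.atleast_2d(np.asarray(coeffs, dtype=float))
    K = coeffs.shape[0]
    full = np.empty((K, coeffs.shape[1] + 1))
    profiles = np.empty((K, z_grid.size))
    for k in range(K):
        zonal = np.concatenate([[0.0], coeffs[k]])
        prof = axial_profile(zonal, z_grid)
        c0 = -prof.min() * alpha_n(0)  # constant term is c0 / sqrt(4*pi)
        full[k, 0] = c0
        full[k, 1:] = coeffs[k]
        profiles[k] = prof - prof.min()
    return full, profiles


def estimate_impulses(
    S: SHCoefficients,
    directions: np.ndarray,
    lam: float = DEFAULT_LAMBDA,
    z_grid: np.ndarray | None = None,
) -> FascicleEstimate:
    """Full stage-2 pipeline: per-degree LS then degree-0 resolution."""
    if z_grid is None:
        z_grid = np.linspace(-1.0, 1.0, DEFAULT_Z_GRID)
    directions = np.atleast_2d(np.asarray(directions, dtype=float))
    hi = fit_direction_coeffs(S, directions, lam=lam)
    full, profiles = resolve_degree0(hi, z_grid)
    return FascicleEstimate(
        directions=directions,
        degrees=sh_degrees(S.n_max),
        coeffs=full,
        z_grid=np.asarray(z_grid, dtype=float),
        profiles=profiles,
        lam=lam,
    )


def threshold_peaks(
    peaks: np.ndarray, threshold: float = 0.1
) -> np.ndarray:
    """Keep peaks whose norm is >= threshold x the voxel's largest peak norm.

    ``peaks`` is a flat (3*K,) vector of direction triples; survivors are
    returned l2-normalized as an (K', 3) array (possibly empty).
    """
    p = np.asarray(peaks, dtype=float).reshape(-1, 3)
    norms = np.linalg.norm(p, axis=1)
    if norms.max(initial=0.0) == 0:
        return np.empty((0, 3))
    keep = norms >= threshold * norms.max()
    return p[keep] / norms[keep, None]


def fit_volume_impulses(
    dwi: np.ndarray,
    scheme,
    peaks: np.ndarray,
    lam: float = DEFAULT_LAMBDA,
    threshold: float = 0.1,
    n_max: int = 8,
    lambda_lb: float = 0.006,
    k_max: int = 3,
    z_grid: np.ndarray | None = None,
) -> np.ndarray:
    """Per-voxel impulse coefficients over a 4D volume.

    ``peaks`` has 3 components per peak in its last axis (as produced by
    stage 1 or an external peak finder).  Peaks below ``threshold`` x the
    voxel's maximum peak norm are dropped and the survivors l2-normalized
    before fitting.  Output shape is ``dwi.shape[:3] + (k_max * n_deg,)``
    with the per-degree real coefficients (degree 0 first) of each fascicle;
    absent fascicles and voxels with no surviving peak are zero-filled.
    """
    dwi = np.asarray(dwi, dtype=float)
    if dwi.ndim != 4:
        raise ValueError("dwi must be 4D")
    degrees = sh_degrees(n_max)
    solver = sh_design(scheme.directions, n_max, lambda_lb)
    out = np.zeros(dwi.shape[:3] + (k_max * len(degrees),))
    n_empty = 0
    for idx in np.ndindex(dwi.shape[:3]):
        vdirs = threshold_peaks(peaks[idx], threshold)
        if vdirs.shape[0] == 0 or not np.any(dwi[idx]):
            n_empty += 1
            continue
        vdirs = vdirs[:k_max]
        est = estimate_impulses(solver(dwi[idx]), vdirs, lam=lam, z_grid=z_grid)
        for k in range(vdirs.shape[0]):
            out[idx][k * len(degrees) : (k + 1) * len(degrees)] = est.coeffs[k]
    if n_empty:
        import logging

        logging.getLogger(__name__).info(
            "fit_volume_impulses: %d voxels had no surviving peaks", n_empty
        )
    return out
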