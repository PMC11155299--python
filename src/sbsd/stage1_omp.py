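"""Stage 1: blind orientation retrieval via complex orthogonal matching pursuit.

The degree-n0 coefficient vector of the observed signal is, under the sparse
mixture model, a linear combination of K rotation filters
``S^{n0} = sum_k nu_k C_{k,n0}^0 U_{u_k}^{n0}``.  A dictionary of rotation
filters is precomputed on a fine hemisphere grid of candidate directions and
the K directions are retrieved greedily: at each step OMP selects the atom
with the largest |correlation| with the residual (atoms are unit norm, so no
renormalization is needed), re-solves the joint complex least squares over
all selected atoms, and updates the residual.  Atoms within an exclusion
angle of already selected directions are masked from later picks, since the
atom correlation ``P_n(cos gamma)`` decays slowly at low degree.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .sphharm import rotation_filter, sh_design

__all__ = [
    "OMPResult",
    "RotationDictionary",
    "build_dictionary",
    "fit_volume_directions",
    "omp_directions",
]


def fibonacci_hemisphere(n: int) -> np.ndarray:
    """Deterministic near-uniform grid of ``n`` directions with z > 0."""
    i = np.arange(n)
    z = (i + 0.5) / n
    phi = i * np.pi * (3.0 - np.sqrt(5.0))  # golden angle
    r = np.sqrt(1.0 - z**2)
    return np.stack([r * np.cos(phi), r * np.sin(phi), z], axis=1)


@dataclass(frozen=True)
class RotationDictionary:
    """Rotation-filter dictionary at a single even degree ``n0``.

    ``atoms`` has shape (2*n0+1, n_grid); column j is the unit-norm filter
    ``U_{v_j}^{n0}`` for grid direction ``v_j``.
    """

    n0: int
    grid: np.ndarray   # (n_grid, 3) hemisphere unit vectors
    atoms: np.ndarray  # (2*n0+1, n_grid) complex

    @property
    def n_grid(self) -> int:
        return self.grid.shape[0]

    def nearest(self, u: np.ndarray) -> int:
        """Index of the grid direction closest to axis ``u`` (folded)."""
        return int(np.argmax(np.abs(self.grid @ np.asarray(u, dtype=float))))


def build_dictionary(n0: int, n_grid: int = 4000, seed: int = 0) -> RotationDictionary:
    """Precompute the degree-``n0`` rotation-filter dictionary.

    The candidate directions are a deterministic spiral hemisphere grid
    (near-uniform; nearest-neighbor folded spacing ~ sqrt(2*pi/n_grid)).
    ``seed`` is accepted for API symmetry with the stochastic generators but
    the construction is deterministic.
    """
    if n0 < 2 or n0 % 2:
        raise ValueError("n0 must be an even degree >= 2")
    if n_grid < 2 * n0 + 1:
        raise ValueError(f"n_grid must be at least 2*n0+1 = {2 * n0 + 1}")
    grid = fibonacci_hemisphere(n_grid)
    atoms = rotation_filter(grid, n0).T
    return RotationDictionary(n0=n0, grid=grid, atoms=atoms)


@dataclass
class OMPResult:
    """Greedy sparse decomposition of a degree-n0 coefficient vector."""

    directions: np.ndarray    # (K, 3) selected grid directions
    coefficients: np.ndarray  # (K,) complex, final joint LS re-projection
    residual_norm: float
    n_iter: int

    @property
    def weights(self) -> np.ndarray:
        """|coefficient| per direction, used for peak scaling."""
        return np.abs(self.coefficients)


def omp_directions(
    Sn0: np.ndarray,
    dictionary: RotationDictionary,
    K: int = 2,
    exclusion_angle: float = 15.0,
    residual_tol: float | None = None,
) -> OMPResult:
    """Complex OMP over the rotation-filter dictionary.

    Parameters
    ----------
    Sn0 : complex vector of length 2*n0+1 (the degree-n0 block of the SH
        expansion of the measured signal).
    K : number of atoms (fascicles) to select.
    exclusion_angle : degrees; grid atoms within this folded angle of an
        already selected direction are masked from subsequent picks.  0
        disables masking.
    residual_tol : optional early stop when ``||r|| / ||Sn0||`` drops below
        this ratio (off by default; the fixed-K rule is the standard one).
    """
    Sn0 = np.asarray(Sn0, dtype=complex)
    if Sn0.shape != (2 * dictionary.n0 + 1,):
        raise ValueError(
            f"Sn0 must have length {2 * dictionary.n0 + 1}, got {Sn0.shape}"
        )
    s_norm = np.linalg.norm(Sn0)
    if s_norm == 0:
        raise ValueError("Sn0 is identically zero")
    if K < 1:
        raise ValueError("K must be >= 1")

    atoms = dictionary.atoms
    available = np.ones(dictionary.n_grid, dtype=bool)
    selected: list[int] = []
    residual = Sn0.copy()
    coeffs = np.zeros(0, dtype=complex)
    cos_excl = np.cos(np.radians(exclusion_angle))
    for it in range(K):
        corr = np.abs(atoms.conj().T @ residual)
        corr[~available] = -np.inf
        if not np.any(available):
            raise RuntimeError(
                f"all dictionary atoms masked after {len(selected)} of {K} "
                "picks; reduce exclusion_angle or enlarge the grid"
            )
        j = int(np.argmax(corr))
        selected.append(j)
        if exclusion_angle > 0:
            close = np.abs(dictionary.grid @ dictionary.grid[j]) >= cos_excl
            available &= ~close
        else:
            available[j] = False
        A = atoms[:, selected]
        coeffs, *_ = np.linalg.lstsq(A, Sn0, rcond=None)
        residual = Sn0 - A @ coeffs
        if residual_tol is not None and np.linalg.norm(residual) / s_norm < residual_tol:
            break
    return OMPResult(
        directions=dictionary.grid[selected].copy(),
        coefficients=coeffs,
        residual_norm=float(np.linalg.norm(residual)),
        n_iter=len(selected),
    )


def fit_volume_directions(
    dwi: np.ndarray,
    scheme,
    mask: np.ndarray | None,
    n0: int,
    K: int = 2,
    n_max: int = 8,
    lambda_lb: float = 0.006,
    dictionary: RotationDictionary | None = None,
    exclusion_angle: float = 15.0,
) -> np.ndarray:
    """Per-voxel stage-1 orientation estimation over a 4D volume.

    Returns a peaks volume of shape ``dwi.shape[:3] + (3*K,)``: K direction
    triples per voxel, each scaled by the modulus of its OMP coefficient.
    Voxels outside the mask, or with all-zero signal, are left zero.
    """
    dwi = np.asarray(dwi, dtype=float)
    if dwi.ndim != 4:
        raise ValueError("dwi must be 4D (x, y, z, directions)")
    if dictionary is None:
        dictionary = build_dictionary(n0)
    if mask is None:
        mask = np.ones(dwi.shape[:3], dtype=bool)
    solver = sh_design(scheme.directions, n_max, lambda_lb)
    peaks = np.zeros(dwi.shape[:3] + (3 * K,))
    n_skipped = 0
    coeffs_cls = None
    for idx in np.ndindex(dwi.shape[:3]):
        if not mask[idx]:
            continue
        sig = dwi[idx]
        if not np.any(sig):
            n_skipped += 1
            continue
        c = solver(sig)
        Sn0 = c.degree_vector(n0)
        if np.linalg.norm(Sn0) == 0:
            n_skipped += 1
            continue
        res = omp_directions(Sn0, dictionary, K=K, exclusion_angle=exclusion_angle)
        peaks[idx] = (res.directions * res.weights[:, None]).ravel()
    if n_skipped:
        import logging

        logging.getLogger(__name__).info(
            "fit_volume_directions: %d masked voxels had zero signal", n_skipped
        )
    return peaks
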