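"""Model/Results front end for sparse blind spherical deconvolution.

:class:`SparseBlindDeconvolution` wraps the two-stage pipeline for a single
voxel (or a batch of voxels sharing one acquisition scheme): a regularized
SH expansion of the measured shell, complex OMP over a rotation-filter
dictionary for the fascicle directions, and per-degree regularized least
squares for the per-fascicle axial impulse responses.  ``fit()`` returns a
:class:`SBSDResults` carrying the estimates, diagnostics and a ``summary()``
table, in the spirit of the statsmodels model/results split.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import metrics as _metrics
from .phantom import AcquisitionScheme
from .sphharm import SHCoefficients, sh_design
from .stage1_omp import RotationDictionary, build_dictionary, omp_directions
from .stage2_impulse import FascicleEstimate, estimate_impulses

__all__ = ["SBSDResults", "SparseBlindDeconvolution"]


class SparseBlindDeconvolution:
    """Blind spherical deconvolution of a single-shell DW-MRI signal.

    Parameters
    ----------
    signal : (n_dirs,) or (n_voxels, n_dirs) array
        Diffusion-attenuated amplitudes on the shell (b=0-normalized or not;
        only relative amplitudes matter for directions).
    scheme : AcquisitionScheme
        Shell b-value and unit gradient directions.
    n0 : even degree used for orientation retrieval (2..10). 6 is a good
        default at clinical b-values; 8 resolves sharper crossings but is
        more noise sensitive, 4 is the most robust to noise.
    n_max : SH expansion order; defaults to 8 for b <= 5000 s/mm^2 and 10
        above.
    lambda_lb : Laplace-Beltrami weight of the SH fit (default 0.006).
    lam : ridge weight of the stage-2 per-degree solve (default 1e-4).
    dictionary : optional precomputed rotation dictionary (reused across
        voxels; built on demand otherwise).
    """

    def __init__(
        self,
        signal: np.ndarray,
        scheme: AcquisitionScheme,
        n0: int = 6,
        n_max: int | None = None,
        lambda_lb: float = 0.006,
        lam: float = 1e-4,
        n_grid: int = 4000,
        exclusion_angle: float = 15.0,
        dictionary: RotationDictionary | None = None,
    ) -> None:
        self.signal = np.asarray(signal, dtype=float)
        if self.signal.ndim not in (1, 2):
            raise ValueError("signal must be a vector or a (voxels, dirs) matrix")
        if self.signal.shape[-1] != scheme.n_dirs:
            raise ValueError(
                f"signal has {self.signal.shape[-1]} samples but the scheme "
                f"has {scheme.n_dirs} directions"
            )
        self.scheme = scheme
        self.n0 = n0
        self.n_max = n_max if n_max is not None else _metrics.sh_order_for_bval(scheme.bval)
        self.lambda_lb = lambda_lb
        self.lam = lam
        self.exclusion_angle = exclusion_angle
        self._dictionary = dictionary
        self._n_grid = n_grid
        self._solver = sh_design(scheme.directions, self.n_max, lambda_lb)

    @classmethod
    def from_files(cls, dwi_path, bvals_path, bvecs_path, **kwargs):
        """Build a model from a 4D NIfTI volume and FSL bvals/bvecs tables.

        Voxels are flattened to a (n_voxels, n_dirs) signal matrix; the
        single nonzero shell is extracted and signals normalized by the
        mean b=0 volume.
        """
        from .io import read_dwi

        vol, scheme, b0 = read_dwi(dwi_path, bvals_path, bvecs_path)
        sig = vol.reshape(-1, vol.shape[-1])
        b0 = np.where(b0 <= 0, 1.0, b0).reshape(-1)
        return cls(sig / b0[:, None], scheme, **kwargs)

    @property
    def dictionary(self) -> RotationDictionary:
        if self._dictionary is None:
            self._dictionary = build_dictionary(self.n0, self._n_grid)
        return self._dictionary

    def fit(self, K: int = 2) -> "SBSDResults":
        """Run both stages and return the results object."""
        single = self.signal.ndim == 1
        signals = np.atleast_2d(self.signal)
        coeffs = self._solver(signals) if signals.shape[0] > 1 else None
        directions, weights, residuals, estimates, sh_list = [], [], [], [], []
        for i in range(signals.shape[0]):
            c = (
                SHCoefficients(self.n_max, coeffs[i])
                if coeffs is not None
                else self._solver(signals[i])
            )
            sn0 = c.degree_vector(self.n0)
            res = omp_directions(
                sn0, self.dictionary, K=K, exclusion_angle=self.exclusion_angle
            )
            est = estimate_impulses(c, res.directions, lam=self.lam)
            directions.append(res.directions)
            weights.append(res.weights)
            residuals.append(res.residual_norm / np.linalg.norm(sn0))
            estimates.append(est)
            sh_list.append(c)
        return SBSDResults(
            model=self,
            K=K,
            directions=np.stack(directions),
            peak_weights=np.stack(weights),
            relative_residuals=np.asarray(residuals),
            estimates=estimates,
            sh_coefficients=sh_list,
            single_voxel=single,
        )


@dataclass
class SBSDResults:
    """Estimates and diagnostics from :meth:`SparseBlindDeconvolution.fit`.

    ``directions`` is (n_voxels, K, 3); ``peak_weights`` the moduli of the
    OMP coefficients (|nu_k C_{k,n0}^0|); ``estimates`` holds the stage-2
    per-fascicle impulse coefficients and axial profiles per voxel.
    """

    model: SparseBlindDeconvolution
    K: int
    directions: np.ndarray
    peak_weights: np.ndarray
    relative_residuals: np.ndarray
    estimates: list[FascicleEstimate]
    sh_coefficients: list[SHCoefficients]
    single_voxel: bool = False

    @property
    def n_voxels(self) -> int:
        return self.directions.shape[0]

    def impulse_coeffs(self, voxel: int = 0) -> np.ndarray:
        """(K, n_degrees) real coefficients nu_k C_{k,n}^0, degree 0 first."""
        return self.estimates[voxel].coeffs

    def impulse_profiles(self, voxel: int = 0) -> tuple[np.ndarray, np.ndarray]:
        """(z_grid, (K, nz) profiles) of the reconstructed responses."""
        est = self.estimates[voxel]
        return est.z_grid, est.profiles

    def anisotropy_indices(self, voxel: int = 0) -> np.ndarray:
        """Per-fascicle AI from a tensor fitted to each impulse response."""
        est = self.estimates[voxel]
        return np.array(
            [
                _metrics.fit_tensor_to_impulse(
                    est.coeffs[k], est.directions[k], self.model.scheme
                ).ai
                for k in range(est.coeffs.shape[0])
            ]
        )

    def angular_errors(self, truth: np.ndarray) -> np.ndarray:
        """Folded angular errors (degrees) against ground-truth axes.

        ``truth`` is (K, 3) for a single voxel or (n_voxels, K, 3).
        """
        truth = np.asarray(truth, dtype=float)
        if truth.ndim == 2:
            truth = truth[None]
        return np.stack(
            [
                _metrics.angular_error(self.directions[i], truth[i]).errors
                for i in range(self.n_voxels)
            ]
        )

    def summary(self, voxel: int = 0) -> str:
        """Human-readable per-voxel report."""
        est = self.estimates[voxel]
        m = self.model
        lines = [
            "Sparse Blind Spherical Deconvolution Results",
            "=" * 52,
            f"shell b-value:       {m.scheme.bval:g} s/mm^2 "
            f"({m.scheme.n_dirs} directions)",
            f"SH order:            {m.n_max}   (lambda_lb={m.lambda_lb:g})",
            f"matching degree n0:  {m.n0}   (dictionary {self.model.dictionary.n_grid} atoms)",
            f"fascicles (K):       {self.K}",
            f"stage-1 rel. residual at n0: {self.relative_residuals[voxel]:.4f}",
            "",
            f"{'fascicle':>8} {'direction (x, y, z)':>28} {'|nu C_n0|':>10}",
        ]
        for k in range(self.K):
            d = self.directions[voxel, k]
            lines.append(
                f"{k + 1:>8} ({d[0]:+.4f}, {d[1]:+.4f}, {d[2]:+.4f})"
                f"{self.peak_weights[voxel, k]:>12.4f}"
            )
        lines.append("")
        deg_hdr = " ".join(f"{f'n={n}':>9}" for n in est.degrees)
        lines.append(f"{'nu_k C_k,n^0':>12} {deg_hdr}")
        for k in range(est.coeffs.shape[0]):
            row = " ".join(f"{v:>9.4f}" for v in est.coeffs[k])
            lines.append(f"{f'fascicle {k + 1}':>12} {row}")
        return "\n".join(lines)

    def plot_profiles(self, voxel: int = 0, ax=None):
        """Plot the reconstructed axial impulse responses against z."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        z, profiles = self.impulse_profiles(voxel)
        for k, prof in enumerate(profiles):
            ax.plot(z, prof, label=f"fascicle {k + 1}")
        ax.set_xlabel("z = cos(angle to fascicle axis)")
        ax.set_ylabel("impulse response")
        ax.legend()
        return ax
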