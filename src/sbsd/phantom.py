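"""Synthetic crossing-fascicle DWI phantoms.

A phantom voxel is a linear mixture of two axially symmetric canonical
signals, each rotated to its own fiber direction, measured on a single-shell
acquisition scheme and contaminated with Rician noise:

``y = nu1 * K1(u1 . g) + (1 - nu1) * K2(u2 . g)`` followed by
``noisy = sqrt((y + sigma*N1)^2 + (sigma*N2)^2)``.

The canonical signals are drawn from a bank of analytic axially symmetric
kernels built over a grid of intra-/extra-axonal diffusivities and fiber
volume fractions (stick+zeppelin two-compartment model with a tortuosity
coupling), or from the SMT-style single-compartment kernel
``exp(-B*lpar*z^2) * exp(-B*lperp*(1-z^2))``.

Units: b-values are carried in s·mm^-2 and diffusivities in m^2·s^-1; their
product is formed in exactly one place (:func:`_b_si`) using
1 s·mm^-2 = 1e6 s·m^-2.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from typing import Literal, Sequence

import numpy as np
from scipy.special import roots_legendre

from .sphharm import alpha_n, sh_degrees


@lru_cache(maxsize=8)
def leggauss(n: int):
    """Cached Gauss-Legendre nodes/weights on [-1, 1]."""
    return roots_legendre(n)

__all__ = [
    "AcquisitionScheme",
    "CanonicalKernel",
    "PhantomSample",
    "add_rician",
    "default_kernel_bank",
    "kernel_amplitude",
    "kernel_bank",
    "make_scheme",
    "sample_crossing",
]

# §-grid of the validation protocol: 5 x 5 x 2 = 50 canonical kernels.
DEFAULT_D_IN = (1.5e-9, 2e-9, 2.25e-9, 2.5e-9, 3e-9)
DEFAULT_D_EX = (1e-9, 1.5e-9, 2e-9, 2.5e-9, 3e-9)
DEFAULT_FVF = (0.7, 0.8)


def _b_si(bval_s_per_mm2: float) -> float:
    """Convert a b-value in s·mm^-2 to SI (s·m^-2).  The only unit bridge."""
    return float(bval_s_per_mm2) * 1e6


@dataclass(frozen=True)
class AcquisitionScheme:
    """Single-shell acquisition: one b-value and unit gradient directions."""

    bval: float
    directions: np.ndarray  # (n_dirs, 3) unit vectors
    b0_signal: float = 1.0

    def __post_init__(self) -> None:
        dirs = np.atleast_2d(np.asarray(self.directions, dtype=float))
        nrm = np.linalg.norm(dirs, axis=1)
        if not np.allclose(nrm, 1.0, atol=1e-8):
            raise ValueError("gradient directions must be unit vectors")
        object.__setattr__(self, "directions", dirs)

    @property
    def n_dirs(self) -> int:
        return self.directions.shape[0]

    def min_folded_angle(self) -> float:
        """Smallest pairwise angle (degrees) after antipodal folding."""
        g = np.abs(self.directions @ self.directions.T)
        np.fill_diagonal(g, 0.0)
        return float(np.degrees(np.arccos(np.clip(g.max(), -1, 1))))


def make_scheme(
    n_dirs: int, bval: float, seed: int, n_iter: int = 1000
) -> AcquisitionScheme:
    """Build a shell of gradient directions by electrostatic repulsion.

    Starting from a seeded uniform draw, ``n_dirs`` antipodal point pairs are
    relaxed on the sphere under a Coulomb 1/r^2 repulsion (each point repels
    every other point and every antipode) with projected gradient steps and
    step-size decay.  Deterministic given ``seed``.
    """
    if n_dirs < 2:
        raise ValueError("need at least 2 directions")
    rng = np.random.default_rng(seed)
    p = rng.standard_normal((n_dirs, 3))
    p /= np.linalg.norm(p, axis=1, keepdims=True)
    step0 = 0.1
    for it in range(n_iter):
        diff = p[:, None, :] - p[None, :, :]        # repulsion from points
        dsum = p[:, None, :] + p[None, :, :]        # repulsion from antipodes
        d1 = np.linalg.norm(diff, axis=-1)
        d2 = np.linalg.norm(dsum, axis=-1)
        np.fill_diagonal(d1, np.inf)
        np.fill_diagonal(d2, np.inf)
        force = (diff / d1[..., None] ** 3).sum(axis=1) + (
            dsum / d2[..., None] ** 3
        ).sum(axis=1)
        # project onto the tangent plane, step with decay, renormalize
        force -= (force * p).sum(axis=1, keepdims=True) * p
        fmax = np.abs(force).max()
        if fmax > 0:
            force /= fmax
        p += step0 * (1.0 - it / n_iter) * force
        p /= np.linalg.norm(p, axis=1, keepdims=True)
    return AcquisitionScheme(bval=bval, directions=p)


@dataclass(frozen=True)
class CanonicalKernel:
    """Axially symmetric single-fascicle signal model, normalized to 1 at b=0.

    ``two_compartment``: intra-axonal stick (diffusivity ``d_in`` along the
    axis, none across) plus extra-axonal zeppelin with axial diffusivity
    ``d_ex`` and a tortuosity-coupled radial diffusivity
    ``(1 - fvf) * d_ex``, mixed by the fiber volume fraction ``fvf``.

    ``smt``: ``exp(-B*lambda_par*z^2) * exp(-B*lambda_perp*(1-z^2))``.
    """

    model: Literal["two_compartment", "smt"] = "two_compartment"
    d_in: float = 2e-9
    d_ex: float = 2e-9
    fvf: float = 0.7
    lambda_par: float = 2e-9
    lambda_perp: float = 0.5e-9

    def amplitude(self, bval: float, z: np.ndarray) -> np.ndarray:
        return kernel_amplitude(self, bval, z)

    def zonal_coefficients(
        self, bval: float, n_max: int, n_quad: int = 2048
    ) -> np.ndarray:
        """Quadrature projection onto the zonal harmonics Y_n^0.

        ``C_n^0 = 2*pi * sqrt((2n+1)/(4*pi)) * int_{-1}^{1} K(z) P_n(z) dz``
        by Gauss–Legendre quadrature; returns even degrees 0..n_max.
        """
        x, w = leggauss(n_quad)
        k = self.amplitude(bval, x)
        out = np.empty(len(sh_degrees(n_max)))
        from numpy.polynomial.legendre import legval

        for i, n in enumerate(sh_degrees(n_max)):
            c = np.zeros(n + 1)
            c[n] = 1.0
            out[i] = 2.0 * np.pi / alpha_n(n) * np.sum(w * k * legval(x, c))
        return out

    def spherical_mean(self, bval: float, n_quad: int = 2048) -> float:
        x, w = leggauss(n_quad)
        return float(0.5 * np.sum(w * self.amplitude(bval, x)))


def kernel_amplitude(
    kernel: CanonicalKernel, bval: float, z: np.ndarray
) -> np.ndarray:
    """Signal amplitude of an axially symmetric kernel at ``z = cos(angle)``."""
    if bval < 0:
        raise ValueError("bval must be non-negative")
    z = np.asarray(z, dtype=float)
    if np.any(np.abs(z) > 1 + 1e-12):
        raise ValueError("z must lie in [-1, 1]")
    b = _b_si(bval)
    z2 = z**2
    if kernel.model == "two_compartment":
        d_perp = (1.0 - kernel.fvf) * kernel.d_ex  # tortuosity coupling
        intra = np.exp(-b * kernel.d_in * z2)
        extra = np.exp(-b * kernel.d_ex * z2) * np.exp(-b * d_perp * (1.0 - z2))
        return kernel.fvf * intra + (1.0 - kernel.fvf) * extra
    if kernel.model == "smt":
        return np.exp(-b * kernel.lambda_par * z2) * np.exp(
            -b * kernel.lambda_perp * (1.0 - z2)
        )
    raise ValueError(f"unknown kernel model {kernel.model!r}")


def kernel_bank(
    d_in: Sequence[float] = DEFAULT_D_IN,
    d_ex: Sequence[float] = DEFAULT_D_EX,
    fvf: Sequence[float] = DEFAULT_FVF,
) -> list[CanonicalKernel]:
    """Bank of two-compartment kernels over the full parameter grid.

    The default grid (5 intra-axonal diffusivities x 5 extra-axonal
    diffusivities x 2 volume fractions) yields 50 canonical kernels; ids
    (list positions) iterate d_in slowest, fvf fastest, deterministically.
    """
    if not (len(d_in) and len(d_ex) and len(fvf)):
        raise ValueError("parameter grids must be non-empty")
    return [
        CanonicalKernel(model="two_compartment", d_in=a, d_ex=b, fvf=f)
        for a in d_in
        for b in d_ex
        for f in fvf
    ]


def default_kernel_bank() -> list[CanonicalKernel]:
    return kernel_bank()


def add_rician(signal: np.ndarray, sigma: float, seed: int) -> np.ndarray:
    """Contaminate a magnitude signal with Rician noise.

    ``out = sqrt((s + sigma*N1)^2 + (sigma*N2)^2)`` with N1, N2 iid standard
    normal.  ``sigma = b0_signal / SNR`` when the SNR is defined against the
    b=0 amplitude.  ``sigma=0`` returns the input unchanged.
    """
    if sigma < 0:
        raise ValueError("sigma must be non-negative")
    signal = np.asarray(signal, dtype=float)
    if sigma == 0:
        return signal.copy()
    rng = np.random.default_rng(seed)
    n1 = rng.standard_normal(signal.shape)
    n2 = rng.standard_normal(signal.shape)
    return np.sqrt((signal + sigma * n1) ** 2 + (sigma * n2) ** 2)


@dataclass(frozen=True)
class PhantomSample:
    """One synthetic two-fascicle voxel with its ground truth."""

    scheme: AcquisitionScheme
    noiseless: np.ndarray
    noisy: np.ndarray
    gt_directions: np.ndarray  # (2, 3)
    nu1: float
    kernel_ids: tuple[int, int]
    snr: float
    seed: int


def _fold_upper(u: np.ndarray) -> np.ndarray:
    """Flip a direction into the z >= 0 hemisphere (ties keep +y then +x)."""
    u = np.asarray(u, dtype=float)
    s = np.sign(u[..., 2])
    zero = s == 0
    if np.any(zero):
        s = np.where(zero, np.sign(u[..., 1]) + (u[..., 1] == 0) * np.sign(u[..., 0]), s)
    s = np.where(s == 0, 1.0, s)
    return u * s[..., None]


def folded_angle_deg(u: np.ndarray, v: np.ndarray) -> float:
    """Angle between two axes (degrees), ignoring sign."""
    c = abs(float(np.dot(u, v)) / (np.linalg.norm(u) * np.linalg.norm(v)))
    return float(np.degrees(np.arccos(min(c, 1.0))))


def sample_crossing(
    bank: Sequence[CanonicalKernel],
    scheme: AcquisitionScheme,
    snr: float,
    nu_range: tuple[float, float] = (0.5, 0.85),
    min_angle: float = 25.0,
    seed: int = 0,
) -> PhantomSample:
    """Draw one two-fascicle phantom voxel.

    Two kernels are chosen uniformly from the bank; two directions are drawn
    uniformly on the sphere and rejection-sampled until their folded angle
    is at least ``min_angle`` degrees; the mix coefficient ``nu1`` is uniform
    over ``nu_range``; Rician noise at the given SNR (``inf`` for noiseless)
    is applied against the b=0 reference amplitude.
    """
    if min_angle >= 90:
        raise ValueError("min_angle >= 90 degrees is infeasible after folding")
    rng = np.random.default_rng(seed)
    i1, i2 = rng.integers(0, len(bank), size=2)
    while True:
        u = rng.standard_normal((2, 3))
        u /= np.linalg.norm(u, axis=1, keepdims=True)
        if folded_angle_deg(u[0], u[1]) >= min_angle:
            break
    u = _fold_upper(u)
    nu1 = float(rng.uniform(*nu_range))
    z1 = scheme.directions @ u[0]
    z2 = scheme.directions @ u[1]
    noiseless = nu1 * bank[i1].amplitude(scheme.bval, z1) + (
        1.0 - nu1
    ) * bank[i2].amplitude(scheme.bval, z2)
    noiseless = noiseless * scheme.b0_signal
    sigma = 0.0 if np.isinf(snr) else scheme.b0_signal / snr
    noisy = add_rician(noiseless, sigma, seed=int(rng.integers(0, 2**31)))
    return PhantomSample(
        scheme=scheme,
        noiseless=noiseless,
        noisy=noisy,
        gt_directions=u,
        nu1=nu1,
        kernel_ids=(int(i1), int(i2)),
        snr=snr,
        seed=seed,
    )


def sample_batch(
    bank: Sequence[CanonicalKernel],
    scheme: AcquisitionScheme,
    snr: float,
    n_samples: int,
    seed: int,
    nu_range: tuple[float, float] = (0.5, 0.85),
    min_angle: float = 25.0,
) -> list[PhantomSample]:
    """Draw ``n_samples`` phantoms with per-sample seeds derived by counter."""
    root = np.random.SeedSequence(seed)
    seeds = [int(s.generate_state(1)[0] % 2**31) for s in root.spawn(n_samples)]
    return [
        sample_crossing(bank, scheme, snr, nu_range, min_angle, seed=s)
        for s in seeds
    ]
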