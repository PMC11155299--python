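"""Readers and writers: NIfTI volumes, FSL bvals/bvecs, phantom bundles.

Gradient directions are interpreted in the image coordinate frame exactly
as given in the bvecs table; no affine re-orientation is applied.  Peak
comparisons across tools depend on this convention.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import nibabel as nib
import numpy as np

from .phantom import AcquisitionScheme, PhantomSample

__all__ = [
    "read_dwi",
    "save_phantom_bundle",
    "load_phantom_bundle",
    "write_nifti",
    "write_outputs",
]

log = logging.getLogger(__name__)

B0_THRESHOLD = 50.0  # s/mm^2; smaller b-values are treated as b=0
SHELL_TOL = 0.05     # relative tolerance when grouping b-values into shells


def _read_bvals_bvecs(bvals_path, bvecs_path) -> tuple[np.ndarray, np.ndarray]:
    bvals = np.loadtxt(bvals_path).ravel()
    bvecs = np.loadtxt(bvecs_path)
    if bvecs.shape[0] == 3 and bvecs.shape != (3, 3):
        bvecs = bvecs.T  # FSL layout: three rows of components
    if bvecs.shape[0] != bvals.size:
        raise ValueError(
            f"bvals ({bvals.size}) and bvecs ({bvecs.shape[0]}) disagree"
        )
    return bvals, bvecs


def read_dwi(
    dwi_path,
    bvals_path,
    bvecs_path,
    mask_path=None,
    shell: float | None = None,
):
    """Load a 4D DWI volume and extract one shell.

    Returns ``(shell_volume, AcquisitionScheme, b0_mean)`` and, if a mask
    path is given, ``(..., mask)``.  Volumes with b < 50 s/mm^2 are treated
    as b=0; a single nonzero shell is selected by nearest b-value within 5%
    relative tolerance (pass ``shell=`` explicitly for multi-shell input).
    Non-unit gradient columns are normalized with a logged warning.
    """
    img = nib.load(str(dwi_path))
    data = np.asarray(img.dataobj, dtype=float)
    if data.ndim != 4:
        raise ValueError("expected a 4D DWI volume")
    bvals, bvecs = _read_bvals_bvecs(bvals_path, bvecs_path)
    if data.shape[-1] != bvals.size:
        raise ValueError(
            f"volume has {data.shape[-1]} frames but gradient tables list "
            f"{bvals.size}"
        )
    is_b0 = bvals < B0_THRESHOLD
    shells = sorted({round(float(b), 6) for b in bvals[~is_b0]})
    grouped: list[float] = []
    for b in shells:
        if not grouped or b > grouped[-1] * (1 + SHELL_TOL):
            grouped.append(b)
    if shell is None:
        if len(grouped) > 1:
            raise ValueError(
                f"multi-shell input (shells ~ {grouped}); pass shell= to select"
            )
        shell = grouped[0]
    sel = (~is_b0) & (np.abs(bvals - shell) <= SHELL_TOL * shell)
    if not np.any(sel):
        raise ValueError(f"no volumes within 5% of requested shell b={shell}")
    dirs = bvecs[sel]
    norms = np.linalg.norm(dirs, axis=1)
    if not np.allclose(norms, 1.0, atol=1e-6):
        log.warning("non-unit bvecs columns; normalizing")
    dirs = dirs / norms[:, None]
    b0_mean = (
        data[..., is_b0].mean(axis=-1) if np.any(is_b0) else np.ones(data.shape[:3])
    )
    scheme = AcquisitionScheme(bval=float(np.mean(bvals[sel])), directions=dirs)
    out = (data[..., sel], scheme, b0_mean)
    if mask_path is not None:
        mask = np.asarray(nib.load(str(mask_path)).dataobj) > 0
        return out + (mask,)
    return out


def write_nifti(data: np.ndarray, path, affine: np.ndarray | None = None) -> None:
    if affine is None:
        affine = np.eye(4)
    nib.save(nib.Nifti1Image(np.asarray(data), affine), str(path))


def save_phantom_bundle(samples: list[PhantomSample], out_dir, force=False) -> dict:
    """Write a phantom batch as NIfTI + FSL tables + ground-truth sidecar.

    Layout: 4D NIfTI with samples along X (singleton Y/Z), the 4th dimension
    holding one b=0 frame followed by the gradient frames; ``bvals``/
    ``bvecs`` in FSL text layout; ``ground_truth.json`` with directions,
    mix coefficients, kernel ids, SNR and seeds.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    scheme = samples[0].scheme
    paths = {
        "dwi": out_dir / "dwi.nii.gz",
        "bvals": out_dir / "bvals",
        "bvecs": out_dir / "bvecs",
        "ground_truth": out_dir / "ground_truth.json",
    }
    if not force:
        for p in paths.values():
            if p.exists():
                raise FileExistsError(f"{p} exists; use force=True to overwrite")
    n = len(samples)
    vol = np.zeros((n, 1, 1, scheme.n_dirs + 1))
    vol[:, 0, 0, 0] = scheme.b0_signal
    for i, s in enumerate(samples):
        vol[i, 0, 0, 1:] = s.noisy
    write_nifti(vol, paths["dwi"])
    np.savetxt(
        paths["bvals"],
        np.concatenate([[0.0], np.full(scheme.n_dirs, scheme.bval)])[None],
        fmt="%g",
    )
    np.savetxt(
        paths["bvecs"],
        np.vstack([np.zeros((1, 3)), scheme.directions]).T,
        fmt="%.10f",
    )
    gt = {
        "bval": scheme.bval,
        "n_dirs": scheme.n_dirs,
        "b0_signal": scheme.b0_signal,
        "snr": None if np.isinf(samples[0].snr) else samples[0].snr,
        "samples": [
            {
                "directions": s.gt_directions.tolist(),
                "nu1": s.nu1,
                "kernel_ids": list(s.kernel_ids),
                "seed": s.seed,
            }
            for s in samples
        ],
    }
    paths["ground_truth"].write_text(json.dumps(gt, indent=1))
    return write_outputs(list(paths.values()), out_dir)


def load_phantom_bundle(bundle_dir):
    """Read back a phantom bundle: (signals, AcquisitionScheme, ground truth)."""
    bundle_dir = Path(bundle_dir)
    vol, scheme, _b0 = read_dwi(
        bundle_dir / "dwi.nii.gz", bundle_dir / "bvals", bundle_dir / "bvecs"
    )
    gt = json.loads((bundle_dir / "ground_truth.json").read_text())
    return vol[:, 0, 0, :], scheme, gt


def write_outputs(files: list, out_dir) -> dict:
    """Write a manifest (name -> sha256) covering the given files."""
    out_dir = Path(out_dir)
    manifest = {}
    for f in files:
        f = Path(f)
        manifest[f.name] = hashlib.sha256(f.read_bytes()).hexdigest()
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return manifest
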