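"""File formats: tensor/DWI NIfTI volumes, FSL bval/bvec text, report tables.

Tensor volumes are stored as 4D NIfTI with six components per voxel in the
package's lower-triangular order (Dxx, Dxy, Dyy, Dxz, Dyz, Dzz); 2D fields
are written with a singleton third axis.  Gradient schemes use the FSL
dialect: ``.bval`` holds one whitespace-separated row of b-values and
``.bvec`` three rows (x, y, z components), one column per volume; zero
vectors with b = 0 denote baseline volumes.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .dwi import DWISet, GradientTable
from .tensors import TensorField

__all__ = [
    "read_tensor_nifti",
    "write_tensor_nifti",
    "read_gradients",
    "write_gradients",
    "parse_gradients",
    "read_dwi_nifti",
    "write_dwi_nifti",
    "write_report",
    "write_sidecar",
]


def _affine_from_voxel_size(voxel_size) -> np.ndarray:
    vs = list(voxel_size) + [1.0] * (3 - len(voxel_size))
    affine = np.eye(4)
    affine[0, 0], affine[1, 1], affine[2, 2] = vs
    return affine


def write_tensor_nifti(field: TensorField, path, mask_path=None) -> None:
    """Write a tensor field as 4D NIfTI (..., 6), optionally with a mask image."""
    data = field.data
    squeeze = data.ndim == 3  # 2D slice -> add singleton z
    if squeeze:
        data = data[:, :, None, :]
    img = nib.Nifti1Image(np.asarray(data, dtype=np.float64), _affine_from_voxel_size(field.voxel_size))
    img.header["descrip"] = b"lower-tri tensor: Dxx Dxy Dyy Dxz Dyz Dzz"
    nib.save(img, str(path))
    if mask_path is not None:
        m = field.mask[:, :, None] if squeeze else field.mask
        nib.save(
            nib.Nifti1Image(m.astype(np.uint8), _affine_from_voxel_size(field.voxel_size)),
            str(mask_path),
        )


def read_tensor_nifti(path, mask_path=None) -> TensorField:
    """Read a 4D tensor NIfTI written by :func:`write_tensor_nifti`.

    The last axis must hold exactly 6 components.  A singleton third spatial
    axis is squeezed back to a 2D field.  Without a mask image, voxels whose
    six components are all zero are treated as background.
    """
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=np.float64)
    if data.ndim != 4 or data.shape[-1] != 6:
        raise ValueError(
            f"{path}: expected a 4D volume with 6 tensor components, got shape {data.shape}"
        )
    vs = tuple(float(v) for v in img.header.get_zooms()[:3])
    if data.shape[2] == 1:
        data = data[:, :, 0, :]
        vs = vs[:2]
    if mask_path is not None:
        mimg = nib.load(str(mask_path))
        mask = np.asarray(mimg.dataobj).astype(bool)
        if data.ndim == 3 and mask.ndim == 3 and mask.shape[2] == 1:
            mask = mask[:, :, 0]
    else:
        mask = np.any(data != 0, axis=-1)
    return TensorField(data=data, mask=mask, voxel_size=vs)


def parse_gradients(bval_text: str, bvec_text: str) -> GradientTable:
    """Parse FSL bval/bvec text into a :class:`GradientTable`."""
    bvals = np.array([float(v) for v in bval_text.split()])
    rows = [
        [float(v) for v in line.split()]
        for line in bvec_text.strip().splitlines()
        if line.strip()
    ]
    if len(rows) != 3:
        raise ValueError(f"bvec must have exactly 3 rows (x, y, z), got {len(rows)}")
    bvecs = np.array(rows).T  # (M, 3)
    if bvecs.shape[0] != bvals.shape[0]:
        raise ValueError(
            f"bval/bvec column mismatch: {bvals.shape[0]} b-values vs "
            f"{bvecs.shape[0]} directions"
        )
    norms = np.linalg.norm(bvecs, axis=1)
    is_b0 = (bvals == 0) | (norms == 0)
    if np.any(is_b0 & (bvals != 0)):
        raise ValueError("zero direction vector with non-zero b-value")
    dirs = bvecs[~is_b0]
    dn = np.linalg.norm(dirs, axis=1)
    if np.any(np.abs(dn - 1.0) > 1e-3):
        warnings.warn(
            "gradient directions off unit norm by > 1e-3; renormalising",
            RuntimeWarning,
            stacklevel=2,
        )
    dirs = dirs / dn[:, None]
    return GradientTable(bvals=bvals[~is_b0], bvecs=dirs, n_b0=int(is_b0.sum()))


def read_gradients(bval_path, bvec_path) -> GradientTable:
    """Read an FSL-style bval/bvec pair."""
    return parse_gradients(Path(bval_path).read_text(), Path(bvec_path).read_text())


def write_gradients(gtab: GradientTable, bval_path, bvec_path) -> None:
    """Write FSL-style bval/bvec files, baseline (b=0) columns first."""
    bvals = np.concatenate([np.zeros(gtab.n_b0), gtab.bvals])
    bvecs = np.vstack([np.zeros((gtab.n_b0, 3)), gtab.bvecs]).T  # (3, M)
    Path(bval_path).write_text(" ".join(f"{v:.17g}" for v in bvals) + "\n")
    Path(bvec_path).write_text(
        "\n".join(" ".join(f"{v:.17g}" for v in row) for row in bvecs) + "\n"
    )


def write_dwi_nifti(dwi: DWISet, path, bval_path=None, bvec_path=None) -> None:
    """Write all volumes (baselines first) as 4D NIfTI, plus optional bval/bvec."""
    vols = dwi.volumes()
    if vols.ndim == 3:  # 2D grid
        vols = vols[:, :, None, :]
    nib.save(nib.Nifti1Image(np.asarray(vols, dtype=np.float64), np.eye(4)), str(path))
    if bval_path is not None and bvec_path is not None:
        write_gradients(dwi.gtab, bval_path, bvec_path)


def read_dwi_nifti(path, bval_path, bvec_path, sigma: float | None = None) -> DWISet:
    """Read a 4D DWI NIfTI with its FSL gradient files (baselines first)."""
    gtab = read_gradients(bval_path, bvec_path)
    img = nib.load(str(path))
    vols = np.asarray(img.dataobj, dtype=np.float64)
    if vols.ndim == 4 and vols.shape[2] == 1:
        vols = vols[:, :, 0, :]
    n_total = gtab.n_b0 + gtab.n_directions
    if vols.shape[-1] != n_total:
        raise ValueError(
            f"{path}: {vols.shape[-1]} volumes but gradient files describe {n_total}"
        )
    return DWISet(
        b0=vols[..., : gtab.n_b0], dwi=vols[..., gtab.n_b0 :], gtab=gtab, sigma=sigma
    )


def write_report(report: pd.DataFrame, path) -> None:
    """Write an evaluation table as CSV."""
    report.to_csv(path, index=True)


def write_sidecar(path, config: dict) -> None:
    """Write a JSON sidecar (``<path>.json``) recording configuration and seed."""
    side = Path(str(path) + ".json")

    def _default(o):
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (np.integer, np.floating)):
            return o.item()
        return str(o)

    side.write_text(json.dumps(config, indent=2, default=_default, sort_keys=True) + "\n")
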