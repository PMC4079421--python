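"""Algebra on 3x3 symmetric positive-definite (SPD) diffusion tensors.

A diffusion tensor is a 3x3 SPD matrix whose eigenvalues give the magnitudes
of water diffusion along its eigenvector axes.  Only six components are
independent; throughout the package they are stored in lower-triangular order

    (Dxx, Dxy, Dyy, Dxz, Dyz, Dzz)

which is the common 6-component NIfTI convention.  All functions here are
vectorised: a "tensor" argument may be a single ``(3, 3)`` matrix or an array
of shape ``(..., 3, 3)``.

Diffusivities are carried in whatever unit the caller uses (the phantom uses
cm^2/sec); every operation in this module is unit-agnostic.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "LOWER_TRIANGULAR_COMPONENTS",
    "TensorSpectrum",
    "TensorField",
    "from_lower_triangular",
    "to_lower_triangular",
    "eig_spd",
    "log_spd",
    "exp_spd",
    "invsqrt_spd",
    "floor_eigenvalues",
    "is_spd",
    "fractional_anisotropy",
    "principal_direction",
    "trace_of",
]

#: Component names in storage order.
LOWER_TRIANGULAR_COMPONENTS = ("Dxx", "Dxy", "Dyy", "Dxz", "Dyz", "Dzz")

# row/column index of each stored component in the full 3x3 matrix
_ROWS = np.array([0, 1, 1, 2, 2, 2])
_COLS = np.array([0, 0, 1, 0, 1, 2])


def from_lower_triangular(components: np.ndarray) -> np.ndarray:
    """Expand ``(..., 6)`` lower-triangular components to full ``(..., 3, 3)``."""
    c = np.asarray(components, dtype=float)
    if c.shape[-1] != 6:
        raise ValueError(f"expected 6 tensor components, got {c.shape[-1]}")
    m = np.zeros(c.shape[:-1] + (3, 3), dtype=float)
    m[..., _ROWS, _COLS] = c
    m[..., _COLS, _ROWS] = c
    return m


def to_lower_triangular(matrices: np.ndarray) -> np.ndarray:
    """Collapse full symmetric ``(..., 3, 3)`` matrices to ``(..., 6)``."""
    m = np.asarray(matrices, dtype=float)
    if m.shape[-2:] != (3, 3):
        raise ValueError(f"expected (..., 3, 3) matrices, got shape {m.shape}")
    return m[..., _ROWS, _COLS].copy()


def _check_finite(m: np.ndarray, name: str = "tensor") -> None:
    if not np.all(np.isfinite(m)):
        raise ValueError(f"{name} contains non-finite components")


def _check_symmetric(m: np.ndarray, tol: float = 1e-8, name: str = "matrix") -> None:
    scale = np.maximum(np.abs(m).max(axis=(-2, -1)), 1.0)
    asym = np.abs(m - np.swapaxes(m, -1, -2)).max(axis=(-2, -1))
    if np.any(asym > tol * scale):
        raise ValueError(f"{name} is not symmetric within tolerance {tol}")


@dataclass(frozen=True)
class TensorSpectrum:
    """Eigendecomposition of an SPD tensor.

    Attributes
    ----------
    eigenvalues:
        ``(..., 3)`` sorted descending (lambda1 >= lambda2 >= lambda3).
    eigenvectors:
        ``(..., 3, 3)`` orthonormal; column ``[..., :, i]`` pairs with
        ``eigenvalues[..., i]``.
    """

    eigenvalues: np.ndarray
    eigenvectors: np.ndarray

    def reconstruct(self) -> np.ndarray:
        """Q diag(lambda) Q^T."""
        q = self.eigenvectors
        lam = self.eigenvalues
        return np.einsum("...ik,...k,...jk->...ij", q, lam, q)


def eig_spd(t: np.ndarray) -> TensorSpectrum:
    """Eigendecomposition with eigenvalues sorted descending.

    Warns (without failing) if any eigenvalue is non-positive, since noisy
    least-squares fits routinely produce such tensors.
    """
    m = np.asarray(t, dtype=float)
    _check_finite(m)
    _check_symmetric(m)
    lam, q = np.linalg.eigh(m)  # ascending
    lam = lam[..., ::-1]
    q = q[..., ::-1]
    if np.any(lam <= 0):
        warnings.warn("tensor has non-positive eigenvalues", RuntimeWarning, stacklevel=2)
    return TensorSpectrum(eigenvalues=lam, eigenvectors=q)


def is_spd(t: np.ndarray, tol: float = 0.0) -> np.ndarray:
    """Boolean (scalar or ``(...,)``) — all eigenvalues strictly above ``tol``."""
    m = np.asarray(t, dtype=float)
    lam = np.linalg.eigvalsh(m)
    return np.all(lam > tol, axis=-1)


def floor_eigenvalues(t: np.ndarray, rel_floor: float = 1e-12) -> np.ndarray:
    """Clamp small or negative eigenvalues to a floor relative to the tensor scale.

    Regularises non-SPD tensors from noisy fits so the matrix logarithm is
    defined.  The floor is ``rel_floor`` times the tensor's own largest
    absolute eigenvalue (of order the trace), so the operation is
    scale-covariant; a zero tensor is returned unchanged.
    """
    m = np.asarray(t, dtype=float)
    _check_finite(m)
    lam, q = np.linalg.eigh(m)
    scale = np.abs(lam).max(axis=-1)
    floor = rel_floor * scale[..., None]
    lam = np.maximum(lam, floor)
    return np.einsum("...ik,...k,...jk->...ij", q, lam, q)


def log_spd(t: np.ndarray, floor: float = 0.0) -> np.ndarray:
    """Matrix logarithm Q diag(ln lambda) Q^T of an SPD tensor.

    ``floor`` > 0 clamps eigenvalues to that absolute value before taking the
    log; with ``floor`` = 0 any non-positive eigenvalue raises.
    """
    m = np.asarray(t, dtype=float)
    _check_finite(m)
    _check_symmetric(m)
    lam, q = np.linalg.eigh(m)
    if floor > 0:
        lam = np.maximum(lam, floor)
    elif np.any(lam <= 0):
        raise ValueError("matrix is not positive definite; log_spd undefined")
    return np.einsum("...ik,...k,...jk->...ij", q, np.log(lam), q)


def exp_spd(s: np.ndarray) -> np.ndarray:
    """Matrix exponential of a symmetric matrix; the result is always SPD."""
    m = np.asarray(s, dtype=float)
    _check_finite(m, "symmetric matrix")
    _check_symmetric(m)
    lam, q = np.linalg.eigh(m)
    return np.einsum("...ik,...k,...jk->...ij", q, np.exp(lam), q)


def invsqrt_spd(t: np.ndarray) -> np.ndarray:
    """Inverse matrix square root of an SPD tensor (errors on non-SPD input)."""
    m = np.asarray(t, dtype=float)
    lam, q = np.linalg.eigh(m)
    if np.any(lam <= 0):
        raise ValueError("matrix is not positive definite; invsqrt_spd undefined")
    return np.einsum("...ik,...k,...jk->...ij", q, 1.0 / np.sqrt(lam), q)


def trace_of(t: np.ndarray) -> np.ndarray:
    """Trace Dxx + Dyy + Dzz (equals the eigenvalue sum)."""
    m = np.asarray(t, dtype=float)
    return np.trace(m, axis1=-2, axis2=-1)


def fractional_anisotropy(t: np.ndarray) -> np.ndarray:
    """Fractional anisotropy in [0, 1].

    FA = sqrt(3/2) * ||lambda - mean(lambda)|| / ||lambda||; 0 for isotropic
    tensors, -> 1 as the tensor becomes rank one.  The zero tensor yields 0
    with a warning.
    """
    m = np.asarray(t, dtype=float)
    _check_finite(m)
    lam = np.linalg.eigvalsh(m)
    norm2 = np.sum(lam**2, axis=-1)
    if np.any(norm2 == 0):
        warnings.warn("zero tensor: FA defined as 0", RuntimeWarning, stacklevel=2)
    mean = lam.mean(axis=-1, keepdims=True)
    dev2 = np.sum((lam - mean) ** 2, axis=-1)
    with np.errstate(invalid="ignore", divide="ignore"):
        fa = np.sqrt(1.5 * dev2 / norm2)
    fa = np.where(norm2 == 0, 0.0, fa)
    return np.clip(fa, 0.0, 1.0)


def principal_direction(t: np.ndarray, tie_tol: float = 1e-10) -> np.ndarray:
    """Unit eigenvector of the largest eigenvalue, ``(..., 3)``.

    The eigenvector sign is physically arbitrary (fiber orientation is axial);
    for reproducibility the first component exceeding 1e-12 in magnitude is
    made positive.  Near-degenerate lambda1 ~ lambda2 triggers a warning and a
    deterministic tie-break (the eigenvector index returned by the solver).
    """
    m = np.asarray(t, dtype=float)
    _check_finite(m)
    lam, q = np.linalg.eigh(m)
    v = q[..., -1]  # largest eigenvalue last in ascending order
    gap = lam[..., -1] - lam[..., -2]
    scale = np.maximum(np.abs(lam[..., -1]), 1e-300)
    if np.any(gap <= tie_tol * scale):
        warnings.warn(
            "degenerate principal direction (lambda1 ~= lambda2); "
            "deterministic tie-break applied",
            RuntimeWarning,
            stacklevel=2,
        )
    # sign convention: first component with |v_i| > 1e-12 made positive
    big = np.abs(v) > 1e-12
    first = np.argmax(big, axis=-1)
    lead = np.take_along_axis(v, first[..., None], axis=-1)[..., 0]
    sign = np.where(lead < 0, -1.0, 1.0)
    return v * sign[..., None]


@dataclass
class TensorField:
    """A spatial grid of diffusion tensors.

    Attributes
    ----------
    data:
        ``(*spatial, 6)`` lower-triangular components, ``spatial`` 1-, 2- or
        3-dimensional.
    mask:
        Boolean foreground mask with shape ``spatial``; ``None`` means all
        voxels are foreground.
    voxel_size:
        Physical voxel edge lengths in mm, one per spatial axis.
    """

    data: np.ndarray
    mask: np.ndarray | None = None
    voxel_size: tuple[float, ...] = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim < 2 or self.data.shape[-1] != 6:
            raise ValueError("TensorField data must have shape (*spatial, 6)")
        if self.mask is None:
            self.mask = np.ones(self.data.shape[:-1], dtype=bool)
        else:
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.mask.shape != self.data.shape[:-1]:
                raise ValueError(
                    f"mask shape {self.mask.shape} does not match "
                    f"spatial shape {self.data.shape[:-1]}"
                )
        if self.voxel_size is None:
            self.voxel_size = (1.0,) * self.ndim
        else:
            self.voxel_size = tuple(float(v) for v in self.voxel_size)
            if len(self.voxel_size) != self.ndim:
                raise ValueError("voxel_size length must match spatial ndim")

    @property
    def spatial_shape(self) -> tuple[int, ...]:
        return self.data.shape[:-1]

    @property
    def ndim(self) -> int:
        return self.data.ndim - 1

    def matrices(self) -> np.ndarray:
        """Full ``(*spatial, 3, 3)`` symmetric matrices."""
        return from_lower_triangular(self.data)

    def spd_mask(self) -> np.ndarray:
        """Boolean map of voxels holding strictly positive-definite tensors."""
        return is_spd(self.matrices())

    def validate(self) -> None:
        """Raise if any masked voxel is non-finite or not strictly SPD."""
        _check_finite(self.data[self.mask])
        ok = is_spd(from_lower_triangular(self.data[self.mask]))
        if not np.all(ok):
            bad = np.argwhere(self.mask)[~ok]
            voxel = tuple(int(i) for i in bad[0])
            raise ValueError(f"non-SPD tensor at masked voxel {voxel}")

    def with_data(self, data: np.ndarray) -> "TensorField":
        """New field with the same mask/geometry and replaced components."""
        return TensorField(data=data, mask=self.mask.copy(), voxel_size=self.voxel_size)

    def copy(self) -> "TensorField":
        return TensorField(
            data=self.data.copy(), mask=self.mask.copy(), voxel_size=self.voxel_size
        )
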