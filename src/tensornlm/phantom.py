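"""Synthetic sinusoid-fiber DTI phantom.

A single-slice tensor field containing one curved fiber bundle whose
centerline follows ``y = cy + A sin(2 pi x / T)``.  Inside the bundle each
voxel holds an axially symmetric (prolate) tensor with its principal axis
along the local curve tangent and prescribed trace and fractional
anisotropy; outside, the background is isotropic with the same trace.  The
fiber/background boundary is sharp (no partial-volume voxels), so edge
preservation of a denoiser is directly measurable.

Default diffusivities mimic normal brain parenchyma: trace 2.1e-5 cm^2/sec
and FA 0.8 in the bundle.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .tensors import TensorField

__all__ = ["PhantomSpec", "Phantom", "axially_symmetric_eigenvalues", "generate_phantom"]


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry and diffusivity parameters of the sinusoid phantom.

    ``shape`` is the (x, y) grid in voxels; the sinusoid runs along the first
    axis.  ``seed`` is recorded for provenance; the construction itself is
    deterministic.
    """

    shape: tuple[int, int] = (64, 64)
    amplitude: float = 12.0  # voxels
    period: float = 48.0  # voxels
    half_width: float = 3.0  # voxels, perpendicular to the centerline
    trace: float = 2.1e-5  # cm^2/sec
    fa: float = 0.8
    background_trace: float = 2.1e-5
    background_fa: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.fa < 1.0) or not (0.0 <= self.background_fa < 1.0):
            raise ValueError("fa must lie in [0, 1)")
        if self.trace <= 0 or self.background_trace <= 0:
            raise ValueError("traces must be positive")
        if self.amplitude + self.half_width >= self.shape[1] / 2:
            raise ValueError("fiber bundle does not fit inside the grid")


@dataclass
class Phantom:
    """Generated phantom: tensor field, fiber mask, and ground-truth PD map."""

    field: TensorField
    fiber_mask: np.ndarray  # bool, spatial
    pd: np.ndarray  # (*spatial, 3); zero vectors outside the fiber
    spec: PhantomSpec


def axially_symmetric_eigenvalues(trace: float, fa: float) -> tuple[float, float, float]:
    """Eigenvalues (l1, l2, l2) of a prolate tensor with given trace and FA.

    With the two minor eigenvalues equal, the FA constraint reduces to a
    quadratic in the ratio r = l1/l2:

        FA = (r - 1) / sqrt(r^2 + 2)  =>  r = (1 + sqrt(1 - (1-F^2)(1-2F^2))) / (1 - F^2)

    which is feasible for any FA in [0, 1).
    """
    if not 0.0 <= fa < 1.0:
        raise ValueError("fa must lie in [0, 1)")
    if trace <= 0:
        raise ValueError("trace must be positive")
    f2 = fa * fa
    r = (1.0 + np.sqrt(1.0 - (1.0 - f2) * (1.0 - 2.0 * f2))) / (1.0 - f2)
    lam2 = trace / (r + 2.0)
    lam1 = r * lam2
    return (lam1, lam2, lam2)


def _prolate_tensor(tangent: np.ndarray, lam1: float, lam2: float) -> np.ndarray:
    """Tensor l1 t t^T + l2 (I - t t^T) for unit tangent(s) t, batched."""
    t = np.asarray(tangent, dtype=float)
    outer = t[..., :, None] * t[..., None, :]
    eye = np.eye(3)
    return lam1 * outer + lam2 * (eye - outer)


def generate_phantom(spec: PhantomSpec | None = None) -> Phantom:
    """Build the sinusoid phantom (deterministic for a given spec).

    Fiber membership uses the perpendicular distance from the voxel center to
    the densely sampled centerline, giving a bundle of constant width; the
    principal direction at a fiber voxel is the curve tangent at its nearest
    centerline point, with the sign convention of
    :func:`tensornlm.tensors.principal_direction`.
    """
    spec = spec or PhantomSpec()
    nx, ny = spec.shape
    cy = (ny - 1) / 2.0
    omega = 2.0 * np.pi / spec.period

    # dense centerline samples (exact eighth-voxel steps) with tangents
    xs = np.arange(-8, 8 * nx + 9) / 8.0
    ys = cy + spec.amplitude * np.sin(omega * xs)
    slopes = spec.amplitude * omega * np.cos(omega * xs)
    curve = np.stack([xs, ys], axis=1)

    xi, yi = np.meshgrid(np.arange(nx), np.arange(ny), indexing="ij")
    pts = np.stack([xi.ravel(), yi.ravel()], axis=1).astype(float)
    from scipy.spatial import cKDTree

    dist, nearest = cKDTree(curve).query(pts)
    fiber = (dist <= spec.half_width).reshape(nx, ny)

    slope = slopes[nearest].reshape(nx, ny)
    tangent = np.stack(
        [np.ones_like(slope), slope, np.zeros_like(slope)], axis=-1
    )
    tangent /= np.linalg.norm(tangent, axis=-1, keepdims=True)
    # sign convention: first nonzero component positive (t_x = 1 > 0 already)

    l1, l2, _ = axially_symmetric_eigenvalues(spec.trace, spec.fa)
    bl1, bl2, _ = axially_symmetric_eigenvalues(spec.background_trace, spec.background_fa)

    mats = np.empty((nx, ny, 3, 3))
    mats[...] = _prolate_tensor(np.array([1.0, 0.0, 0.0]), bl1, bl2)
    mats[fiber] = _prolate_tensor(tangent[fiber], l1, l2)

    pd = np.zeros((nx, ny, 3))
    pd[fiber] = tangent[fiber]

    from .tensors import to_lower_triangular

    field = TensorField(
        data=to_lower_triangular(mats),
        mask=np.ones((nx, ny), dtype=bool),
        voxel_size=(1.0, 1.0),
    )
    return Phantom(field=field, fiber_mask=fiber, pd=pd, spec=spec)
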