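"""Bridge between tensor space and diffusion-weighted image (DWI) space.

Covers the forward model (Stejskal-Tanner signal simulation), magnitude-image
Rician noise, linear least-squares tensor estimation, and the unbiased
non-local means baseline applied per DWI direction.

Unit convention: b-values are given in sec/mm^2 (the acquisition convention);
tensor diffusivities may be in cm^2/sec (``tensor_unit="cm2/s"``, the phantom
default; 1 cm^2 = 100 mm^2) or mm^2/sec.  The conversion is applied
internally so that the exponent ``b g^T D g`` is dimensionless.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .tensors import TensorField

__all__ = [
    "GradientTable",
    "DWISet",
    "electrostatic_directions",
    "default_gradient_table",
    "simulate_dwi",
    "add_rician_noise",
    "fit_tensor_lls",
    "unlm_dwi",
]

_UNIT_SCALE = {"cm2/s": 100.0, "mm2/s": 1.0}  # multiply b [s/mm^2] to match D


@dataclass(frozen=True)
class GradientTable:
    """Diffusion-encoding scheme: unit directions, b-values, baseline count.

    ``bvecs`` holds only the diffusion-weighted directions (b > 0); ``n_b0``
    counts the separate unweighted (b = 0) baseline volumes.
    """

    bvals: np.ndarray  # (N,) sec/mm^2
    bvecs: np.ndarray  # (N, 3) unit vectors
    n_b0: int = 1

    def __post_init__(self) -> None:
        object.__setattr__(self, "bvals", np.asarray(self.bvals, dtype=float))
        object.__setattr__(self, "bvecs", np.asarray(self.bvecs, dtype=float))
        if self.bvecs.shape != (self.bvals.shape[0], 3):
            raise ValueError("bvecs must have shape (len(bvals), 3)")
        if np.any(self.bvals < 0):
            raise ValueError("negative b-value")
        norms = np.linalg.norm(self.bvecs, axis=1)
        if np.any(np.abs(norms - 1.0) > 1e-8):
            raise ValueError("gradient directions must be unit norm (1e-8)")
        if self.n_b0 < 0:
            raise ValueError("n_b0 must be >= 0")

    @property
    def n_directions(self) -> int:
        return len(self.bvals)

    def design_matrix(self, unit_scale: float = 1.0) -> np.ndarray:
        """Rows [1, -b*(gx^2, 2 gx gy, gy^2, 2 gx gz, 2 gy gz, gz^2)].

        The leading column estimates ln(S0); b0 rows are included first.  The
        column order of the tensor block matches the package's
        lower-triangular component order.  Raises if the matrix is
        rank-deficient (fewer than 6 non-collinear directions + baseline).
        """
        g = self.bvecs
        quad = np.stack(
            [
                g[:, 0] ** 2,
                2 * g[:, 0] * g[:, 1],
                g[:, 1] ** 2,
                2 * g[:, 0] * g[:, 2],
                2 * g[:, 1] * g[:, 2],
                g[:, 2] ** 2,
            ],
            axis=1,
        )
        b = (self.bvals * unit_scale)[:, None]
        dwi_rows = np.hstack([np.ones((self.n_directions, 1)), -b * quad])
        b0_rows = np.zeros((self.n_b0, 7))
        b0_rows[:, 0] = 1.0
        x = np.vstack([b0_rows, dwi_rows])
        if np.linalg.matrix_rank(x) < 7:
            raise ValueError(
                "rank-deficient design matrix: need >= 6 non-collinear "
                "directions plus a baseline volume"
            )
        return x


@dataclass
class DWISet:
    """Baseline and diffusion-weighted signal volumes on a common grid.

    ``b0`` stacks the baseline volumes along the last axis, ``dwi`` one
    volume per gradient direction, aligned with ``gtab.bvecs``.
    """

    b0: np.ndarray  # (*spatial, n_b0)
    dwi: np.ndarray  # (*spatial, N)
    gtab: GradientTable
    sigma: float | None = None

    def __post_init__(self) -> None:
        self.b0 = np.asarray(self.b0, dtype=float)
        self.dwi = np.asarray(self.dwi, dtype=float)
        if self.b0.shape[:-1] != self.dwi.shape[:-1]:
            raise ValueError("b0 and dwi volumes must share the spatial grid")
        if self.b0.shape[-1] != self.gtab.n_b0:
            raise ValueError("b0 volume count does not match gtab.n_b0")
        if self.dwi.shape[-1] != self.gtab.n_directions:
            raise ValueError("dwi volume count does not match the gradient table")

    @property
    def spatial_shape(self) -> tuple[int, ...]:
        return self.dwi.shape[:-1]

    def volumes(self) -> np.ndarray:
        """All volumes stacked, baselines first: ``(*spatial, n_b0 + N)``."""
        return np.concatenate([self.b0, self.dwi], axis=-1)

    def copy(self) -> "DWISet":
        return DWISet(self.b0.copy(), self.dwi.copy(), self.gtab, self.sigma)


def electrostatic_directions(n: int, seed: int = 0, n_iter: int = 2000) -> np.ndarray:
    """Deterministic set of ``n`` well-spread unit vectors on the half-sphere.

    Minimises an antipodally symmetric Coulomb energy by projected gradient
    descent from a seeded random start; suitable as a non-collinear
    diffusion-encoding scheme when the acquired set is unknown.
    """
    rng = np.random.default_rng(seed)
    x = rng.normal(size=(n, 3))
    x /= np.linalg.norm(x, axis=1, keepdims=True)
    step = 0.005
    for _ in range(n_iter):
        force = np.zeros_like(x)
        for sign in (1.0, -1.0):
            diff = x[:, None, :] - sign * x[None, :, :]  # (n, n, 3)
            dist2 = np.sum(diff**2, axis=-1)
            np.fill_diagonal(dist2, np.inf)
            dist2 = np.maximum(dist2, 1e-12)
            force += np.sum(diff / dist2[..., None] ** 1.5, axis=1)
        x = x + step * force
        x /= np.linalg.norm(x, axis=1, keepdims=True)
    # canonical hemisphere and order for reproducibility
    flip = x[:, 2] < 0
    x[flip] *= -1
    order = np.lexsort((x[:, 1], x[:, 0], x[:, 2]))
    return x[order]


def default_gradient_table(b: float = 1000.0, n_b0: int = 1) -> GradientTable:
    """The packaged 32-direction scheme at the given b-value (sec/mm^2)."""
    from importlib.resources import files

    from .io import parse_gradients

    bval_text = files("tensornlm.data").joinpath("dirs32.bval").read_text()
    bvec_text = files("tensornlm.data").joinpath("dirs32.bvec").read_text()
    gtab = parse_gradients(bval_text, bvec_text)
    return GradientTable(
        bvals=np.full(gtab.n_directions, float(b)), bvecs=gtab.bvecs, n_b0=n_b0
    )


def simulate_dwi(
    field: TensorField,
    gtab: GradientTable,
    s0: float = 1.0,
    tensor_unit: str = "cm2/s",
) -> DWISet:
    """Noise-free Stejskal-Tanner signals ``a_i = S0 exp(-b g_i^T D g_i)``.

    Voxels outside the field mask receive the baseline signal ``s0`` (as if
    diffusion-free).
    """
    if s0 <= 0:
        raise ValueError("s0 must be positive")
    scale = _UNIT_SCALE[tensor_unit]
    mats = field.matrices()
    g = gtab.bvecs
    adc = np.einsum("ik,...kl,il->...i", g, mats, g)  # (*spatial, N)
    atten = np.exp(-(gtab.bvals * scale) * adc)
    dwi = s0 * atten
    dwi[~field.mask] = s0
    b0 = np.full(field.spatial_shape + (gtab.n_b0,), float(s0))
    return DWISet(b0=b0, dwi=dwi, gtab=gtab, sigma=0.0)


def add_rician_noise(dwi: DWISet, sigma: float, seed: int | None = None) -> DWISet:
    """Corrupt magnitudes with Rician noise: s = sqrt((a + x)^2 + y^2).

    ``x`` and ``y`` are independent zero-mean Gaussians with standard
    deviation ``sigma`` (in signal units, so sigma = 0.05 with S0 = 1 is 5%
    noise).  ``sigma = 0`` returns an exact copy.
    """
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    out = dwi.copy()
    out.sigma = float(sigma)
    if sigma == 0:
        return out
    rng = np.random.default_rng(seed)
    for arr in (out.b0, out.dwi):
        x = rng.normal(0.0, sigma, size=arr.shape)
        y = rng.normal(0.0, sigma, size=arr.shape)
        arr[...] = np.sqrt((arr + x) ** 2 + y**2)
    return out


def fit_tensor_lls(
    dwi: DWISet,
    tensor_unit: str = "cm2/s",
    mask: np.ndarray | None = None,
    signal_floor: float = 1e-6,
    voxel_size: tuple[float, ...] | None = None,
) -> TensorField:
    """Per-voxel linear least-squares tensor fit.

    Solves ``ln s = ln S0 - b g^T D g`` by ordinary least squares for the six
    unique components and ln(S0) jointly.  Signals are clamped to
    ``signal_floor`` times the median baseline before the log.  Fitted
    tensors may be non-SPD under noise; they are returned as-is (use
    :meth:`tensornlm.tensors.TensorField.spd_mask` to flag them).
    """
    scale = _UNIT_SCALE[tensor_unit]
    x = dwi.gtab.design_matrix(unit_scale=scale)
    signals = dwi.volumes()
    ref = np.median(dwi.b0)
    eps = signal_floor * max(ref, np.finfo(float).tiny)
    y = np.log(np.maximum(signals, eps))
    beta = y @ np.linalg.pinv(x).T  # (*spatial, 7)
    data = beta[..., 1:]
    if mask is None:
        mask = np.ones(dwi.spatial_shape, dtype=bool)
    return TensorField(data=data, mask=mask, voxel_size=voxel_size)


def _nlm_scalar_squared(
    vol: np.ndarray,
    search_window: int,
    patch_radius: int,
    h: float,
) -> np.ndarray:
    """NLM average of ``vol**2`` with patchwise intensity weights."""
    shape = vol.shape
    radius = search_window // 2
    h2 = h * h
    patch_kernel = np.ones((2 * patch_radius + 1,) * vol.ndim) if patch_radius else None
    num = np.zeros(shape)
    z = np.zeros(shape)
    from .nlm import _offset_slices, _window_offsets  # shared slicing helpers

    for off in _window_offsets(vol.ndim, radius):
        p_sl, q_sl = _offset_slices(shape, off)
        diff2 = np.zeros(shape)
        diff2[p_sl] = (vol[p_sl] - vol[q_sl]) ** 2
        inb = np.zeros(shape, dtype=bool)
        inb[p_sl] = True
        if patch_kernel is not None:
            d2 = ndimage.convolve(np.where(inb, diff2, 0.0), patch_kernel, mode="constant")
        else:
            d2 = diff2
        w = np.where(inb, np.exp(-d2 / h2), 0.0)
        sq = np.zeros(shape)
        sq[p_sl] = vol[q_sl] ** 2
        num += w * sq
        z += w
    return num / z


def unlm_dwi(
    dwi: DWISet,
    sigma: float,
    search_window: int = 11,
    patch_radius: int = 1,
    h: float | None = None,
) -> DWISet:
    """Unbiased non-local means denoising in DWI space, per direction.

    Each baseline and direction volume is denoised independently: classical
    NLM with patch-based intensity weights is applied to the squared
    magnitudes, and the Rician noise floor is removed by the unbiased
    estimator ``sqrt(max(NLM(s^2) - 2 sigma^2, 0))``.  The default bandwidth
    is ``h = 1.2 sigma sqrt(P)`` with ``P`` the patch voxel count, applied to
    patch-summed squared differences.  ``sigma = 0`` returns a copy.
    """
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    if search_window < 3 or search_window % 2 == 0:
        raise ValueError("search_window must be odd and >= 3")
    out = dwi.copy()
    if sigma == 0:
        return out
    ndim = len(dwi.spatial_shape)
    if h is None:
        patch_size = (2 * patch_radius + 1) ** ndim
        h = 1.2 * sigma * np.sqrt(patch_size)
    for arr in (out.b0, out.dwi):
        for k in range(arr.shape[-1]):
            sq = _nlm_scalar_squared(arr[..., k], search_window, patch_radius, h)
            arr[..., k] = np.sqrt(np.maximum(sq - 2.0 * sigma**2, 0.0))
    return out
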