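"""Similarity metrics between diffusion tensors.

Three distances between SPD matrices, all vectorised over leading axes:

* ``euclidean_distance`` — Frobenius norm of the matrix difference.  Defined
  on all symmetric matrices (positive-definiteness not required) and
  rotation-invariant, but it admits non-positive tensors and exhibits the
  swelling effect under averaging.
* ``riemannian_distance`` — the affine-invariant geodesic distance
  sqrt(sum_i ln^2 lambda_i) with lambda_i the eigenvalues of ``a^-1 b``;
  invariant under any congruence ``X -> G X G^T`` with invertible ``G``.
* ``log_euclidean_distance`` — Frobenius norm of ``log(a) - log(b)``; a fast
  proxy for the Riemannian distance that agrees with it exactly whenever the
  two tensors commute.

``a^-1 b`` is not symmetric; its eigenvalues are computed from the similar
symmetric matrix ``a^-1/2 b a^-1/2`` for numerical stability (the two share
eigenvalues, which are real and positive for SPD inputs).
"""

from __future__ import annotations

from enum import Enum

import numpy as np

from .tensors import _check_finite, _check_symmetric, invsqrt_spd, log_spd

__all__ = [
    "MetricKind",
    "euclidean_distance",
    "riemannian_distance",
    "log_euclidean_distance",
    "tensor_distance",
]


class MetricKind(str, Enum):
    """Which tensor similarity measure weights the non-local average."""

    euclidean = "euclidean"
    riemannian = "riemannian"
    log_euclidean = "log_euclidean"


def _frobenius(m: np.ndarray) -> np.ndarray:
    return np.sqrt(np.sum(m**2, axis=(-2, -1)))


def euclidean_distance(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Frobenius norm of the full-matrix difference (off-diagonals counted twice)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    _check_finite(a), _check_finite(b)
    _check_symmetric(a), _check_symmetric(b)
    return _frobenius(a - b)


def riemannian_distance(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Affine-invariant distance sqrt(sum ln^2 lambda_i(a^-1 b)).

    Raises on non-SPD input; this metric is defined only on the positive
    definite cone.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    _check_finite(a), _check_finite(b)
    a_isqrt = invsqrt_spd(a)  # raises if a is not SPD
    w = a_isqrt @ b @ a_isqrt
    w = 0.5 * (w + np.swapaxes(w, -1, -2))
    lam = np.linalg.eigvalsh(w)
    if np.any(lam <= 0):
        raise ValueError("riemannian_distance requires positive definite inputs")
    return np.sqrt(np.sum(np.log(lam) ** 2, axis=-1))


def log_euclidean_distance(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Frobenius norm of log(a) - log(b); raises on non-SPD input."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    return _frobenius(log_spd(a) - log_spd(b))


_DISPATCH = {
    MetricKind.euclidean: euclidean_distance,
    MetricKind.riemannian: riemannian_distance,
    MetricKind.log_euclidean: log_euclidean_distance,
}


def tensor_distance(a: np.ndarray, b: np.ndarray, metric: MetricKind | str) -> np.ndarray:
    """Dispatch to the selected metric."""
    return _DISPATCH[MetricKind(metric)](a, b)
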