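import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(20240615)


@pytest.fixture
def random_spd(rng):
    """Factory for random SPD matrices: A A^T + eps*I, optionally rescaled."""

    def _make(n=None, scale=1.0, eps=0.1):
        shape = (3, 3) if n is None else (int(n), 3, 3)
        a = rng.normal(size=shape)
        m = a @ np.swapaxes(a, -1, -2) + eps * np.eye(3)
        return m * scale

    return _make


@pytest.fixture
def random_rotation(rng):
    """Factory for random proper rotation matrices via QR."""

    def _make(n=None):
        shape = (3, 3) if n is None else (int(n), 3, 3)
        a = rng.normal(size=shape)
        q, r = np.linalg.qr(a)
        d = np.sign(np.diagonal(r, axis1=-2, axis2=-1))
        q = q * d[..., None, :]
        det = np.linalg.det(q)
        q[..., :, 0] *= np.where(det < 0, -1.0, 1.0)[..., None]
        return q

    return _make


@pytest.fixture
def small_phantom():
    """A compact sinusoid phantom for fast end-to-end tests."""
    from tensornlm.phantom import PhantomSpec, generate_phantom

    return generate_phantom(
        PhantomSpec(shape=(32, 32), amplitude=6.0, period=24.0, half_width=2.0)
    )
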