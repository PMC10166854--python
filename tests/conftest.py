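import numpy as np
import pytest

from tractlesion import BundleSpec, gen_bundle


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def helix():
    """100-point noisy helix streamline."""
    t = np.linspace(0, 4 * np.pi, 100)
    pts = np.column_stack([10 * np.cos(t), 10 * np.sin(t), 2 * t])
    pts += np.random.default_rng(7).normal(0, 0.05, pts.shape)
    return pts


@pytest.fixture
def three_bundle():
    """Synthetic tract of three sub-bundles offset -6/0/+6 mm along +y."""
    spec = BundleSpec(n_streamlines=300, jitter_sd=0.8, seed=42)
    return gen_bundle(spec)


def rigid_transform(angle=0.4, axis=(0.2, 0.5, 0.8), shift=(5.0, -3.0, 2.0)):
    """A rotation + translation 4x4 affine (helper for isometry tests)."""
    ax = np.asarray(axis, dtype=float)
    ax /= np.linalg.norm(ax)
    K = np.array([[0, -ax[2], ax[1]], [ax[2], 0, -ax[0]], [-ax[1], ax[0], 0]])
    R = np.eye(3) + np.sin(angle) * K + (1 - np.cos(angle)) * (K @ K)
    A = np.eye(4)
    A[:3, :3] = R
    A[:3, 3] = shift
    return A
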