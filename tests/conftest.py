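import numpy as np
import pytest
from scipy.ndimage import gaussian_filter

from poseface import gabor, geometry, synthetic
from poseface.ensemble import LabeledDataset


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def texture_field():
    """Smooth high-contrast random texture large enough to cut shifted crops."""
    rng = np.random.default_rng(7)
    base = gaussian_filter(rng.random((160, 160)), 1.2)
    base = (base - base.min()) / (base.max() - base.min())
    return base


@pytest.fixture(scope="session")
def default_bank():
    return gabor.make_bank()


@pytest.fixture(scope="session")
def small_bank():
    """Reduced bank (short kernels) for brute-force-oracle comparisons."""
    cfg = gabor.BankConfig(scales=(4.0, 8.0), downsample=2)
    return gabor.make_bank(cfg)


@pytest.fixture(scope="session")
def head_setup():
    """Ellipsoid + anchors + camera matching the synthetic renderer."""
    ell = geometry.Ellipsoid()
    anchors = geometry.default_anchors(ell)
    cam = geometry.Camera(scale=48.0, cx=64.0, cy=64.0)
    return ell, anchors, cam


@pytest.fixture
def separable_blobs():
    """Linearly separable 2-class dataset with subject ids."""
    X, y, subj = synthetic.make_classification_data(
        n_per_class=20, dim=2, separation=5.0, noise=1.0, n_classes=2, seed=42
    )
    return LabeledDataset(X, np.where(y == 1, 1, -1), subj)


@pytest.fixture(scope="session")
def rendered_scene():
    """One rendered sequence with ground truth (slow-ish; shared)."""
    scene = synthetic.expression_scene(
        expression_class=0, subject=0, n_frames=5,
        yaw_max=np.deg2rad(6.0), deformation_amplitude=0.5, seed=11,
    )
    frames, truth = synthetic.render_sequence(scene)
    return scene, frames, truth
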