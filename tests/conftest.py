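import numpy as np
import pytest

from fetalbiom.imaging_io import LabelMask
from fetalbiom.phantom import PhantomSpec, generate_af_loop, generate_biometry_loop
from fetalbiom.segmentation import PhantomBackend


def ellipse_points(a, b, theta_deg, cr, cc, n=100, noise_sd=0.0, rng=None):
    """Parametric (row, col) samples of an ellipse; the generator is the
    oracle for the direct least-squares fit."""
    t = np.linspace(0.0, 2.0 * np.pi, n, endpoint=False)
    th = np.radians(theta_deg)
    x = a * np.cos(t)
    y = b * np.sin(t)
    col = cc + x * np.cos(th) - y * np.sin(th)
    row = cr + x * np.sin(th) + y * np.cos(th)
    pts = np.column_stack([row, col])
    if noise_sd > 0:
        pts = pts + rng.normal(0.0, noise_sd, size=pts.shape)
    return pts


def random_blob(rng, shape=(64, 64)):
    """A random connected-ish blob mask (union of a few discs)."""
    grid = np.zeros(shape, dtype=bool)
    rows, cols = np.mgrid[0 : shape[0], 0 : shape[1]]
    for _ in range(rng.integers(1, 4)):
        cr = rng.uniform(10, shape[0] - 10)
        cc = rng.uniform(10, shape[1] - 10)
        r = rng.uniform(3, 9)
        grid |= (rows - cr) ** 2 + (cols - cc) ** 2 <= r * r
    return LabelMask(grid, "af_pocket")


@pytest.fixture(scope="session")
def cephalic_case():
    spec = PhantomSpec(kind="cephalic", seed=11)
    loop, labels, truth = generate_biometry_loop(spec)
    backend = PhantomBackend(labels, truth.flags, truth.confidences)
    return loop, labels, truth, backend


@pytest.fixture(scope="session")
def abdominal_case():
    spec = PhantomSpec(kind="abdominal", seed=12)
    loop, labels, truth = generate_biometry_loop(spec)
    backend = PhantomBackend(labels, truth.flags, truth.confidences)
    return loop, labels, truth, backend


@pytest.fixture(scope="session")
def femoral_case():
    spec = PhantomSpec(kind="femoral", seed=13)
    loop, labels, truth = generate_biometry_loop(spec)
    backend = PhantomBackend(labels, truth.flags, truth.confidences)
    return loop, labels, truth, backend


@pytest.fixture(scope="session")
def amniotic_case():
    spec = PhantomSpec(kind="amniotic", seed=14)
    loop, labels, truth = generate_af_loop(spec)
    backend = PhantomBackend(labels, truth.flags, truth.confidences)
    return loop, labels, truth, backend
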