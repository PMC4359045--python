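import numpy as np
import pytest
from scipy.spatial import cKDTree

from wingbone import canals, synthetic


@pytest.fixture(scope="session")
def recovery_run():
    """One end-to-end synthetic canal-field analysis, shared across tests.

    Generates a field with known class labels at the emulated histology
    resolution (2.1 µm/px), rasterizes it, runs the image-analysis path,
    and matches measured canals back to truth by nearest centroid.
    """
    spec = synthetic.SyntheticCanalFieldSpec(n_canals=150, seed=7)
    fld = synthetic.generate_canal_field(spec)
    img = synthetic.render_canal_field(fld)
    measured = canals.analyze_canal_image(img, fld.contour, fld.pixel_scale)
    tree = cKDTree(fld.canals[["x_um", "y_um"]].to_numpy())
    dist, idx = tree.query(measured[["x_um", "y_um"]].to_numpy())
    truth = fld.canals.true_class.to_numpy()[idx]
    return fld, measured, truth, dist


@pytest.fixture(scope="session")
def bm_tree_64():
    """Fixed 64-tip unit-depth Yule tree with its BM covariance."""
    from wingbone import scaling

    tree = synthetic.simulate_pure_birth_tree(64, seed=21)
    labels = [f"s{i}" for i in range(1, 65)]
    _, v = scaling.vcv_brownian(tree, order=labels)
    chol = np.linalg.cholesky(v + 1e-12 * np.eye(64))
    return tree, labels, v, chol
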