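import numpy as np
import pytest

import traffickit as tk


@pytest.fixture(scope="session")
def disk_mask():
    """Unperturbed 10-px-radius disk in a 64x64 frame."""
    return tk.make_cell_mask((64, 64), (32, 32), 10, 0.0, seed=1)


@pytest.fixture(scope="session")
def small_field():
    """Noise-free 3-cell field, membrane 300 / cytoplasm 100 / background 50."""
    spec = tk.FieldSpec(
        image_shape=(256, 256),
        n_cells=3,
        poisson_noise=False,
        gaussian_noise_sd=0.0,
        seed=11,
    )
    truths = tk.random_truths(spec, membrane_intensity=300.0, cytoplasm_intensity=100.0)
    field, truths = tk.render_field(spec, truths)
    return spec, field, truths


@pytest.fixture(scope="session")
def noisefree_bret_spec():
    return tk.BretSimSpec(noise_sd=0.0, well_offset_sd=0.0, baseline_drift_per_s=0.0, seed=5)


def signed_chebyshev_index(mask):
    """Independent oracle: per-pixel signed band index from the chessboard
    distance transform (inside: distance-to-background − 1; outside:
    −distance-to-mask)."""
    from scipy.ndimage import distance_transform_cdt

    inside = distance_transform_cdt(mask, metric="chessboard")
    outside = distance_transform_cdt(~mask, metric="chessboard")
    return np.where(mask, inside - 1, -outside)
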