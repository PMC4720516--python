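"""Shared fixtures: small synthetic discs and rendered image fixtures."""

import numpy as np
import pandas as pd
import pytest

from furrow.core import DiscSample
from furrow.synthetic import SyntheticConfig, generate_disc, render_image


@pytest.fixture(scope="session")
def default_disc():
    """One modest disc with the default (study-condition) parameters."""
    cfg = SyntheticConfig(seed=11, n_columns=10, rows_per_column=5)
    sample, truth = generate_disc(cfg)
    return cfg, sample, truth


@pytest.fixture(scope="session")
def quiet_disc():
    """Noise-free, jitter-free disc with no bleed: levels sit on the curve."""
    cfg = SyntheticConfig(
        seed=7,
        n_columns=8,
        rows_per_column=4,
        baseline_cv=0.0,
        noise_spikes={},
        bleed_fraction=0.0,
        lattice_jitter_px=0.0,
        rfp_cv=0.0,
        nuclear_size_cv=0.0,
    )
    sample, truth = generate_disc(cfg)
    return cfg, sample, truth


@pytest.fixture(scope="session")
def sparse_grid_sample():
    """64 well-separated nuclei on a jittered grid (for segmentation)."""
    rng = np.random.default_rng(0)
    rows = []
    cid = 0
    for i in range(8):
        for j in range(8):
            rows.append(
                dict(
                    disc_id="fixture",
                    cell_id=cid,
                    x_px=20 + 22 * i + rng.uniform(-2, 2),
                    y_px=20 + 22 * j + rng.uniform(-2, 2),
                    section=0,
                    cell_type="progenitor",
                    yfp_mean=rng.uniform(60, 200),
                    rfp_mean=rng.uniform(80, 150),
                    nuclear_size_px=110.0,
                )
            )
            cid += 1
    return DiscSample("fixture", pd.DataFrame(rows))


@pytest.fixture(scope="session")
def sparse_grid_rendered(sparse_grid_sample):
    img, mask, origin = render_image(
        sparse_grid_sample, psf_sigma=1.0, background=2.0, seed=1, return_origin=True
    )
    return sparse_grid_sample, img, mask, origin
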