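import numpy as np
import pytest
from hypothesis import settings

import retinotex as rt

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def small_spec() -> rt.PhantomSpec:
    """A reduced-geometry phantom eye spec shared across tests.

    128 columns over 6 mm and 512 axial pixels at 2 μm keep generation fast
    while preserving the layer anatomy, pit, texture, speckle and shadows.
    Shadow columns are placed in the parafoveal/perifoveal range.
    """
    return rt.PhantomSpec(
        n_columns=128,
        n_rows=512,
        shadow_columns=(24, 25, 26, 96, 97, 98, 99),
        seed=7,
    )


@pytest.fixture(scope="session")
def phantom_eye(small_spec):
    return rt.generate_phantom_eye(small_spec)


@pytest.fixture(scope="session")
def preprocessed_eye(phantom_eye):
    scan_set, _ = phantom_eye
    return rt.preprocess_scan_set(scan_set)


def random_scan_with_layers(
    rng: np.random.Generator, n_rows: int = 48, n_cols: int = 24
) -> tuple[rt.BScan, rt.LayerSegmentation]:
    """A random reflectivity matrix with random monotone layer boundaries."""
    img = rng.uniform(0.05, 1.5, size=(n_rows, n_cols))
    ilm = rng.uniform(1, 4, size=n_cols)
    heights = rng.uniform(1.0, (n_rows - 8) / 7.0, size=(7, n_cols))
    boundaries = np.vstack([ilm, ilm + np.cumsum(heights, axis=0)])
    scan = rt.BScan(
        reflectivity=img,
        axial_spacing_um=2.0,
        lateral_extent_mm=6.0,
        fovea_column=n_cols // 2,
        eye_id="rand",
        subject_id="rand",
        group_label="H",
    )
    return scan, rt.LayerSegmentation(boundaries)
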