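import numpy as np
import pytest

from autoquant.scene_sim import (
    SceneParams,
    generate_lysosome_scene,
    generate_tandem_scene,
)
from autoquant.segmentation import CellGeometry


@pytest.fixture(scope="session")
def disk_geometry() -> CellGeometry:
    """Disk cell of radius 100 px with a centered nucleus."""
    rr, cc = np.mgrid[0:220, 0:220]
    d2 = (rr - 110) ** 2 + (cc - 110) ** 2
    return CellGeometry(
        cell_mask=d2 <= 100**2,
        nucleus_mask=d2 <= 30**2,
        nucleus_centroid=(110.0, 110.0),
        pixel_size=0.05,
    )


@pytest.fixture(scope="session")
def clean_lysosome_scene():
    """Noise-free lysosome scene, uniform ring weights, 400 puncta."""
    params = SceneParams(
        seed=11,
        n_puncta=400,
        ring_weights=(0.25, 0.25, 0.25, 0.25),
        background_level=0.0,
        poisson_noise=False,
        read_noise_sigma=0.0,
    )
    return generate_lysosome_scene(params)


@pytest.fixture(scope="session")
def tandem_scene():
    """High-SNR tandem scene with 20 APG and 30 AL puncta."""
    params = SceneParams(
        seed=5,
        n_puncta=50,
        apg_fraction=0.4,
        background_level=5.0,
        poisson_noise=True,
        read_noise_sigma=1.0,
        spot_amplitude=300.0,
    )
    return generate_tandem_scene(params)


def star_geometry(seed: int, size: int = 160) -> CellGeometry:
    """Random star-shaped cell mask with a random interior nucleus centroid."""
    rng = np.random.default_rng(seed)
    params = SceneParams(
        shape=(size, size),
        cell_shape="star",
        cell_radius=0.35 * size,
        star_amplitude=0.2,
        seed=seed,
    )
    from autoquant.scene_sim import _cell_mask

    cell = _cell_mask(params, rng)
    # nucleus: disk at a random offset from the center, kept inside the cell
    c0 = (size - 1) / 2.0
    for _ in range(100):
        dr, dc = rng.uniform(-0.15 * size, 0.15 * size, size=2)
        rr, cc = np.mgrid[0:size, 0:size]
        nucleus = ((rr - c0 - dr) ** 2 + (cc - c0 - dc) ** 2) <= (0.1 * size) ** 2
        nucleus &= cell
        if nucleus.sum() > 20:
            from scipy import ndimage as ndi

            cen = ndi.center_of_mass(nucleus)
            if cell[int(round(cen[0])), int(round(cen[1]))]:
                return CellGeometry(cell, nucleus, (float(cen[0]), float(cen[1])))
    raise RuntimeError("could not place a nucleus")
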