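"""Synthetic fluorescence scenes and annotation tables with ground truth.

Every downstream stage of the pipeline is validated against the output
of this module: single cells with a nucleus, marker puncta placed with a
controllable radial bias, two-channel (red/green) tandem-reporter scenes
with a controllable autophagosome fraction, per-vacuole annotation
tables obeying the classification rule, and densitometry band tables
with known fold changes.

Puncta are rendered as isotropic 2-D Gaussians truncated at 4 sigma.
All randomness flows through one ``numpy.random.Generator`` seeded from
``SceneParams.seed`` — identical parameters give bit-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
from scipy import ndimage as ndi

from .errors import ParameterError
from .imgio import ImageStack
from .radial_rings import compute_ring_partition
from .segmentation import CellGeometry

__all__ = [
    "SceneParams",
    "SceneGroundTruth",
    "generate_lysosome_scene",
    "generate_tandem_scene",
    "generate_vacuole_table",
    "generate_band_table",
]


@dataclass
class SceneParams:
    """Parameters of a synthetic single-cell scene.

    ``ring_weights`` is the probability of placing a punctum in each of
    the four equal-area rings, ordered ring 1 (peripheral) to ring 4
    (perinuclear).  ``cell_shape`` is ``disk``, ``ellipse`` or ``star``
    (radius modulated by random low-order harmonics).
    """

    shape: tuple[int, int] = (256, 256)
    pixel_size: float = 0.05  # µm/px, matches a 50 nm lateral voxel
    cell_shape: str = "disk"
    cell_radius: float = 100.0
    ellipse_ratio: float = 0.7
    star_harmonics: int = 3
    star_amplitude: float = 0.15
    nucleus_radius_fraction: float = 0.3
    n_puncta: int = 100
    spot_sigma: float = 1.5
    spot_amplitude: float = 200.0
    ring_weights: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)
    apg_fraction: float = 0.5
    mask_amplitude: float = 150.0  # brightness of the DAPI / tracer channels
    background_level: float = 10.0
    gradient_amplitude: float = 0.0
    poisson_noise: bool = False
    read_noise_sigma: float = 0.0
    n_z: int = 1
    z_step: float = 0.5  # µm, matches the 500 nm axial voxel
    seed: int = 0

    def validate(self) -> None:
        if min(self.shape) <= 0:
            raise ParameterError(f"non-positive image shape {self.shape}")
        w = np.asarray(self.ring_weights, dtype=float)
        if w.size != 4 or (w < 0).any() or abs(w.sum() - 1.0) > 1e-9:
            raise ParameterError(
                f"ring weights must be 4 non-negative values summing to 1, got {self.ring_weights}"
            )
        if self.n_puncta < 0:
            raise ParameterError("n_puncta must be >= 0")
        if self.spot_sigma <= 0:
            raise ParameterError("spot sigma must be > 0")
        if not 0.0 <= self.apg_fraction <= 1.0:
            raise ParameterError("APG fraction must be in [0, 1]")
        if self.cell_shape not in ("disk", "ellipse", "star"):
            raise ParameterError(f"unknown cell shape {self.cell_shape!r}")


@dataclass
class SceneGroundTruth:
    """Everything the generator knows about a scene.

    ``puncta`` has one row per punctum: center, ring index it was drawn
    into, and (for tandem scenes) whether it is dual-positive (APG).
    ``ring_fractions`` are the realized per-ring intensity fractions of
    the noise-free marker signal.
    """

    cell_mask: np.ndarray
    nucleus_mask: np.ndarray
    nucleus_centroid: tuple[float, float]
    puncta: pd.DataFrame
    ring_fractions: np.ndarray
    ring_labels: np.ndarray
    params: SceneParams

    @property
    def geometry(self) -> CellGeometry:
        return CellGeometry(
            cell_mask=self.cell_mask,
            nucleus_mask=self.nucleus_mask,
            nucleus_centroid=self.nucleus_centroid,
            pixel_size=self.params.pixel_size,
        )

    def params_dict(self) -> dict:
        d = asdict(self.params)
        d["shape"] = list(d["shape"])
        d["ring_weights"] = list(d["ring_weights"])
        return d


# ---------------------------------------------------------------------------
# geometry


def _cell_mask(params: SceneParams, rng: np.random.Generator) -> np.ndarray:
    rows, cols = params.shape
    r0, c0 = (rows - 1) / 2.0, (cols - 1) / 2.0
    rr, cc = np.mgrid[0:rows, 0:cols]
    dy, dx = rr - r0, cc - c0
    theta = np.arctan2(dy, dx)
    dist = np.hypot(dy, dx)
    if params.cell_shape == "disk":
        radius = np.full_like(theta, params.cell_radius)
    elif params.cell_shape == "ellipse":
        a = params.cell_radius
        b = params.cell_radius * params.ellipse_ratio
        radius = a * b / np.sqrt((b * np.cos(theta)) ** 2 + (a * np.sin(theta)) ** 2)
    else:  # star: radius modulated by random harmonics, star-shaped about center
        radius = np.full_like(theta, 1.0)
        for m in range(2, 2 + params.star_harmonics):
            amp = params.star_amplitude * rng.uniform(0.3, 1.0) / (m - 1)
            phase = rng.uniform(0, 2 * np.pi)
            radius = radius + amp * np.cos(m * theta + phase)
        radius = params.cell_radius * radius
    return dist <= radius


def _nucleus_mask(
    params: SceneParams, cell: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    rows, cols = params.shape
    r0, c0 = (rows - 1) / 2.0, (cols - 1) / 2.0
    rr, cc = np.mgrid[0:rows, 0:cols]
    radius = params.nucleus_radius_fraction * params.cell_radius
    mask = np.hypot(rr - r0, cc - c0) <= radius
    return mask & cell


def _render_puncta(
    shape: tuple[int, int], centers: np.ndarray, sigma: float, amplitude: float
) -> np.ndarray:
    """Sum of isotropic Gaussians truncated at 4 sigma."""
    image = np.zeros(shape, dtype=float)
    half = int(np.ceil(4 * sigma))
    for r, c in centers:
        ri, ci = int(np.floor(r)), int(np.floor(c))
        r_lo, r_hi = max(ri - half, 0), min(ri + half + 2, shape[0])
        c_lo, c_hi = max(ci - half, 0), min(ci + half + 2, shape[1])
        rr, cc = np.mgrid[r_lo:r_hi, c_lo:c_hi]
        d2 = (rr - r) ** 2 + (cc - c) ** 2
        patch = amplitude * np.exp(-d2 / (2 * sigma**2))
        patch[d2 > (4 * sigma) ** 2] = 0.0
        image[r_lo:r_hi, c_lo:c_hi] += patch
    return image


def _sample_centers(
    gt_labels: np.ndarray,
    weights: np.ndarray,
    n: int,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Sample a target ring per punctum, then a uniform point in that ring."""
    ring_idx = rng.choice(4, size=n, p=weights) + 1  # 1..4
    ring_pixels = {k: np.argwhere(gt_labels == k) for k in range(1, 5)}
    centers = np.zeros((n, 2), dtype=float)
    for i, k in enumerate(ring_idx):
        pix = ring_pixels[int(k)]
        if pix.shape[0] == 0:
            raise ParameterError(f"ring {k} is empty; cannot place puncta")
        centers[i] = pix[rng.integers(pix.shape[0])]
        centers[i] += rng.uniform(-0.5, 0.5, size=2)
    return centers, ring_idx


def _add_noise_and_background(
    signal: np.ndarray, params: SceneParams, rng: np.random.Generator
) -> np.ndarray:
    rows, cols = params.shape
    image = signal + params.background_level
    if params.gradient_amplitude > 0:
        cc = np.linspace(0, 1, cols)[None, :]
        rr = np.linspace(0, 1, rows)[:, None]
        image = image + params.gradient_amplitude * (0.6 * cc + 0.4 * rr * rr)
    if params.poisson_noise:
        image = rng.poisson(np.clip(image, 0, None)).astype(float)
    if params.read_noise_sigma > 0:
        image = image + rng.normal(0, params.read_noise_sigma, size=image.shape)
    return np.clip(image, 0, None)


def _to_zstack(
    plane: np.ndarray, params: SceneParams, rng: np.random.Generator
) -> np.ndarray:
    """Spread a plane into n_z planes whose per-pixel max is the plane.

    Each pixel's full value is assigned to one random plane; the other
    planes carry an attenuated copy, so the maximum-intensity projection
    of the stack recovers the input plane exactly.
    """
    if params.n_z == 1:
        return plane[None]
    best = rng.integers(0, params.n_z, size=plane.shape)
    atten = rng.uniform(0.2, 0.8, size=(params.n_z,) + plane.shape)
    stack = plane[None] * atten
    z_idx = np.arange(params.n_z)[:, None, None]
    stack = np.where(z_idx == best[None], plane[None], stack)
    return stack


def _ring_fractions(signal: np.ndarray, gt_labels: np.ndarray) -> np.ndarray:
    sums = np.array([signal[gt_labels == k].sum() for k in range(1, 5)])
    total = sums.sum()
    if total <= 0:
        return np.full(4, np.nan)
    return sums / total


# ---------------------------------------------------------------------------
# scene generators


def _base_scene(params: SceneParams, rng: np.random.Generator):
    cell = _cell_mask(params, rng)
    nucleus = _nucleus_mask(params, cell, rng)
    centroid = ndi.center_of_mass(nucleus)
    geometry = CellGeometry(
        cell_mask=cell,
        nucleus_mask=nucleus,
        nucleus_centroid=(float(centroid[0]), float(centroid[1])),
        pixel_size=params.pixel_size,
    )
    partition = compute_ring_partition(geometry)
    return geometry, partition


def generate_lysosome_scene(
    params: SceneParams,
) -> tuple[ImageStack, SceneGroundTruth]:
    """Generate a DAPI + marker + tracer scene with ring-biased puncta.

    Marker puncta are placed by sampling a ring from ``ring_weights``
    and then a uniform position within that true equal-area ring.  The
    realized per-ring fractions of the noise-free marker signal are
    recorded in the ground truth.
    """
    params.validate()
    rng = np.random.default_rng(params.seed)
    geometry, partition = _base_scene(params, rng)
    weights = np.asarray(params.ring_weights, dtype=float)

    centers, ring_idx = _sample_centers(
        partition.labels, weights, params.n_puncta, rng
    )
    marker_signal = _render_puncta(
        params.shape, centers, params.spot_sigma, params.spot_amplitude
    )
    fractions = _ring_fractions(marker_signal, partition.labels)

    dapi = geometry.nucleus_mask * params.mask_amplitude
    tracer = geometry.cell_mask * params.mask_amplitude
    channels = []
    for plane in (dapi, marker_signal, tracer):
        noisy = _add_noise_and_background(plane, params, rng)
        channels.append(_to_zstack(noisy, params, rng))
    data = np.stack(channels)

    puncta = pd.DataFrame(
        {
            "row": centers[:, 0],
            "col": centers[:, 1],
            "ring": ring_idx,
            "channel": "marker",
        }
    )
    stack = ImageStack(
        data=data,
        channel_names=("dapi", "marker", "tracer"),
        pixel_size=params.pixel_size,
        z_step=params.z_step if params.n_z > 1 else None,
        provenance=f"scene_sim.lysosome(seed={params.seed})",
    )
    gt = SceneGroundTruth(
        cell_mask=geometry.cell_mask,
        nucleus_mask=geometry.nucleus_mask,
        nucleus_centroid=geometry.nucleus_centroid,
        puncta=puncta,
        ring_fractions=fractions,
        ring_labels=partition.labels,
        params=params,
    )
    return stack, gt


def generate_tandem_scene(
    params: SceneParams,
) -> tuple[ImageStack, SceneGroundTruth]:
    """Generate a red + green tandem-reporter scene.

    Every punctum appears in the red channel; exactly
    ``round(apg_fraction * n_puncta)`` of them (the first in sampling
    order) also appear in green at the same position, modelling
    autophagosomes whose GFP is not yet quenched.
    """
    params.validate()
    rng = np.random.default_rng(params.seed)
    geometry, partition = _base_scene(params, rng)
    weights = np.asarray(params.ring_weights, dtype=float)

    centers, ring_idx = _sample_centers(
        partition.labels, weights, params.n_puncta, rng
    )
    n_apg = int(round(params.apg_fraction * params.n_puncta))
    is_apg = np.zeros(params.n_puncta, dtype=bool)
    is_apg[:n_apg] = True

    red_signal = _render_puncta(
        params.shape, centers, params.spot_sigma, params.spot_amplitude
    )
    green_signal = _render_puncta(
        params.shape, centers[is_apg], params.spot_sigma, params.spot_amplitude
    )
    fractions = _ring_fractions(red_signal, partition.labels)

    channels = []
    for plane in (red_signal, green_signal):
        noisy = _add_noise_and_background(plane, params, rng)
        channels.append(_to_zstack(noisy, params, rng))
    data = np.stack(channels)

    puncta = pd.DataFrame(
        {
            "row": centers[:, 0],
            "col": centers[:, 1],
            "ring": ring_idx,
            "channel": np.where(is_apg, "red+green", "red"),
            "is_apg": is_apg,
        }
    )
    stack = ImageStack(
        data=data,
        channel_names=("red", "green"),
        pixel_size=params.pixel_size,
        z_step=params.z_step if params.n_z > 1 else None,
        provenance=f"scene_sim.tandem(seed={params.seed})",
    )
    gt = SceneGroundTruth(
        cell_mask=geometry.cell_mask,
        nucleus_mask=geometry.nucleus_mask,
        nucleus_centroid=geometry.nucleus_centroid,
        puncta=puncta,
        ring_fractions=fractions,
        ring_labels=partition.labels,
        params=params,
    )
    return stack, gt


# ---------------------------------------------------------------------------
# tabular generators

APG_CRITERIA = (
    "double_membrane",
    "no_attached_ribosomes",
    "luminal_density_similar_to_cytosol",
    "identifiable_organelles_in_lumen",
)
AUT_CRITERIA = (
    "single_membrane_or_lt40pct_double",
    "luminal_density_lower_than_cytosol",
    "multivesicular_amorphous_content",
)


def generate_vacuole_table(
    n: int,
    apg_mix: float = 0.5,
    sub_threshold_fraction: float = 0.0,
    size_gate: float = 0.5,
    n_cells: int = 1,
    seed: int = 0,
) -> pd.DataFrame:
    """Generate per-vacuole annotations with known true classes.

    APG rows get >= 2 true autophagosome criteria (and <= 1 would-be AUT
    criterion is irrelevant because the APG rule takes precedence); AUT
    rows get >= 1 AUT criterion and <= 1 APG criterion.  A
    ``sub_threshold_fraction`` of rows is drawn below the diameter gate.
    """
    if n < 0:
        raise ParameterError("n must be >= 0")
    if not 0.0 <= apg_mix <= 1.0:
        raise ParameterError("class mix must be in [0, 1]")
    rng = np.random.default_rng(seed)
    rows = []
    for i in range(n):
        true_class = "APG" if rng.random() < apg_mix else "AUT"
        crit = {c: False for c in APG_CRITERIA + AUT_CRITERIA}
        if true_class == "APG":
            k = int(rng.integers(2, 5))  # 2..4 criteria true
            for c in rng.choice(APG_CRITERIA, size=k, replace=False):
                crit[c] = True
        else:
            k = int(rng.integers(1, 4))
            for c in rng.choice(AUT_CRITERIA, size=k, replace=False):
                crit[c] = True
            if rng.random() < 0.3:  # at most one APG criterion allowed
                crit[str(rng.choice(APG_CRITERIA))] = True
        if rng.random() < sub_threshold_fraction:
            diameter = rng.uniform(0.5 * size_gate, 0.98 * size_gate)
            true_class = "excluded"
        else:
            diameter = rng.uniform(size_gate * 1.1, size_gate * 4.0)
        rows.append(
            {
                "vacuole": f"v{i:04d}",
                "cell": f"c{i % n_cells:03d}",
                "diameter_um": diameter,
                "area_um2": np.pi * (diameter / 2) ** 2,
                **crit,
                "true_class": true_class,
            }
        )
    columns = (
        ["vacuole", "cell", "diameter_um", "area_um2"]
        + list(APG_CRITERIA)
        + list(AUT_CRITERIA)
        + ["true_class"]
    )
    return pd.DataFrame(rows, columns=columns)


def generate_band_table(
    group_means: dict[str, float],
    n_lanes: int = 6,
    loading_mean: float = 1.0,
    noise_sigma: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Generate a densitometry band table with known true fold changes.

    Marker intensity for a lane in group g is
    ``group_means[g] * loading * exp(noise)``, so the marker/loading
    ratio is unbiased (in the median) around the group mean.
    """
    if any(m <= 0 for m in group_means.values()):
        raise ParameterError("true group means must be positive")
    if loading_mean <= 0:
        raise ParameterError("loading-control mean must be positive")
    rng = np.random.default_rng(seed)
    rows = []
    lane = 0
    for group, mean in group_means.items():
        for _ in range(n_lanes):
            loading = loading_mean * np.exp(rng.normal(0, noise_sigma / 2))
            marker = mean * loading * np.exp(rng.normal(0, noise_sigma))
            rows.append(
                {
                    "lane": f"lane{lane:03d}",
                    "group": group,
                    "marker": marker,
                    "loading": loading,
                }
            )
            lane += 1
    return pd.DataFrame(rows)
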