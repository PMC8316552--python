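"""Equal-area concentric-ring partition and radial intensity profiling.

The cell is divided into K concentric rings of equal area (default 4).
Ring boundaries are uniform scalings of the cell boundary about the
nucleus centroid: a pixel ``p`` belongs to the region scaled by ``s``
when the point ``centroid + (p - centroid) / s`` falls inside the cell
mask.  Because scaled copies of a non-convex mask about an off-center
point need not nest inside the cell, every scaled region is intersected
with the cell mask and the scale factors are solved numerically
(bisection on pixel-counted areas) so that each ring holds 1/K of the
cell area within a relative tolerance.

Ring labels run 1 = outermost (peripheral) to K = innermost
(perinuclear); 0 marks pixels outside the cell.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage as ndi

from .errors import ParameterError, PartitionError, ProfileError
from .segmentation import CellGeometry

logger = logging.getLogger(__name__)

__all__ = [
    "RingPartition",
    "RadialProfile",
    "rolling_ball_subtract",
    "compute_ring_partition",
    "ring_intensity_profile",
    "aggregate_profiles",
]

DEFAULT_N_RINGS = 4
DEFAULT_AREA_TOL = 0.02
DEFAULT_ROLLING_BALL_RADIUS = 30


@dataclass
class RingPartition:
    """Label image partitioning a cell into concentric equal-area rings.

    ``labels`` is 0 outside the cell and 1..K inside (1 = peripheral,
    K = perinuclear).  ``scales`` are the K-1 boundary scale factors in
    decreasing order; ``areas[k-1]`` is the pixel area of ring k.
    """

    labels: np.ndarray
    n_rings: int
    scales: tuple[float, ...]
    areas: np.ndarray
    area_tol: float = DEFAULT_AREA_TOL

    def ring_mask(self, k: int) -> np.ndarray:
        if not 1 <= k <= self.n_rings:
            raise ParameterError(f"ring index {k} out of range 1..{self.n_rings}")
        return self.labels == k

    def validate(self, cell_mask: np.ndarray) -> None:
        """Assert cover/disjointness and the equal-area property."""
        if ((self.labels > 0) != cell_mask).any():
            raise PartitionError("ring labels do not cover the cell mask exactly")
        total = self.areas.sum()
        target = total / self.n_rings
        worst = np.abs(self.areas - target).max() / target
        if worst > self.area_tol:
            raise PartitionError(
                f"equal-area violated: max deviation {worst:.3f} > {self.area_tol}"
            )


@dataclass
class RadialProfile:
    """Per-ring intensity measurements for a single cell.

    ``density[k]`` is intensity per pixel in ring k+1, ``norm_density``
    the density divided by the whole-cell density (uniform signal gives
    1.0 everywhere), ``fraction`` the share of total intensity.
    """

    intensity: np.ndarray
    area: np.ndarray
    density: np.ndarray
    cell_density: float
    norm_density: np.ndarray
    fraction: np.ndarray
    cell_id: str = ""
    condition: str = ""

    def to_frame(self) -> pd.DataFrame:
        k = np.arange(1, len(self.intensity) + 1)
        return pd.DataFrame(
            {
                "cell": self.cell_id,
                "condition": self.condition,
                "ring": k,
                "intensity": self.intensity,
                "area_px2": self.area,
                "density": self.density,
                "norm_density": self.norm_density,
                "fraction": self.fraction,
            }
        )


def rolling_ball_subtract(
    image: np.ndarray, radius: int = DEFAULT_ROLLING_BALL_RADIUS
) -> np.ndarray:
    """Subtract a rolling-ball background estimate (default radius 30 px).

    The background is the grayscale opening of the image by a ball of
    the given radius; the result is ``image - background`` clipped at 0.
    """
    image = np.asarray(image, dtype=float)
    if image.ndim != 2:
        raise ParameterError("rolling-ball subtraction expects a 2-D image")
    if radius < 1:
        raise ParameterError(f"rolling-ball radius must be >= 1, got {radius}")
    if radius >= min(image.shape):
        raise ParameterError(
            f"rolling-ball radius {radius} >= smallest image dimension {min(image.shape)}"
        )
    footprint, structure = _ball_structure(radius)
    background = ndi.grey_opening(image, footprint=footprint, structure=structure)
    return np.clip(image - background, 0, None)


def _ball_structure(radius: int) -> tuple[np.ndarray, np.ndarray]:
    """Footprint and height profile of a ball structuring element."""
    r = int(radius)
    yy, xx = np.mgrid[-r : r + 1, -r : r + 1]
    d2 = yy * yy + xx * xx
    footprint = d2 <= r * r
    heights = np.zeros(footprint.shape, dtype=float)
    heights[footprint] = np.sqrt(r * r - d2[footprint])
    return footprint, heights


def _scaled_region(
    cell_mask: np.ndarray, centroid: tuple[float, float], s: float
) -> np.ndarray:
    """Pixels of the cell whose pre-image under scaling by s lies in the cell.

    Membership test: p is inside the boundary scaled by s about the
    centroid iff centroid + (p - centroid)/s is inside the cell mask.
    """
    rows, cols = cell_mask.shape
    rr, cc = np.nonzero(cell_mask)
    r0, c0 = centroid
    src_r = np.rint(r0 + (rr - r0) / s).astype(int)
    src_c = np.rint(c0 + (cc - c0) / s).astype(int)
    inside = (src_r >= 0) & (src_r < rows) & (src_c >= 0) & (src_c < cols)
    member = np.zeros(rr.shape, dtype=bool)
    member[inside] = cell_mask[src_r[inside], src_c[inside]]
    out = np.zeros_like(cell_mask)
    out[rr[member], cc[member]] = True
    return out


def compute_ring_partition(
    geometry: CellGeometry,
    n_rings: int = DEFAULT_N_RINGS,
    area_tol: float = DEFAULT_AREA_TOL,
    max_iter: int = 100,
) -> RingPartition:
    """Partition the cell into ``n_rings`` concentric rings of equal area.

    Boundaries are solved innermost-out: for each cumulative target area
    k·A/K the scale ``s`` is found by bisection on the pixel-counted area
    of the scaled region.  Each cell pixel is assigned to the innermost
    ring whose region contains it, which resolves boundary ties
    deterministically.
    """
    if n_rings < 2:
        raise ParameterError(f"need at least 2 rings, got {n_rings}")
    geometry.validate()
    cell = geometry.cell_mask
    centroid = geometry.nucleus_centroid
    total = int(cell.sum())
    target = total / n_rings

    labels = np.zeros(cell.shape, dtype=np.uint8)
    labels[cell] = 1
    scales: list[float] = []
    # cumulative region for ring k..K has target area (K - k + 1) * A / K
    for k in range(n_rings, 1, -1):
        goal = (k - 1) * target  # area inside the boundary between ring k-1 and k
        lo, hi = 0.0, 1.0
        best_s, best_area = 1.0, total
        for _ in range(max_iter):
            s = 0.5 * (lo + hi)
            area = int(_scaled_region(cell, centroid, s).sum())
            if abs(area - goal) < abs(best_area - goal):
                best_s, best_area = s, area
            if area > goal:
                hi = s
            elif area < goal:
                lo = s
            else:
                break
            if hi - lo < 1e-12:
                break
        region = _scaled_region(cell, centroid, best_s)
        labels[region] = n_rings - k + 2
        scales.append(best_s)

    areas = np.array([(labels == k).sum() for k in range(1, n_rings + 1)], dtype=float)
    worst = np.abs(areas - target).max() / target
    if worst > area_tol:
        raise PartitionError(
            f"ring areas {areas.tolist()} deviate from target {target:.1f} "
            f"by {worst:.3f} (> {area_tol}) after {max_iter} iterations"
        )
    partition = RingPartition(
        labels=labels,
        n_rings=n_rings,
        scales=tuple(scales),
        areas=areas,
        area_tol=area_tol,
    )
    partition.validate(cell)
    return partition


def ring_intensity_profile(
    image: np.ndarray,
    partition: RingPartition,
    cell_id: str = "",
    condition: str = "",
) -> RadialProfile:
    """Measure per-ring intensity, density and normalized density.

    The image must already be background-subtracted.  Normalized density
    is ring density over whole-cell density; fractions are shares of the
    total intensity within the cell.
    """
    image = np.asarray(image, dtype=float)
    if image.shape != partition.labels.shape:
        raise ParameterError("image and partition shapes differ")
    K = partition.n_rings
    intensity = np.array(
        [image[partition.labels == k].sum() for k in range(1, K + 1)]
    )
    area = partition.areas
    total_i = intensity.sum()
    if total_i <= 0:
        raise ProfileError("cell has zero total intensity")
    density = intensity / area
    cell_density = total_i / area.sum()
    return RadialProfile(
        intensity=intensity,
        area=area,
        density=density,
        cell_density=cell_density,
        norm_density=density / cell_density,
        fraction=intensity / total_i,
        cell_id=cell_id,
        condition=condition,
    )


def aggregate_profiles(
    profiles: list[RadialProfile], min_cells_warning: int = 30
) -> pd.DataFrame:
    """Per-condition, per-ring mean ± SEM table.

    SEM is sd/sqrt(n) with ddof=1.  A warning is logged for conditions
    with fewer than ``min_cells_warning`` cells.
    """
    if not profiles:
        raise ParameterError("no profiles to aggregate")
    frames = pd.concat([p.to_frame() for p in profiles], ignore_index=True)
    rows = []
    for (cond, ring), grp in frames.groupby(["condition", "ring"], sort=True):
        n = len(grp)
        if n < 2:
            raise ParameterError(
                f"condition {cond!r} has {n} profile(s); need at least 2"
            )
        for metric in ("norm_density", "fraction"):
            vals = grp[metric].to_numpy()
            rows.append(
                {
                    "condition": cond,
                    "ring": ring,
                    "metric": metric,
                    "mean": vals.mean(),
                    "sem": vals.std(ddof=1) / np.sqrt(n),
                    "n": n,
                }
            )
    out = pd.DataFrame(rows)
    for cond, grp in out.groupby("condition"):
        n = int(grp["n"].iloc[0])
        if n < min_cells_warning:
            logger.warning(
                "condition %r has %d cells (< %d)", cond, n, min_cells_warning
            )
    return out
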