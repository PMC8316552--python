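"""Cell and nucleus segmentation producing the geometry for ring analysis.

Automatic segmentation is a fixed, testable recipe (3x3 median filter,
Otsu threshold, hole filling, one closing with a radius-2 disk).  Manually
drawn masks are first-class inputs via :func:`load_manual_masks`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi
from skimage import filters, morphology

from .errors import ParameterError, SegmentationError

logger = logging.getLogger(__name__)

__all__ = ["CellGeometry", "segment_nucleus", "segment_cell", "load_manual_masks"]


@dataclass
class CellGeometry:
    """A segmented cell: masks, nucleus centroid and pixel size.

    Invariants: the nucleus mask is contained in the cell mask, the cell
    mask is one connected component, and the nucleus centroid lies inside
    the cell mask.  ``validate()`` enforces them.
    """

    cell_mask: np.ndarray
    nucleus_mask: np.ndarray
    nucleus_centroid: tuple[float, float]
    pixel_size: float = 1.0

    def __post_init__(self) -> None:
        self.cell_mask = np.asarray(self.cell_mask, dtype=bool)
        self.nucleus_mask = np.asarray(self.nucleus_mask, dtype=bool)

    @property
    def cell_area(self) -> int:
        """Cell area in px²."""
        return int(self.cell_mask.sum())

    @property
    def cell_area_um2(self) -> float:
        return self.cell_area * self.pixel_size**2

    def validate(self) -> None:
        if self.cell_mask.shape != self.nucleus_mask.shape:
            raise ParameterError("cell and nucleus masks differ in shape")
        if not self.cell_mask.any():
            raise SegmentationError("empty cell mask")
        if not self.nucleus_mask.any():
            raise SegmentationError("empty nucleus mask")
        if (self.nucleus_mask & ~self.cell_mask).any():
            raise SegmentationError("nucleus mask extends outside the cell mask")
        n_comp = ndi.label(self.cell_mask)[1]
        if n_comp != 1:
            raise SegmentationError(f"cell mask has {n_comp} connected components")
        r, c = (int(round(x)) for x in self.nucleus_centroid)
        if not (0 <= r < self.cell_mask.shape[0] and 0 <= c < self.cell_mask.shape[1]):
            raise SegmentationError("nucleus centroid outside image bounds")
        if not self.cell_mask[r, c]:
            raise SegmentationError("nucleus centroid outside the cell mask")
        if self.pixel_size <= 0:
            raise ParameterError("pixel size must be positive")


def _auto_mask(image: np.ndarray) -> np.ndarray:
    """Median-filter, Otsu-threshold, fill holes, one closing pass."""
    image = np.asarray(image, dtype=float)
    if image.ndim != 2:
        raise ParameterError(f"expected a 2-D image, got ndim={image.ndim}")
    smoothed = ndi.median_filter(image, size=3)
    if np.ptp(smoothed) == 0:
        raise SegmentationError("image is constant; nothing to segment")
    thresh = filters.threshold_otsu(smoothed)
    mask = smoothed > thresh
    if not mask.any():
        raise SegmentationError("no foreground pixels above the Otsu threshold")
    mask = ndi.binary_fill_holes(mask)
    mask = morphology.closing(mask, morphology.disk(2))
    return ndi.binary_fill_holes(mask)


def segment_nucleus(dapi: np.ndarray) -> tuple[np.ndarray, tuple[float, float]]:
    """Segment the nucleus from the DNA channel.

    Returns the largest above-threshold connected component and its
    mask-based (intensity-unweighted) centroid.
    """
    mask = _auto_mask(dapi)
    labels, n = ndi.label(mask)
    if n == 0:
        raise SegmentationError("no nucleus found")
    sizes = ndi.sum_labels(np.ones_like(labels), labels, index=range(1, n + 1))
    largest = int(np.argmax(sizes)) + 1
    nucleus = labels == largest
    centroid = ndi.center_of_mass(nucleus)
    return nucleus, (float(centroid[0]), float(centroid[1]))


def segment_cell(tracer: np.ndarray, nucleus_mask: np.ndarray) -> np.ndarray:
    """Segment the cell body as the foreground component containing the nucleus.

    Holes are filled; the returned mask is guaranteed to contain the
    nucleus mask (the nucleus is OR-ed in before hole filling).
    """
    nucleus_mask = np.asarray(nucleus_mask, dtype=bool)
    if tracer.shape != nucleus_mask.shape:
        raise ParameterError("tracer image and nucleus mask differ in shape")
    mask = _auto_mask(tracer)
    labels, n = ndi.label(mask)
    hit = np.unique(labels[nucleus_mask])
    hit = hit[hit > 0]
    if hit.size == 0:
        raise SegmentationError("no foreground component contains the nucleus")
    # the component overlapping the nucleus most
    overlaps = [(labels[nucleus_mask] == h).sum() for h in hit]
    cell = labels == hit[int(np.argmax(overlaps))]
    cell = ndi.binary_fill_holes(cell | nucleus_mask)
    return cell


def load_manual_masks(
    cell_mask: np.ndarray,
    nucleus_mask: np.ndarray,
    pixel_size: float = 1.0,
    max_clip_fraction: float = 0.10,
) -> CellGeometry:
    """Build a validated :class:`CellGeometry` from externally drawn masks.

    The nucleus is clipped to the cell mask; clipping more than
    ``max_clip_fraction`` of its area is an error, smaller clips log a
    warning.
    """
    cell = np.asarray(cell_mask) > 0
    nucleus = np.asarray(nucleus_mask) > 0
    if cell.shape != nucleus.shape:
        raise ParameterError("mask shapes differ")
    if not cell.any():
        raise SegmentationError("empty cell mask")
    if not nucleus.any():
        raise SegmentationError("empty nucleus mask")
    clipped = nucleus & cell
    lost = 1.0 - clipped.sum() / nucleus.sum()
    if not clipped.any():
        raise SegmentationError("nucleus mask is entirely outside the cell mask")
    if lost > max_clip_fraction:
        raise SegmentationError(
            f"clipping the nucleus to the cell removes {lost:.0%} of it "
            f"(> {max_clip_fraction:.0%})"
        )
    if lost > 0:
        logger.warning("nucleus clipped to cell mask: lost %.1f%% of area", 100 * lost)
    centroid = ndi.center_of_mass(clipped)
    geom = CellGeometry(
        cell_mask=cell,
        nucleus_mask=clipped,
        nucleus_centroid=(float(centroid[0]), float(centroid[1])),
        pixel_size=pixel_size,
    )
    geom.validate()
    return geom
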