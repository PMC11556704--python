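"""Watershed repair of warped label masks.

Piecewise-affine warping with nearest-neighbour label resampling leaves
cell boundaries ragged: incomplete edges, isolated points, locally thick
or thin borders.  This module repairs a warped mask by re-segmenting the
warped image with marker-based watershed: each warped region, eroded to a
conservative core, seeds a flood over an elevation map (Sobel gradient
magnitude by default, so floods meet on intensity edges).  Marker-based
flooding guarantees the region count is preserved — every input region
contributes exactly one marker and therefore one output basin.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.filters import sobel
from skimage.segmentation import watershed

log = logging.getLogger(__name__)

__all__ = ["RefineConfig", "refine_mask", "boundary_from_labels", "labels_from_boundary"]


@dataclass(frozen=True)
class RefineConfig:
    """Parameters of the watershed refinement stage.

    marker_erosion_radius
        Radius (px) by which each region is shrunk to build its marker.
        Regions that vanish under erosion are restored as a single-pixel
        marker at their most interior point.
    elevation_mode
        ``"gradient"`` floods the Sobel gradient magnitude of the warped
        image; ``"inverted_intensity"`` floods ``1 - image`` (useful when
        borders are dark rather than sharp).
    min_region_area
        Output regions smaller than this (px) are merged into their
        largest neighbour; absorbs isolated-point artefacts.
    elevation_smoothing
        Gaussian sigma (px) applied to the elevation map.  A dark border
        band produces twin Sobel ridges with a contested valley between
        them; smoothing merges them into one centred ridge so watershed
        lines are stable instead of wandering inside the band.
    """

    marker_erosion_radius: int = 2
    elevation_mode: str = "gradient"
    min_region_area: int = 5
    elevation_smoothing: float = 1.0
    max_iterations: int = 5

    def __post_init__(self) -> None:
        if self.marker_erosion_radius < 0:
            raise ValueError("marker_erosion_radius must be >= 0")
        if self.elevation_mode not in ("gradient", "inverted_intensity"):
            raise ValueError(f"unknown elevation_mode: {self.elevation_mode!r}")
        if self.min_region_area < 0:
            raise ValueError("min_region_area must be >= 0")
        if self.elevation_smoothing < 0:
            raise ValueError("elevation_smoothing must be >= 0")
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be >= 1")


def boundary_from_labels(mask: np.ndarray) -> np.ndarray:
    """Two-sided boundary of a label raster.

    A pixel is boundary iff any of its 8-neighbours carries a different
    id, so the interface between two touching regions is two pixels wide
    (one on each side).  The image frame itself is not treated as an
    interface (edge pixels are compared only against in-image neighbours).

    Returns a boolean raster; idempotent through a
    label -> boundary -> label round trip on thick-region masks.
    """
    mask = np.asarray(mask)
    if mask.ndim != 2:
        raise ValueError("label mask must be 2-D")
    hi = ndimage.maximum_filter(mask, size=3, mode="nearest")
    lo = ndimage.minimum_filter(mask, size=3, mode="nearest")
    return hi != lo


def labels_from_boundary(
    boundary: np.ndarray,
    *,
    frame_background_fraction: float = 0.5,
    min_sliver_area: int = 5,
) -> np.ndarray:
    """Connected-component labels of the non-boundary pixels (4-connectivity).

    A component touching the image frame whose area exceeds
    ``frame_background_fraction`` of the image is treated as background
    (id 0) rather than a cell.  Components below ``min_sliver_area`` px —
    pinch-off debris where the two-sided boundary band fully crosses a
    narrow neck, typically at triple junctions — are folded back into the
    boundary (id 0) so the region count survives a
    label -> boundary -> label round trip.
    """
    boundary = np.asarray(boundary).astype(bool)
    structure = ndimage.generate_binary_structure(2, 1)  # 4-connectivity
    labels, n = ndimage.label(~boundary, structure=structure)
    if n == 0:
        return labels

    areas = np.bincount(labels.ravel(), minlength=n + 1)
    drop = np.zeros(n + 1, dtype=bool)
    if min_sliver_area > 0:
        drop |= areas < min_sliver_area
    frame_ids = np.unique(
        np.concatenate([labels[0, :], labels[-1, :], labels[:, 0], labels[:, -1]])
    )
    limit = frame_background_fraction * labels.size
    for i in frame_ids:
        if i > 0 and areas[i] > limit:
            drop[i] = True
    drop[0] = False

    remap = np.zeros(n + 1, dtype=labels.dtype)
    new_id = 0
    for old in range(1, n + 1):
        if not drop[old]:
            new_id += 1
            remap[old] = new_id
    return remap[labels]


def _markers(mask: np.ndarray, radius: int) -> np.ndarray:
    """Per-region cores: pixels farther than ``radius`` from any other id.

    Uses a single distance transform to the two-sided boundary set, which
    erodes every region simultaneously without label bleeding.  Regions
    erased entirely are restored as one marker pixel at their interior
    point of maximal boundary distance.
    """
    if radius == 0:
        return mask.copy()
    boundary = boundary_from_labels(mask)
    dist = ndimage.distance_transform_edt(~boundary)
    markers = np.where(dist >= radius, mask, 0)
    ids = np.unique(mask)
    ids = ids[ids > 0]
    kept = set(np.unique(markers[markers > 0]).tolist())
    for rid in ids:
        if int(rid) in kept:
            continue
        region = mask == rid
        d = np.where(region, dist, -1.0)
        y, x = np.unravel_index(int(np.argmax(d)), d.shape)
        markers[y, x] = rid
        log.warning("marker for region %d vanished under erosion; restored at (%d, %d)", rid, x, y)
    return markers


def _merge_small(labels: np.ndarray, min_area: int) -> np.ndarray:
    """Merge regions below ``min_area`` px into their largest neighbour."""
    if min_area <= 0:
        return labels
    out = labels.copy()
    while True:
        ids, areas = np.unique(out, return_counts=True)
        small = [(int(i), int(a)) for i, a in zip(ids, areas) if i > 0 and a < min_area]
        if not small:
            return out
        rid, _ = min(small, key=lambda t: t[1])
        region = out == rid
        halo = ndimage.binary_dilation(region, ndimage.generate_binary_structure(2, 2)) & ~region
        neigh = out[halo]
        neigh = neigh[neigh != 0]
        if neigh.size == 0:
            return out  # isolated region with no neighbour: leave as-is
        counts = np.bincount(neigh)
        # largest neighbour by total area, not halo contact length
        candidates = np.nonzero(counts)[0]
        target = max(candidates, key=lambda i: int(np.sum(out == i)))
        log.info("merging region %d (area < %d) into neighbour %d", rid, min_area, int(target))
        out[region] = target


def refine_mask(image_w: np.ndarray, mask_w: np.ndarray, cfg: RefineConfig | None = None) -> np.ndarray:
    """Re-segment a warped image seeded by its warped mask.

    Parameters
    ----------
    image_w : 2-D float raster in [0, 1], the warped intensity image.
    mask_w : 2-D integer raster, the warped label mask (ids >= 1).
    cfg : refinement parameters; defaults are tuned for cell mosaics.

    Returns a label raster covering every pixel, with the same id set as
    ``mask_w`` (up to ``min_region_area`` merges, which are logged).

    The marker/flood step is iterated to a fixed point (at most
    ``max_iterations`` passes; convergence is typically immediate), so
    for a fixed elevation the operation is exactly idempotent: flood-order
    ties on gradient plateaus would otherwise let a handful of ridge
    pixels flip when refinement is applied to its own output.
    """
    cfg = cfg or RefineConfig()
    image_w = np.asarray(image_w, dtype=np.float64)
    mask_w = np.asarray(mask_w)
    if image_w.shape != mask_w.shape:
        raise ValueError(f"image {image_w.shape} and mask {mask_w.shape} dimensions differ")
    if not np.any(mask_w > 0):
        raise ValueError("empty mask: no regions to refine")

    if cfg.elevation_mode == "gradient":
        elevation = sobel(image_w)
    else:
        elevation = 1.0 - image_w
    if cfg.elevation_smoothing > 0:
        elevation = ndimage.gaussian_filter(elevation, cfg.elevation_smoothing)

    current = np.asarray(mask_w)
    for _ in range(cfg.max_iterations):
        markers = _markers(current, cfg.marker_erosion_radius)
        # 4-connected flooding keeps every basin a 4-connected region and
        # the implied interfaces 8-connected curves (digital 4/8 duality);
        # 8-connected flooding leaves diagonal debris along the lines
        refined = watershed(elevation, markers=markers, connectivity=1)
        refined = _merge_small(refined, cfg.min_region_area)
        if np.array_equal(refined, current):
            return refined
        current = refined
    log.warning("watershed refinement did not reach a fixed point in %d passes", cfg.max_iterations)
    return current
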