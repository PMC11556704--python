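"""Synthetic cell-mosaic image/mask pairs.

Specular microscopy of the corneal endothelium shows a tessellation of
bright near-hexagonal cells separated by thin dark borders, sometimes
interrupted by guttae (dark drop-like excrescences), and degraded by
illumination gradients, blur and noise.  This module emulates those
images generatively so the warping pipeline can be exercised and tested
with exact ground-truth labels: cells are Voronoi regions of random seed
points (endothelial mosaics are near-Voronoi), a chosen fraction of
regions is rendered as dark guttae, and the render is degraded by a
smooth multiplicative illumination field, additive Gaussian noise and
Gaussian blur.

Intensities are floats in [0, 1] in memory and native 8/16-bit on disk;
generated intensities are quantized to the 16-bit grid so disk round
trips are exact.  Coordinates are 0-based ``(x=column, y=row)`` with the
pixel-centre convention throughout the package.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile
from PIL import Image
from scipy import ndimage

from .refine import boundary_from_labels, labels_from_boundary
from .rng import rng_from

log = logging.getLogger(__name__)

__all__ = ["MosaicSpec", "RegionInfo", "LabeledPair", "generate_mosaic", "write_pair", "read_pair"]

# render intensities (before illumination/noise/blur)
_CELL_LO, _CELL_HI = 0.60, 0.85
_GUTTA_LO, _GUTTA_HI = 0.05, 0.15
_BORDER_LEVEL = 0.15


@dataclass(frozen=True)
class MosaicSpec:
    """Parameters of a synthetic endothelial mosaic.

    guttae_fraction is the fraction of Voronoi cells rendered as dark
    guttae blobs; their region ids stay in the label mask so that
    augmentation treats them like cells.  illumination_amplitude is the
    peak relative deviation of the smooth multiplicative shading field;
    noise_sd is the standard deviation of additive Gaussian noise in
    [0, 1] intensity units.
    """

    height: int = 96
    width: int = 96
    n_cells: int = 20
    guttae_fraction: float = 0.0
    border_width: int = 1
    illumination_amplitude: float = 0.0
    blur_sigma: float = 0.0
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.height < 1 or self.width < 1:
            raise ValueError("height and width must be >= 1")
        if self.n_cells < 1:
            raise ValueError(f"n_cells must be >= 1, got {self.n_cells}")
        if self.n_cells > self.height * self.width:
            raise ValueError("n_cells exceeds the number of pixels; seeds must be distinct")
        if not 0.0 <= self.guttae_fraction <= 1.0:
            raise ValueError(f"guttae_fraction must be in [0, 1], got {self.guttae_fraction}")
        if self.border_width < 1:
            raise ValueError(f"border_width must be >= 1, got {self.border_width}")
        if not 0.0 <= self.illumination_amplitude <= 1.0:
            raise ValueError(f"illumination_amplitude must be in [0, 1], got {self.illumination_amplitude}")
        if self.blur_sigma < 0:
            raise ValueError(f"blur_sigma must be >= 0, got {self.blur_sigma}")
        if self.noise_sd < 0:
            raise ValueError(f"noise_sd must be >= 0, got {self.noise_sd}")


@dataclass(frozen=True)
class RegionInfo:
    """One row of the generator's region table."""

    id: int
    seed_x: int
    seed_y: int
    is_gutta: bool


@dataclass
class LabeledPair:
    """An intensity image and its label mask, kept in lockstep.

    ``label_mask`` assigns each pixel a region id >= 1 (the generator
    emits a full partition; masks loaded from disk may contain id 0 for
    boundary/background pixels).  ``boundary_mask`` is derived: a pixel
    is boundary iff an 8-neighbour carries a different id.
    """

    image: np.ndarray
    label_mask: np.ndarray
    regions: tuple[RegionInfo, ...] | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        self.image = np.asarray(self.image, dtype=np.float64)
        self.label_mask = np.asarray(self.label_mask).astype(np.int32, copy=False)
        if self.image.ndim != 2 or self.label_mask.ndim != 2:
            raise ValueError("image and label_mask must be 2-D")
        if self.image.shape != self.label_mask.shape:
            raise ValueError(
                f"image {self.image.shape} and mask {self.label_mask.shape} dimensions differ"
            )

    @property
    def shape(self) -> tuple[int, int]:
        return self.image.shape

    @property
    def boundary_mask(self) -> np.ndarray:
        return boundary_from_labels(self.label_mask)

    def region_ids(self) -> np.ndarray:
        ids = np.unique(self.label_mask)
        return ids[ids > 0]


def _sample_seeds(rng: np.random.Generator, height: int, width: int, n: int) -> np.ndarray:
    """Distinct seed pixels with a minimum mutual separation.

    Endothelial cells are near-uniform in size, so seeds are drawn by
    dart throwing with an initial exclusion radius of 0.45 * sqrt(hw/n)
    (relaxed geometrically if the quota cannot be filled); this avoids
    the degenerate slivers a plain uniform draw produces.
    """
    r = 0.45 * np.sqrt(height * width / n)
    accepted: list[tuple[int, int]] = []
    while len(accepted) < n:
        for _ in range(200 * n):
            if len(accepted) == n:
                break
            y = int(rng.integers(0, height))
            x = int(rng.integers(0, width))
            if all((y - ay) ** 2 + (x - ax) ** 2 >= r * r for ay, ax in accepted):
                accepted.append((y, x))
        r *= 0.8  # quota not met at this radius: relax and keep going
        if r < 1.0 and len(accepted) < n:  # fall back to any free pixel
            taken = set(accepted)
            for flat in rng.permutation(height * width):
                if len(accepted) == n:
                    break
                yx = (int(flat) // width, int(flat) % width)
                if yx not in taken:
                    accepted.append(yx)
                    taken.add(yx)
    return np.array(accepted, dtype=np.int64)


def _voronoi_labels(height: int, width: int, seeds_yx: np.ndarray) -> np.ndarray:
    """Nearest-seed partition with exact integer arithmetic.

    Squared distances are computed in int64 and ties break toward the
    lowest seed index, so the partition is bit-stable across platforms.
    """
    ys = np.arange(height, dtype=np.int64)[:, None]
    xs = np.arange(width, dtype=np.int64)[None, :]
    best_d = np.full((height, width), np.iinfo(np.int64).max, dtype=np.int64)
    labels = np.zeros((height, width), dtype=np.int32)
    for i, (sy, sx) in enumerate(seeds_yx, start=1):
        d = (ys - sy) ** 2 + (xs - sx) ** 2
        better = d < best_d
        best_d[better] = d[better]
        labels[better] = i
    return _repair_connectivity(labels, seeds_yx)


def _repair_connectivity(labels: np.ndarray, seeds_yx: np.ndarray) -> np.ndarray:
    """Make every region a single 4-connected component.

    Pixel discretization of a Voronoi diagram can leave slivers attached
    to their region only diagonally; such stray components are reassigned
    to the majority 4-neighbour region, keeping the component holding the
    region's seed point.
    """
    four = ndimage.generate_binary_structure(2, 1)
    for _ in range(8):  # repairs converge in one or two passes
        dirty = False
        for rid, (sy, sx) in enumerate(seeds_yx, start=1):
            comp, n = ndimage.label(labels == rid, structure=four)
            if n <= 1:
                continue
            dirty = True
            keep = comp[sy, sx]
            if keep == 0:  # seed pixel stolen by a closer seed's tie-break
                keep = 1
            for ci in range(1, n + 1):
                if ci == keep:
                    continue
                region = comp == ci
                halo = ndimage.binary_dilation(region, four) & ~region
                neigh = labels[halo]
                neigh = neigh[neigh != rid]
                if neigh.size:
                    labels[region] = np.bincount(neigh).argmax()
        if not dirty:
            break
    return labels


def generate_mosaic(spec: MosaicSpec) -> LabeledPair:
    """Render a synthetic mosaic pair; bit-identical for a fixed spec.

    The label mask is the Voronoi partition of ``n_cells`` random seed
    pixels (ids 1..n_cells); ``round(guttae_fraction * n_cells)`` regions
    are flagged as guttae and rendered dark.  The image is the flat-shaded
    mosaic (bright cell interiors, dark borders of ``border_width`` px,
    dark guttae) times a smooth illumination field, plus Gaussian noise,
    then Gaussian blur, clipped to [0, 1] and quantized to the 16-bit grid.
    """
    h, w, n = spec.height, spec.width, spec.n_cells

    geom = rng_from(spec.seed, 0)
    seeds_yx = _sample_seeds(geom, h, w, n)
    labels = _voronoi_labels(h, w, seeds_yx)

    n_guttae = int(round(spec.guttae_fraction * n))
    gutta_ids = set(geom.choice(np.arange(1, n + 1), size=n_guttae, replace=False).tolist())

    interior_levels = geom.uniform(_CELL_LO, _CELL_HI, size=n + 1)
    gutta_levels = geom.uniform(_GUTTA_LO, _GUTTA_HI, size=n + 1)
    levels = interior_levels.copy()
    for gid in gutta_ids:
        levels[gid] = gutta_levels[gid]
    base = levels[labels]

    border = boundary_from_labels(labels)
    if spec.border_width > 1:
        border = ndimage.binary_dilation(
            border, iterations=spec.border_width - 1,
            structure=ndimage.generate_binary_structure(2, 2),
        )
    if gutta_ids:
        # guttae are filled blobs: no border rim drawn inside them
        border &= ~np.isin(labels, sorted(gutta_ids))
    image = np.where(border, _BORDER_LEVEL, base)

    if spec.illumination_amplitude > 0:
        theta = geom.uniform(0, 2 * np.pi)
        ys, xs = np.mgrid[0:h, 0:w]
        proj = np.cos(theta) * xs + np.sin(theta) * ys
        proj = (proj - proj.min()) / max(np.ptp(proj), 1.0)
        image = image * (1.0 + spec.illumination_amplitude * (2.0 * proj - 1.0))

    if spec.noise_sd > 0:
        noise = rng_from(spec.seed, 1).normal(0.0, spec.noise_sd, size=(h, w))
        image = image + noise

    if spec.blur_sigma > 0:
        image = ndimage.gaussian_filter(image, sigma=spec.blur_sigma, mode="nearest")

    image = np.clip(image, 0.0, 1.0)
    image = np.round(image * 65535.0) / 65535.0

    table = tuple(
        RegionInfo(id=i, seed_x=int(sx), seed_y=int(sy), is_gutta=i in gutta_ids)
        for i, (sy, sx) in enumerate(seeds_yx, start=1)
    )
    return LabeledPair(image=image, label_mask=labels, regions=table)


# ---------------------------------------------------------------------------
# disk I/O (TIF / PNG, 8- or 16-bit)

def _write_raster(path: Path, arr: np.ndarray) -> None:
    suffix = path.suffix.lower()
    if suffix in (".tif", ".tiff"):
        tifffile.imwrite(path, arr)
    elif suffix == ".png":
        Image.fromarray(arr).save(path)
    else:
        raise ValueError(f"unsupported image format: {path.suffix!r} (use TIF or PNG)")


def _read_raster(path: Path) -> np.ndarray:
    suffix = path.suffix.lower()
    if suffix in (".tif", ".tiff"):
        arr = tifffile.imread(path)
    elif suffix == ".png":
        arr = np.asarray(Image.open(path))
    else:
        raise ValueError(f"unsupported image format: {path.suffix!r} (use TIF or PNG)")
    if arr.ndim == 3:
        log.warning("multi-channel raster %s reduced to channel 0", path)
        arr = arr[..., 0] if arr.shape[-1] <= 4 else arr[0]
    return arr


def write_pair(pair: LabeledPair, image_path: str | Path, mask_path: str | Path, *, bit_depth: int = 16) -> None:
    """Write image (scaled to ``bit_depth``) and integer label mask.

    Round trip through :func:`read_pair` restores the pair exactly when
    the image intensities lie on the target bit-depth grid.
    """
    if bit_depth not in (8, 16):
        raise ValueError(f"bit_depth must be 8 or 16, got {bit_depth}")
    image_path, mask_path = Path(image_path), Path(mask_path)
    scale = 2**bit_depth - 1
    dtype = np.uint8 if bit_depth == 8 else np.uint16
    img = np.round(np.clip(pair.image, 0.0, 1.0) * scale).astype(dtype)
    _write_raster(image_path, img)
    if pair.label_mask.max() > 65535:
        raise ValueError("label ids exceed the uint16 range of mask files")
    _write_raster(mask_path, pair.label_mask.astype(np.uint16))


def read_pair(image_path: str | Path, mask_path: str | Path, *, mask_kind: str = "auto") -> LabeledPair:
    """Read an image/mask pair from disk.

    Intensities are normalized to [0, 1] by the file's bit depth.  A mask
    whose values are all in {0, 1} or {0, 255} is treated as a binary
    boundary mask and converted to labels by 4-connected labeling of the
    non-boundary pixels (override with ``mask_kind`` in
    {"labels", "boundary"}).
    """
    raw = _read_raster(Path(image_path))
    denom = float(np.iinfo(raw.dtype).max) if np.issubdtype(raw.dtype, np.integer) else 1.0
    img = raw.astype(np.float64) / denom

    mask = _read_raster(Path(mask_path))
    if img.shape != mask.shape:
        raise ValueError(f"image {img.shape} and mask {mask.shape} dimensions differ")
    values = np.unique(mask)
    is_binary = set(values.tolist()) <= {0, 1} or set(values.tolist()) <= {0, 255}
    if mask_kind == "boundary" or (mask_kind == "auto" and is_binary):
        labels = labels_from_boundary(mask > 0)
    elif mask_kind in ("labels", "auto"):
        labels = mask.astype(np.int32)
    else:
        raise ValueError(f"mask_kind must be 'auto', 'labels' or 'boundary', got {mask_kind!r}")
    return LabeledPair(image=img, label_mask=labels)
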