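"""Bounded random shifts and piecewise local affine warping.

Each interior keypoint (xi, yi) of K is shifted to
``(xi + dx, yi + dy)`` with ``dx = R1 * d_min / s`` and
``dy = R2 * d_min / s``, where R1, R2 are independent uniform(-1, 1)
draws, d_min is the minimum pairwise keypoint distance under the
per-axis-min metric, and the strain parameter s > 0 inversely controls
deformation strength (s = 2 strong, s = 3 mild; the useful regime is
s in [1, 3]).  Border keypoints are never shifted.

Delaunay connectivity is computed on the shifted set K' and the same
index triples are imposed on K, so each triangle pair defines one exact
affine map; the warped image is resampled through the inverse map
(bilinear for intensities, nearest-neighbour for labels).  A sampled
warp is accepted only if no triangle folds over (both source and target
areas strictly positive — the certificate that the piecewise map is a
bijection of the image rectangle) and the warped mask keeps every region
id as a single 4-connected component; otherwise shifts are redrawn, up
to a retry budget.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .fixtures import LabeledPair
from .geometry import (
    KeypointSet,
    TriangleMesh,
    border_lattice,
    combine_keypoints,
    delaunay,
    extract_centroids,
    min_pairwise_distance,
    triangle_signed_areas,
)
from .refine import labels_from_boundary
from .rng import rng_from

log = logging.getLogger(__name__)

__all__ = [
    "ShiftField",
    "PiecewiseAffineMap",
    "WarpRejectedError",
    "sample_shifts",
    "build_map",
    "apply_warp",
    "warp_pair",
    "D_MIN_FLOOR",
]

D_MIN_FLOOR = 1.0  # px; applied when interior keypoints share a row/column
DEFAULT_RETRY_BUDGET = 20


class WarpRejectedError(RuntimeError):
    """Raised when no acceptable warp is found within the retry budget."""

    def __init__(self, s: float, attempts: int, n_foldover: int, n_region_loss: int):
        self.s = s
        self.attempts = attempts
        self.n_foldover = n_foldover
        self.n_region_loss = n_region_loss
        super().__init__(
            f"no acceptable warp at s={s} after {attempts} attempts "
            f"({n_foldover} mesh fold-overs, {n_region_loss} region-loss rejections); "
            f"increase s or the retry budget"
        )


@dataclass(frozen=True)
class ShiftField:
    """Per-keypoint random shifts with their provenance.

    Invariants: |dx|, |dy| <= d_min_used / s for every keypoint, and
    border-role keypoints carry (0, 0).
    """

    deltas: np.ndarray
    s: float
    d_min_used: float
    rng_seed: int
    stream: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "deltas", np.asarray(self.deltas, dtype=np.float64).reshape(-1, 2))

    @property
    def bound(self) -> float:
        return self.d_min_used / self.s


def sample_shifts(K: KeypointSet, s: float, seed: int, *, stream: int = 0) -> ShiftField:
    """Draw one bounded random shift per interior keypoint.

    ``stream`` distinguishes retry attempts under the same seed; draws
    come from a counter-based Philox generator so results are
    deterministic and platform-stable.
    """
    if s <= 0:
        raise ValueError(f"strain parameter s must be > 0, got {s}")
    if K.n_interior < 1:
        raise ValueError("keypoint set has no interior points to shift")
    d_min = min_pairwise_distance(K)
    if d_min < D_MIN_FLOOR:
        log.info("degenerate d_min=%.3g px; using floor of %.3g px", d_min, D_MIN_FLOOR)
        d_min = D_MIN_FLOOR
    rng = rng_from(seed, stream)
    deltas = np.zeros((len(K), 2), dtype=np.float64)
    inter = K.interior_mask
    deltas[inter] = rng.uniform(-1.0, 1.0, size=(int(inter.sum()), 2)) * (d_min / s)
    return ShiftField(deltas=deltas, s=float(s), d_min_used=float(d_min), rng_seed=int(seed), stream=stream)


def _affines(src: np.ndarray, dst: np.ndarray, tris: np.ndarray) -> np.ndarray:
    """Per-triangle affine coefficients mapping src vertices onto dst.

    Returns an (M, 2, 3) array A with ``dst = A[:, :, :2] @ src + A[:, :, 2]``,
    solved exactly from the three vertex correspondences.
    """
    a = src[tris]  # (M, 3, 2)
    ones = np.ones((len(tris), 3, 1))
    lhs = np.concatenate([a, ones], axis=2)  # (M, 3, 3) rows: [x, y, 1]
    rhs = dst[tris]  # (M, 3, 2)
    sol = np.linalg.solve(lhs, rhs)  # (M, 3, 2): columns are [a b; c d; tx ty]
    return np.transpose(sol, (0, 2, 1))  # (M, 2, 3)


def _apply_affine(coeff: np.ndarray, pts: np.ndarray) -> np.ndarray:
    return np.einsum("nij,nj->ni", coeff[:, :, :2], pts) + coeff[:, :, 2]


@dataclass
class PiecewiseAffineMap:
    """The piecewise warping function f and its inverse.

    Shared connectivity over source points K and target points K'; the
    forward map carries source coordinates to warped coordinates, the
    inverse recovers source coordinates of each warped pixel.  ``valid``
    certifies bijectivity: every triangle keeps strictly positive signed
    area on both sides.
    """

    source_points: KeypointSet
    target_points: KeypointSet
    connectivity: TriangleMesh
    connectivity_side: str = "target"
    forward_coeff: np.ndarray = field(init=False, repr=False)
    inverse_coeff: np.ndarray = field(init=False, repr=False)
    valid: bool = field(init=False)

    def __post_init__(self) -> None:
        src = self.source_points.points
        dst = self.target_points.points
        tris = self.connectivity.triangles
        src_areas = triangle_signed_areas(src, tris)
        dst_areas = triangle_signed_areas(dst, tris)
        self.valid = bool(np.all(src_areas > 0) and np.all(dst_areas > 0))
        if self.valid:
            self.forward_coeff = _affines(src, dst, tris)
            self.inverse_coeff = _affines(dst, src, tris)
        else:
            self.forward_coeff = np.empty((0, 2, 3))
            self.inverse_coeff = np.empty((0, 2, 3))

    # -- point location ----------------------------------------------------
    def _locate(self, side_points: np.ndarray, pts: np.ndarray) -> np.ndarray:
        """Index of the triangle containing each query point.

        The side on which connectivity was computed has a Qhull locator;
        the other side uses a vectorized barycentric search (valid maps
        tile the rectangle, so every in-rectangle point lies in some
        triangle up to round-off; ties on shared edges pick the triangle
        with the largest minimum barycentric coordinate).
        """
        locator = self.connectivity._locator
        use_qhull = locator is not None and (
            (side_points is self.target_points.points and self.connectivity_side == "target")
            or (side_points is self.source_points.points and self.connectivity_side == "source")
        )
        if use_qhull:
            idx = locator.find_simplex(pts)
            miss = idx < 0
            if np.any(miss):
                idx = idx.copy()
                idx[miss] = self._barycentric_search(side_points, pts[miss])
            return idx
        return self._barycentric_search(side_points, pts)

    def _barycentric_search(self, side_points: np.ndarray, pts: np.ndarray) -> np.ndarray:
        tris = self.connectivity.triangles
        a = side_points[tris[:, 0]]
        b = side_points[tris[:, 1]]
        c = side_points[tris[:, 2]]
        det = (b[:, 0] - a[:, 0]) * (c[:, 1] - a[:, 1]) - (c[:, 0] - a[:, 0]) * (b[:, 1] - a[:, 1])
        out = np.empty(len(pts), dtype=np.int64)
        chunk = 2048
        for lo in range(0, len(pts), chunk):
            p = pts[lo : lo + chunk]
            vx = p[:, None, 0] - a[None, :, 0]
            vy = p[:, None, 1] - a[None, :, 1]
            w1 = ((c[:, 1] - a[:, 1])[None, :] * vx - (c[:, 0] - a[:, 0])[None, :] * vy) / det[None, :]
            w2 = (-(b[:, 1] - a[:, 1])[None, :] * vx + (b[:, 0] - a[:, 0])[None, :] * vy) / det[None, :]
            w0 = 1.0 - w1 - w2
            score = np.minimum(np.minimum(w0, w1), w2)
            out[lo : lo + chunk] = np.argmax(score, axis=1)
        return out

    def forward(self, pts: np.ndarray) -> np.ndarray:
        """Map source-domain coordinates to warped coordinates."""
        if not self.valid:
            raise ValueError("cannot evaluate an invalid (folded) map")
        pts = np.asarray(pts, dtype=np.float64).reshape(-1, 2)
        idx = self._locate(self.source_points.points, pts)
        return _apply_affine(self.forward_coeff[idx], pts)

    def inverse(self, pts: np.ndarray) -> np.ndarray:
        """Map warped-domain coordinates back to source coordinates."""
        if not self.valid:
            raise ValueError("cannot evaluate an invalid (folded) map")
        pts = np.asarray(pts, dtype=np.float64).reshape(-1, 2)
        idx = self._locate(self.target_points.points, pts)
        return _apply_affine(self.inverse_coeff[idx], pts)


def build_map(K: KeypointSet, shifts: ShiftField, *, connectivity_side: str = "target") -> PiecewiseAffineMap:
    """Construct the piecewise affine map between K and K' = K + deltas.

    Connectivity is a single Delaunay triangulation computed on the
    shifted set K' (default) or on K (``connectivity_side="source"``) and
    shared by both sides, which is what makes the per-triangle affines
    well defined.  The map is flagged invalid — not raised — when any
    triangle on either side has non-positive area.
    """
    if connectivity_side not in ("target", "source"):
        raise ValueError(f"connectivity_side must be 'target' or 'source', got {connectivity_side!r}")
    if len(shifts.deltas) != len(K):
        raise ValueError("shift field and keypoint set are not aligned")
    target_pts = K.points + shifts.deltas
    target = KeypointSet(points=target_pts, roles=K.roles.copy())
    mesh_side = target if connectivity_side == "target" else K
    mesh = delaunay(mesh_side)
    return PiecewiseAffineMap(
        source_points=K, target_points=target, connectivity=mesh, connectivity_side=connectivity_side
    )


def apply_warp(pair: LabeledPair, pmap: PiecewiseAffineMap, *, mask_warp: str = "labels") -> LabeledPair:
    """Resample image and mask through the inverse map.

    For every output pixel (x', y') the inverse map gives the source
    location; the image is sampled bilinearly there and the label mask
    with nearest-neighbour (labels are never blended).  With
    ``mask_warp="labels"`` (default) the label raster is warped and the
    boundary re-derived; ``mask_warp="boundary"`` warps the thin binary
    boundary raster instead and rebuilds labels from it by connected
    components (region ids are then renumbered).
    """
    if not pmap.valid:
        raise ValueError("map is invalid (mesh fold-over); resample shifts and rebuild")
    if mask_warp not in ("labels", "boundary"):
        raise ValueError(f"mask_warp must be 'labels' or 'boundary', got {mask_warp!r}")
    h, w = pair.shape
    ys, xs = np.mgrid[0:h, 0:w]
    grid = np.column_stack([xs.ravel(), ys.ravel()]).astype(np.float64)
    src = pmap.inverse(grid)
    # snap sub-1e-5 deviations to the pixel grid: keeps identity maps
    # bit-exact and nearest-neighbour labels stable at pixel centres
    snapped = np.round(src)
    near = np.abs(src - snapped) < 1e-5
    src[near] = snapped[near]
    rows = np.clip(src[:, 1], 0.0, h - 1.0).reshape(h, w)
    cols = np.clip(src[:, 0], 0.0, w - 1.0).reshape(h, w)
    image_w = ndimage.map_coordinates(pair.image, [rows, cols], order=1, mode="nearest")
    if mask_warp == "labels":
        mask_w = ndimage.map_coordinates(pair.label_mask, [rows, cols], order=0, mode="nearest")
    else:
        boundary_w = ndimage.map_coordinates(
            pair.boundary_mask.astype(np.uint8), [rows, cols], order=0, mode="nearest"
        )
        mask_w = labels_from_boundary(boundary_w > 0)
    regions = pair.regions if mask_warp == "labels" else None
    return LabeledPair(image=image_w, label_mask=mask_w, regions=regions)


def _regions_intact(mask_in: np.ndarray, mask_out: np.ndarray) -> bool:
    """True iff the id sets match and regions stay 4-connected.

    Connectivity is only enforced for regions that were a single
    4-connected component on input; a region supplied fragmented is not
    required to heal.
    """
    ids_in = np.unique(mask_in[mask_in > 0])
    ids_out = np.unique(mask_out[mask_out > 0])
    if not np.array_equal(ids_in, ids_out):
        return False
    four = ndimage.generate_binary_structure(2, 1)
    for rid in ids_out:
        _, n_out = ndimage.label(mask_out == rid, structure=four)
        if n_out != 1:
            _, n_in = ndimage.label(mask_in == rid, structure=four)
            if n_out > n_in:
                return False
    return True


def warp_pair(
    pair: LabeledPair,
    s: float,
    seed: int,
    *,
    retry_budget: int = DEFAULT_RETRY_BUDGET,
    connectivity_side: str = "target",
    mask_warp: str = "labels",
) -> tuple[LabeledPair, ShiftField]:
    """Full augmentation of one image/mask pair at strain s.

    Composes centroid extraction, the border lattice, shift sampling,
    map construction and resampling.  A draw is rejected (and redrawn
    with a fresh stream under the same seed) when the mesh folds over or
    the warped mask loses or fragments a region; this automates the
    plausibility screening that would otherwise be manual.  Returns the
    accepted warped pair together with its ShiftField for exact replay.
    """
    if s <= 0:
        raise ValueError(f"strain parameter s must be > 0, got {s}")
    if retry_budget < 1:
        raise ValueError("retry_budget must be >= 1")
    K = combine_keypoints(extract_centroids(pair), border_lattice(pair.shape[1], pair.shape[0]))
    n_foldover = n_region_loss = 0
    for attempt in range(retry_budget):
        shifts = sample_shifts(K, s, seed, stream=attempt)
        pmap = build_map(K, shifts, connectivity_side=connectivity_side)
        if not pmap.valid:
            n_foldover += 1
            continue
        warped = apply_warp(pair, pmap, mask_warp=mask_warp)
        if mask_warp == "labels" and not _regions_intact(pair.label_mask, warped.label_mask):
            n_region_loss += 1
            continue
        if attempt > 0:
            log.info("warp accepted after %d rejected draw(s) at s=%.3g", attempt, s)
        return warped, shifts
    raise WarpRejectedError(s, retry_budget, n_foldover, n_region_loss)
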