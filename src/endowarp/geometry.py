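"""Keypoints and triangulations for mask-guided warping.

The warp is anchored on a keypoint set K built from two sources: one
interior keypoint per mask region (its area centroid) and a fixed
lattice of border points sampled densely along the image frame — at the
corners, edge midpoints, and the quarter and eighth fractions of each
edge (32 unique points).  The dense border lattice prevents degenerate
"black triangle" artefacts at the frame and, because border points are
never shifted, guarantees the warped mesh still tiles the full
rectangle.

The shift magnitude downstream is scaled by d_min, the minimum pairwise
keypoint distance under the per-axis-min metric
``d(a, b) = min(|xa - xb|, |ya - yb|)``.  That metric is zero whenever
two points share an x or y coordinate — always true for the collinear
border lattice — so d_min is computed over interior–interior pairs only;
a floor is applied at shift-sampling time.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import ndimage
from scipy.spatial import Delaunay as _SciPyDelaunay
from scipy.spatial import QhullError

from .fixtures import LabeledPair

log = logging.getLogger(__name__)

__all__ = [
    "KeypointSet",
    "TriangleMesh",
    "extract_centroids",
    "border_lattice",
    "combine_keypoints",
    "min_pairwise_distance",
    "delaunay",
    "triangle_signed_areas",
]

INTERIOR = "interior"
BORDER = "border"


@dataclass(frozen=True)
class KeypointSet:
    """Ordered 2-D pixel coordinates with role tags.

    ``points`` is an (N, 2) float array of (x, y) = (column, row)
    coordinates; ``roles`` is the parallel array of "interior" /
    "border" tags.
    """

    points: np.ndarray
    roles: np.ndarray

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=np.float64).reshape(-1, 2)
        roles = np.asarray(self.roles, dtype="<U8")
        if len(pts) != len(roles):
            raise ValueError("points and roles must have equal length")
        if len(np.unique(pts, axis=0)) != len(pts):
            raise ValueError("keypoints must be distinct")
        object.__setattr__(self, "points", pts)
        object.__setattr__(self, "roles", roles)

    def __len__(self) -> int:
        return len(self.points)

    @property
    def interior_mask(self) -> np.ndarray:
        return self.roles == INTERIOR

    @property
    def n_interior(self) -> int:
        return int(np.sum(self.interior_mask))

    def save_csv(self, path: str | Path) -> None:
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["x", "y", "role"])
            for (x, y), role in zip(self.points, self.roles):
                writer.writerow([x, y, role])

    @classmethod
    def load_csv(cls, path: str | Path) -> "KeypointSet":
        with open(path, newline="") as fh:
            rows = list(csv.DictReader(fh))
        pts = np.array([[float(r["x"]), float(r["y"])] for r in rows])
        roles = np.array([r["role"] for r in rows])
        return cls(points=pts, roles=roles)


@dataclass(frozen=True)
class TriangleMesh:
    """Vertex-index triples over a KeypointSet, stored counter-clockwise.

    "Counter-clockwise" is defined algebraically on (x, y) coordinates:
    every triple has strictly positive signed area under the standard
    cross-product formula.  The same connectivity can be applied to a
    second point set of equal length (source vs shifted target points).
    """

    triangles: np.ndarray
    _locator: _SciPyDelaunay | None = None

    def __post_init__(self) -> None:
        tris = np.asarray(self.triangles, dtype=np.int64).reshape(-1, 3)
        object.__setattr__(self, "triangles", tris)

    def __len__(self) -> int:
        return len(self.triangles)

    def save_off(self, points: np.ndarray, path: str | Path) -> None:
        """Export as an OFF-style text listing for external plotting."""
        with open(path, "w") as fh:
            fh.write("OFF\n")
            fh.write(f"{len(points)} {len(self.triangles)} 0\n")
            for x, y in np.asarray(points):
                fh.write(f"{x} {y} 0\n")
            for a, b, c in self.triangles:
                fh.write(f"3 {a} {b} {c}\n")


def triangle_signed_areas(points: np.ndarray, triangles: np.ndarray) -> np.ndarray:
    """Signed areas of index-triples over (x, y) points (CCW positive)."""
    p = np.asarray(points, dtype=np.float64)
    a, b, c = p[triangles[:, 0]], p[triangles[:, 1]], p[triangles[:, 2]]
    return 0.5 * ((b[:, 0] - a[:, 0]) * (c[:, 1] - a[:, 1]) - (c[:, 0] - a[:, 0]) * (b[:, 1] - a[:, 1]))


def extract_centroids(pair: LabeledPair | np.ndarray) -> KeypointSet:
    """One interior keypoint per region: its area centroid, in id order.

    Centroids are rounded to the nearest pixel with round-half-to-even;
    regions whose centroids coincide after rounding are merged into one
    keypoint (logged).
    """
    mask = pair.label_mask if isinstance(pair, LabeledPair) else np.asarray(pair)
    ids = np.unique(mask)
    ids = ids[ids > 0]
    if len(ids) == 0:
        raise ValueError("no cells found: label mask has no region with id >= 1")
    centroids = ndimage.center_of_mass(np.ones_like(mask), labels=mask, index=ids)
    pts = np.array([[cx, cy] for cy, cx in centroids], dtype=np.float64)
    pts = np.round(pts)  # numpy rounds half to even
    uniq, first = np.unique(pts, axis=0, return_index=True)
    if len(uniq) < len(pts):
        log.warning("%d centroid(s) merged after rounding to pixel grid", len(pts) - len(uniq))
        pts = pts[np.sort(first)]
    return KeypointSet(points=pts, roles=np.full(len(pts), INTERIOR))


def border_lattice(width: int, height: int) -> KeypointSet:
    """Fixed frame keypoints at eighth-fractions of each edge.

    Points sit at fractions {0, 1/8, ..., 7/8, 1} of each edge, at pixel
    positions ``round(f * (size - 1))`` (round half to even); the four
    corners are shared between edges, leaving 32 unique points.
    """
    if width < 9 or height < 9:
        # with size-1 < 8 the rounded eighth-fractions collide
        raise ValueError(f"image must be at least 9 px per side, got {width}x{height}")
    fracs = np.arange(9) / 8.0
    xs = np.round(fracs * (width - 1))
    ys = np.round(fracs * (height - 1))
    pts = []
    for x in xs:
        pts.append((x, 0.0))
        pts.append((x, float(height - 1)))
    for y in ys:
        pts.append((0.0, y))
        pts.append((float(width - 1), y))
    pts = np.array(sorted(set(pts)), dtype=np.float64)
    return KeypointSet(points=pts, roles=np.full(len(pts), BORDER))


def combine_keypoints(interior: KeypointSet, border: KeypointSet) -> KeypointSet:
    """Concatenate centroid and lattice keypoints into the full set K.

    An interior centroid that lands exactly on a lattice point is dropped
    (the border point, which stays fixed, wins); logged when it happens.
    """
    border_set = {tuple(p) for p in border.points}
    keep = np.array([tuple(p) not in border_set for p in interior.points], dtype=bool)
    if not np.all(keep):
        log.warning("%d centroid(s) coincide with border lattice points; dropped", int(np.sum(~keep)))
    pts = np.vstack([interior.points[keep], border.points])
    roles = np.concatenate([interior.roles[keep], border.roles])
    return KeypointSet(points=pts, roles=roles)


def min_pairwise_distance(K: KeypointSet) -> float:
    """Minimum pairwise distance under d(a,b) = min(|dx|, |dy|).

    Computed over interior–interior pairs when the set has at least two
    interior points (border lattice points are collinear, which would
    force the metric to zero); otherwise over all pairs.  The raw value
    is returned — may be 0 for degenerate configurations; callers apply
    the 1 px floor.
    """
    if len(K) < 2:
        raise ValueError("need at least 2 keypoints for a pairwise distance")
    pts = K.points[K.interior_mask] if K.n_interior >= 2 else K.points
    dx = np.abs(pts[:, None, 0] - pts[None, :, 0])
    dy = np.abs(pts[:, None, 1] - pts[None, :, 1])
    d = np.minimum(dx, dy)
    iu = np.triu_indices(len(pts), k=1)
    return float(d[iu].min())


def delaunay(K: KeypointSet | np.ndarray) -> TriangleMesh:
    """Delaunay triangulation with CCW-normalized triangles.

    Raises ``ValueError`` when the points are all collinear (or fewer
    than 3).  For cocircular point sets any valid Delaunay triangulation
    is accepted; downstream behaviour does not depend on the choice.
    """
    pts = K.points if isinstance(K, KeypointSet) else np.asarray(K, dtype=np.float64)
    if len(pts) < 3:
        raise ValueError("need at least 3 points to triangulate")
    try:
        qhull = _SciPyDelaunay(pts)
    except QhullError as exc:
        raise ValueError("cannot triangulate: points are collinear or degenerate") from exc
    tris = qhull.simplices.astype(np.int64)
    areas = triangle_signed_areas(pts, tris)
    flip = areas < 0
    tris[flip] = tris[flip][:, [0, 2, 1]]
    if np.any(triangle_signed_areas(pts, tris) <= 0):
        raise ValueError("degenerate (zero-area) triangle in triangulation")
    return TriangleMesh(triangles=tris, _locator=qhull)
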