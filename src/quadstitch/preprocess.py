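"""Fragment standardization, tissue segmentation, and edge geometry.

Each quadrant image is downsampled, flipped as directed, converted to
grayscale in [0, 1], and segmented into a single connected tissue mask.
The two cut edges of each fragment (the boundaries that face adjacent
quadrants in the reconstruction) are then located from the minimum-area
bounding box of the mask, and fit with robust Theil-Sen lines whose
endpoints drive both the initial reconstruction and the misalignment cost.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import imageio.v3 as iio
from scipy import ndimage
from shapely.geometry import MultiPoint
from skimage import measure
from skimage.color import rgb2gray
from skimage.filters import threshold_otsu
from skimage.morphology import closing, disk
from skimage.transform import resize

from .raster_core import (
    GrayImage, Quadrant, QuadrantSet, RigidTransform, TissueMask, TransformSet,
)


class SegmentationError(RuntimeError):
    """Tissue segmentation produced an empty or degenerate foreground."""


class GeometryError(RuntimeError):
    """Edge/corner geometry could not be derived from a mask."""


# anatomic label -> which min-area-bbox corner points away from the section
# center (and therefore bounds no stitch edge).  Scored on corner (x, y).
_EXTERNAL_CORNER_SCORE = {
    "ul": lambda c: -(c[0] + c[1]),
    "ur": lambda c: c[0] - c[1],
    "ll": lambda c: c[1] - c[0],
    "lr": lambda c: c[0] + c[1],
}


@dataclass
class Edge:
    """One stitch edge: contour pixels plus a robust best-fit line.

    ``orientation`` is ``"horizontal"`` when the edge faces a vertically
    adjacent quadrant (the line is fit as y = slope*x + intercept) and
    ``"vertical"`` otherwise (fit with axes swapped, x = slope*y + intercept).
    ``c_out``/``c_in`` are the best-fit segment endpoints nearest the outer
    prostate boundary and the section center respectively.
    """

    pixels: np.ndarray        # (N, 2) ordered (x, y) boundary-contour points
    orientation: str
    line_slope: float = 0.0
    line_intercept: float = 0.0
    c_out: np.ndarray = None
    c_in: np.ndarray = None

    def midpoint(self) -> np.ndarray:
        return 0.5 * (self.c_out + self.c_in)


@dataclass
class EdgeGeometry:
    """Derived per-quadrant geometry: bbox, corner points, and the two edges."""

    bbox_corners: np.ndarray      # (4, 2)
    corner_points: np.ndarray     # (3, 2) contour points nearest relevant corners
    external_corner: np.ndarray   # (2,) the bbox corner external to the section
    edges: dict                   # {"horizontal": Edge, "vertical": Edge}


def read_raster(path) -> np.ndarray:
    """Read a PNG/TIFF raster (8- or 16-bit, gray or RGB) as float in [0,1]."""
    arr = iio.imread(Path(path))
    if arr.size == 0:
        raise IOError(f"empty image file: {path}")
    if arr.ndim == 3:
        if arr.shape[2] == 4:
            arr = arr[:, :, :3]
        arr = rgb2gray(arr)  # also rescales integer dtypes to [0, 1]
        return np.clip(arr, 0.0, 1.0)
    if np.issubdtype(arr.dtype, np.integer):
        info = np.iinfo(arr.dtype)
        return arr.astype(float) / info.max
    return np.clip(arr.astype(float), 0.0, 1.0)


def standardize(image_file, flip_h: bool = False, flip_v: bool = False,
                target_max_dim: int = 1024,
                scale_um_per_px: float = 1.0) -> GrayImage:
    """Load, flip, gray-convert and downsample one fragment image.

    The result has ``max(width, height) == target_max_dim`` (images already
    smaller are left at native size), intensities in [0, 1], and an adjusted
    physical pixel size.
    """
    if isinstance(image_file, np.ndarray):
        arr = image_file
        if arr.ndim == 3:
            arr = np.clip(rgb2gray(arr[:, :, :3]), 0.0, 1.0)
        elif np.issubdtype(arr.dtype, np.integer):
            arr = arr.astype(float) / np.iinfo(arr.dtype).max
        arr = np.asarray(arr, dtype=float)
    else:
        arr = read_raster(image_file)
    if flip_h:
        arr = np.fliplr(arr)
    if flip_v:
        arr = np.flipud(arr)
    rows, cols = arr.shape
    factor = target_max_dim / max(rows, cols)
    if factor < 1.0:
        shape = (max(1, round(rows * factor)), max(1, round(cols * factor)))
        if min(shape) < 2:
            raise ValueError("image degenerates to a line after downsampling")
        arr = resize(arr, shape, order=1, anti_aliasing=True, preserve_range=True)
        scale_um_per_px = scale_um_per_px / factor
    return GrayImage(np.clip(arr, 0.0, 1.0), scale_um_per_px)


def segment_tissue(img: GrayImage, closing_radius_px: int = 5,
                   threshold: float = None) -> TissueMask:
    """Segment the (dark) tissue foreground from the (bright) background.

    Otsu threshold on the inverted intensities, morphological closing, hole
    filling, and retention of the largest connected component.
    """
    inverted = 1.0 - img.pixels
    if float(inverted.max() - inverted.min()) < 1e-6:
        raise SegmentationError(
            "image has no intensity variation; supply an explicit threshold")
    thr = threshold_otsu(inverted) if threshold is None else float(threshold)
    fg = inverted > thr
    if closing_radius_px > 0:
        fg = closing(fg, disk(closing_radius_px))
    fg = ndimage.binary_fill_holes(fg)
    if not fg.any():
        raise SegmentationError(
            "empty foreground after thresholding; override segment.threshold")
    labels, n = ndimage.label(fg)
    if n > 1:
        sizes = ndimage.sum_labels(fg, labels, index=np.arange(1, n + 1))
        fg = labels == (1 + int(np.argmax(sizes)))
    return TissueMask(fg)


def min_area_bbox(mask: TissueMask) -> np.ndarray:
    """Minimum-area rotated rectangle around the foreground, as 4 corners.

    Pixels are treated as unit squares (the rectangle of an axis-aligned
    w x h block has area w*h, not (w-1)*(h-1)).
    """
    ys, xs = np.nonzero(mask.bits)
    if xs.size < 3:
        raise GeometryError("mask needs at least 3 foreground pixels")
    centers = np.column_stack([xs, ys]).astype(float)
    hull = MultiPoint(centers).convex_hull
    hull_pts = np.asarray(hull.exterior.coords) if hull.geom_type == "Polygon" \
        else centers
    # expand hull points to their pixel-square corners before the final hull
    offs = np.array([[-0.5, -0.5], [-0.5, 0.5], [0.5, -0.5], [0.5, 0.5]])
    expanded = (hull_pts[:, None, :] + offs[None, :, :]).reshape(-1, 2)
    rect = MultiPoint(expanded).minimum_rotated_rectangle
    corners = np.asarray(rect.exterior.coords)[:4]
    return corners


def theil_sen(points, max_points: int = 500):
    """Robust line fit: median of all pairwise slopes.

    Returns ``(slope, intercept)`` for y = slope*x + intercept, with
    ``intercept = median(y_i - slope * x_i)``.  Point sets larger than
    ``max_points`` are thinned by a deterministic even stride before the
    O(n^2) slope enumeration.
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    if pts.shape[0] < 2:
        raise GeometryError("Theil-Sen needs at least 2 points")
    if np.allclose(pts, pts[0]):
        raise GeometryError("all points identical")
    if pts.shape[0] > max_points:
        idx = np.linspace(0, pts.shape[0] - 1, max_points).round().astype(int)
        pts = pts[np.unique(idx)]
    x, y = pts[:, 0], pts[:, 1]
    dx = x[:, None] - x[None, :]
    dy = y[:, None] - y[None, :]
    iu = np.triu_indices(len(x), k=1)
    dx, dy = dx[iu], dy[iu]
    ok = dx != 0
    if not ok.any():
        raise GeometryError("vertical point set; fit with axes swapped")
    slope = float(np.median(dy[ok] / dx[ok]))
    intercept = float(np.median(y - slope * x))
    return slope, intercept


def _boundary_contour(mask: TissueMask) -> np.ndarray:
    """Longest closed boundary contour of the mask as (N, 2) (x, y) points."""
    contours = measure.find_contours(mask.bits.astype(float), 0.5)
    if not contours:
        raise GeometryError("mask has no boundary contour")
    contour = max(contours, key=len)
    pts = contour[:, ::-1]  # (row, col) -> (x, y)
    if np.allclose(pts[0], pts[-1]):
        pts = pts[:-1]
    if len(pts) < 10:
        raise GeometryError("boundary contour shorter than 10 px")
    return pts


def _principal_angle(pts: np.ndarray) -> float:
    """Orientation of a point run in [0, 180) degrees."""
    d = pts - pts.mean(axis=0)
    cov = d.T @ d
    w, v = np.linalg.eigh(cov)
    direction = v[:, np.argmax(w)]
    ang = np.rad2deg(np.arctan2(direction[1], direction[0])) % 180.0
    return ang


def _fit_edge(pixels: np.ndarray, orientation: str, inner_corner: np.ndarray,
              max_points: int = 500) -> Edge:
    """Fit the Theil-Sen line of an edge run and place its endpoints."""
    if orientation == "horizontal":
        slope, intercept = theil_sen(pixels, max_points)
        u = np.array([1.0, slope])
    else:
        slope, intercept = theil_sen(pixels[:, ::-1], max_points)
        u = np.array([slope, 1.0])
    u = u / np.linalg.norm(u)
    anchor = (np.array([0.0, intercept]) if orientation == "horizontal"
              else np.array([intercept, 0.0]))
    # project the extreme contour points onto the fitted line
    proj = (pixels - anchor) @ u
    p_lo = anchor + proj.min() * u
    p_hi = anchor + proj.max() * u
    if np.linalg.norm(p_lo - inner_corner) <= np.linalg.norm(p_hi - inner_corner):
        c_in, c_out = p_lo, p_hi
    else:
        c_in, c_out = p_hi, p_lo
    return Edge(pixels, orientation, slope, intercept, c_out=c_out, c_in=c_in)


def detect_corners_and_edges(q: Quadrant, max_points: int = 500) -> EdgeGeometry:
    """Locate the two stitch edges of a quadrant from its mask geometry.

    The min-area bounding-box corner pointing away from the section center is
    external to the prostate; boundary-contour points nearest the other three
    corners delimit two contour runs facing the section interior, which become
    the horizontal- and vertical-facing edges.
    """
    contour = _boundary_contour(q.mask)
    corners = min_area_bbox(q.mask)
    scores = [_EXTERNAL_CORNER_SCORE[q.label](c) for c in corners]
    ext_idx = int(np.argmax(scores))
    external = corners[ext_idx]
    others = [corners[i] for i in range(4) if i != ext_idx]

    def nearest_idx(point):
        return int(np.argmin(np.linalg.norm(contour - point, axis=1)))

    corner_idx = sorted(nearest_idx(c) for c in others)
    ext_contour_idx = nearest_idx(external)
    n = len(contour)
    runs = []
    for a, b in zip(corner_idx, corner_idx[1:] + [corner_idx[0] + n]):
        idxs = np.arange(a, b + 1) % n
        contains_ext = (a <= ext_contour_idx <= b) or \
            (a <= ext_contour_idx + n <= b)
        runs.append((idxs, contains_ext))
    edge_runs = [contour[idxs] for idxs, has_ext in runs if not has_ext]
    if len(edge_runs) != 2:
        # external point coincided with a corner point; drop the longest run
        runs_sorted = sorted(runs, key=lambda r: len(r[0]))
        edge_runs = [contour[idxs] for idxs, _ in runs_sorted[:2]]

    ang = [_principal_angle(r) for r in edge_runs]
    horiz_dev = [min(a, 180.0 - a) for a in ang]
    hi = int(np.argmin(horiz_dev))
    inner_corner = corners[(ext_idx + 2) % 4]
    edges = {
        "horizontal": _fit_edge(edge_runs[hi], "horizontal", inner_corner,
                                max_points),
        "vertical": _fit_edge(edge_runs[1 - hi], "vertical", inner_corner,
                              max_points),
    }
    corner_points = np.array([contour[i] for i in corner_idx])
    return EdgeGeometry(corners, corner_points, external, edges)


# adjacency table: (first label, second label, facing-edge orientation)
ADJACENCIES = (
    ("ul", "ur", "vertical"),
    ("ur", "lr", "horizontal"),
    ("lr", "ll", "vertical"),
    ("ll", "ul", "horizontal"),
)


def _transformed_edge_mid(q: Quadrant, t: RigidTransform, orientation: str):
    e = q.edges.edges[orientation]
    return t.apply(e.midpoint())[0]


def initial_align(qs: QuadrantSet, factor: int = 1,
                  max_overlap_frac: float = 0.01,
                  max_push_px: int = 40) -> TransformSet:
    """Low-resolution initial reconstruction.

    Each quadrant is rotated so its horizontal-facing edge is parallel to the
    x-axis, then translated so the midpoints of facing best-fit lines meet;
    overlapping pairs are pushed apart along the facing normal until overlap
    falls below ``max_overlap_frac`` of the smaller quadrant.  Input quadrants
    are at a coarse pyramid ``factor``; the returned transforms are in
    base-resolution units with the ul quadrant fixed at the identity.
    """
    for lbl, q in qs.items():
        if q.edges is None:
            raise GeometryError(f"quadrant {lbl!r} has no edge geometry")
    rot = {}
    for lbl, q in qs.items():
        slope = q.edges.edges["horizontal"].line_slope
        theta = -np.rad2deg(np.arctan(slope))
        rot[lbl] = RigidTransform(0.0, 0.0, theta,
                                  center=tuple(q.mask.centroid()))

    t = {lbl: rot[lbl] for lbl in ("ul", "ur", "ll", "lr")}

    def with_shift(lbl, shift):
        base = t[lbl]
        return RigidTransform(base.tx + shift[0], base.ty + shift[1],
                              base.theta, base.flip_h, base.center)

    # join facing edge midpoints, anchored on ul
    t["ur"] = with_shift("ur", _transformed_edge_mid(qs["ul"], t["ul"], "vertical")
                         - _transformed_edge_mid(qs["ur"], t["ur"], "vertical"))
    t["ll"] = with_shift("ll", _transformed_edge_mid(qs["ul"], t["ul"], "horizontal")
                         - _transformed_edge_mid(qs["ll"], t["ll"], "horizontal"))
    s1 = _transformed_edge_mid(qs["ur"], t["ur"], "horizontal") \
        - _transformed_edge_mid(qs["lr"], t["lr"], "horizontal")
    s2 = _transformed_edge_mid(qs["ll"], t["ll"], "vertical") \
        - _transformed_edge_mid(qs["lr"], t["lr"], "vertical")
    t["lr"] = with_shift("lr", 0.5 * (s1 + s2))

    # push each moving quadrant away from its partner along the facing normal
    # until the pairwise overlap is small
    areas = {lbl: q.mask.area() for lbl, q in qs.items()}
    pushes = (
        ("ur", "ul", np.array([1.0, 0.0])),
        ("ll", "ul", np.array([0.0, 1.0])),
        ("lr", "ur", np.array([0.0, 1.0])),
        ("lr", "ll", np.array([1.0, 0.0])),
    )
    for mover, partner, direction in pushes:
        limit = max_overlap_frac * min(areas[mover], areas[partner])
        for _ in range(max_push_px):
            if _overlap_area(qs[mover], t[mover], qs[partner], t[partner]) \
                    <= limit:
                break
            t[mover] = with_shift(mover, direction)

    return _normalized(qs, t, factor)


def _overlap_area(qa, ta, qb, tb) -> int:
    """Foreground overlap (px) of two transformed masks, by point transform."""
    ys, xs = np.nonzero(qa.mask.bits)
    pts = ta.apply(np.column_stack([xs, ys]).astype(float))
    inv = tb.inverse()
    local = inv.apply(pts)
    xi = np.round(local[:, 0]).astype(int)
    yi = np.round(local[:, 1]).astype(int)
    ok = (xi >= 0) & (xi < qb.mask.width) & (yi >= 0) & (yi < qb.mask.height)
    return int(qb.mask.bits[yi[ok], xi[ok]].sum())


def _normalized(qs: QuadrantSet, t: dict, factor: int = 1) -> TransformSet:
    """Re-express transforms relative to ul (identity) in base-res units."""
    M_ul_inv = np.linalg.inv(t["ul"].matrix())
    out = {}
    for lbl, q in qs.items():
        M = M_ul_inv @ t[lbl].matrix()
        center = q.mask.centroid() * factor
        if factor != 1:
            S = np.diag([factor, factor, 1.0])
            M = S @ M @ np.linalg.inv(S)
        out[lbl] = RigidTransform.from_matrix(M, center=tuple(center))
    # force exact identity on the anchor
    out["ul"] = RigidTransform(center=out["ul"].center)
    return TransformSet(out, "ul")
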