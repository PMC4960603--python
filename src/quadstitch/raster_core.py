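"""Image, mask, and rigid-transform primitives shared by every other module.

Conventions used throughout the package:

* arrays are indexed ``[row, col]`` = ``[y, x]``, 0-based, pixel centers at
  integer coordinates, *y* increasing downward;
* point arrays are shaped ``(N, 2)`` and ordered ``(x, y)``;
* intensities live in ``[0, 1]``;
* rotations are in degrees, positive counter-clockwise in the (x, y)
  coordinate sense, about an explicit center point.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import ndimage
from skimage.transform import resize

QUADRANT_LABELS = ("ul", "ur", "ll", "lr")

#: rendering order when quadrants overlap on the composite canvas
COMPOSITE_ORDER = ("ul", "ur", "ll", "lr")


class DimensionError(ValueError):
    """Raised when a canvas cannot contain a transformed quadrant."""


@dataclass
class GrayImage:
    """A 2-D grayscale raster with intensities rescaled to [0, 1].

    Parameters
    ----------
    pixels
        2-D float array of intensities in [0, 1].
    scale_um_per_px
        Physical size of one pixel in micrometres.
    """

    pixels: np.ndarray
    scale_um_per_px: float = 1.0

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.ndim != 2 or self.pixels.size == 0:
            raise ValueError("GrayImage requires a non-empty 2-D array")
        lo, hi = float(self.pixels.min()), float(self.pixels.max())
        if lo < -1e-9 or hi > 1 + 1e-9:
            raise ValueError(f"intensities must lie in [0, 1]; got [{lo}, {hi}]")
        if not self.scale_um_per_px > 0:
            raise ValueError("scale_um_per_px must be positive")

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]


@dataclass
class TissueMask:
    """Binary foreground (tissue) mask congruent with a :class:`GrayImage`."""

    bits: np.ndarray

    def __post_init__(self) -> None:
        self.bits = np.asarray(self.bits).astype(bool)
        if self.bits.ndim != 2 or self.bits.size == 0:
            raise ValueError("TissueMask requires a non-empty 2-D array")

    @property
    def height(self) -> int:
        return self.bits.shape[0]

    @property
    def width(self) -> int:
        return self.bits.shape[1]

    def area(self) -> int:
        return int(self.bits.sum())

    def centroid(self) -> np.ndarray:
        """(x, y) centroid of the foreground pixels."""
        ys, xs = np.nonzero(self.bits)
        if xs.size == 0:
            raise ValueError("empty mask has no centroid")
        return np.array([xs.mean(), ys.mean()])


def _rotmat(theta_deg: float) -> np.ndarray:
    a = np.deg2rad(theta_deg)
    c, s = np.cos(a), np.sin(a)
    return np.array([[c, -s], [s, c]])


@dataclass(frozen=True)
class RigidTransform:
    """3-DOF rigid pose: translation (px) + rotation (deg) about ``center``.

    A point ``p`` maps to ``R(theta) @ (p - center) + center + (tx, ty)``.
    ``flip_h`` records a pre-applied horizontal mirror (bookkeeping only; it
    does not enter the mapping).
    """

    tx: float = 0.0
    ty: float = 0.0
    theta: float = 0.0
    flip_h: bool = False
    center: tuple = (0.0, 0.0)

    def matrix(self) -> np.ndarray:
        """3x3 homogeneous matrix acting on (x, y, 1) columns."""
        R = _rotmat(self.theta)
        c = np.asarray(self.center, dtype=float)
        t = np.array([self.tx, self.ty], dtype=float)
        M = np.eye(3)
        M[:2, :2] = R
        M[:2, 2] = c + t - R @ c
        return M

    def apply(self, points: np.ndarray) -> np.ndarray:
        """Map an (N, 2) array of (x, y) points."""
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        R = _rotmat(self.theta)
        c = np.asarray(self.center, dtype=float)
        return (pts - c) @ R.T + c + np.array([self.tx, self.ty])

    def inverse(self) -> "RigidTransform":
        Rinv = _rotmat(-self.theta)
        t = Rinv @ np.array([self.tx, self.ty])
        return RigidTransform(-t[0], -t[1], -self.theta, self.flip_h, self.center)

    def compose(self, first: "RigidTransform") -> "RigidTransform":
        """Return ``self o first`` (apply ``first``, then ``self``).

        Both transforms must share the same rotation center.
        """
        if not np.allclose(self.center, first.center):
            raise ValueError("compose requires a common rotation center")
        R = _rotmat(self.theta)
        t = R @ np.array([first.tx, first.ty]) + np.array([self.tx, self.ty])
        return RigidTransform(
            t[0], t[1], self.theta + first.theta,
            self.flip_h ^ first.flip_h, self.center,
        )

    def is_identity(self, tol: float = 1e-9) -> bool:
        return abs(self.tx) <= tol and abs(self.ty) <= tol and abs(self.theta) <= tol

    @classmethod
    def from_matrix(cls, M: np.ndarray, center=(0.0, 0.0),
                    flip_h: bool = False) -> "RigidTransform":
        """Recover (tx, ty, theta) about ``center`` from a rigid 3x3 matrix."""
        theta = np.rad2deg(np.arctan2(M[1, 0], M[0, 0]))
        c = np.append(np.asarray(center, dtype=float), 1.0)
        t = (M @ c)[:2] - c[:2]
        return cls(float(t[0]), float(t[1]), float(theta), flip_h, tuple(center))


@dataclass
class Quadrant:
    """One tissue fragment: image + mask + anatomic label + edge geometry."""

    label: str
    image: GrayImage
    mask: TissueMask
    edges: object = None  # preprocess.EdgeGeometry, attached lazily

    def __post_init__(self) -> None:
        if self.label not in QUADRANT_LABELS:
            raise ValueError(f"label must be one of {QUADRANT_LABELS}")
        if self.image.pixels.shape != self.mask.bits.shape:
            raise ValueError("image and mask dimensions differ")


@dataclass
class QuadrantSet:
    """Exactly four quadrants, one per anatomic label."""

    quadrants: dict

    def __post_init__(self) -> None:
        if set(self.quadrants) != set(QUADRANT_LABELS):
            raise ValueError(f"need exactly the labels {QUADRANT_LABELS}")
        for lbl, q in self.quadrants.items():
            if q.label != lbl:
                raise ValueError(f"quadrant labelled {q.label!r} stored under {lbl!r}")

    def __getitem__(self, label: str) -> Quadrant:
        return self.quadrants[label]

    def items(self):
        return ((lbl, self.quadrants[lbl]) for lbl in QUADRANT_LABELS)


@dataclass
class TransformSet:
    """One rigid transform per quadrant; the fixed quadrant is the identity."""

    transforms: dict
    fixed_label: str = "ul"

    def __post_init__(self) -> None:
        if set(self.transforms) != set(QUADRANT_LABELS):
            raise ValueError(f"need exactly the labels {QUADRANT_LABELS}")
        if not self.transforms[self.fixed_label].is_identity(tol=1e-6):
            raise ValueError(f"transform of fixed quadrant {self.fixed_label!r} "
                             "must be the identity")

    def __getitem__(self, label: str) -> RigidTransform:
        return self.transforms[label]

    def to_json(self) -> str:
        payload = {
            "fixed": self.fixed_label,
            "transforms": {
                lbl: {
                    "tx": float(t.tx), "ty": float(t.ty), "theta": float(t.theta),
                    "flip_h": bool(t.flip_h),
                    "center": [float(t.center[0]), float(t.center[1])],
                }
                for lbl, t in ((l, self.transforms[l]) for l in QUADRANT_LABELS)
            },
            "units": {"translation": "px_base", "rotation": "deg"},
        }
        return json.dumps(payload, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "TransformSet":
        payload = json.loads(text)
        transforms = {}
        for lbl, rec in payload["transforms"].items():
            transforms[lbl] = RigidTransform(
                rec["tx"], rec["ty"], rec["theta"],
                bool(rec.get("flip_h", False)),
                tuple(rec.get("center", (0.0, 0.0))),
            )
        return cls(transforms, payload.get("fixed", "ul"))


@dataclass
class Pyramid:
    """Multi-resolution stack, coarsest level first, finest factor = 1."""

    levels: list  # of (GrayImage, TissueMask, int factor)

    def __post_init__(self) -> None:
        factors = [f for _, _, f in self.levels]
        if not factors or factors[-1] != 1:
            raise ValueError("finest pyramid factor must be 1")
        if any(a <= b for a, b in zip(factors, factors[1:])):
            raise ValueError("pyramid factors must be strictly decreasing")


def _mask_extent(mask: TissueMask, t: RigidTransform) -> tuple:
    """(min_xy, max_xy) of the transformed foreground's bounding box.

    Uses the convex hull of the foreground pixels so rotation of a compact
    mask inside a larger frame is not overestimated.
    """
    ys, xs = np.nonzero(mask.bits)
    if xs.size == 0:
        raise ValueError("empty mask")
    pts = np.column_stack([xs, ys]).astype(float)
    if len(pts) > 4:
        try:
            from scipy.spatial import ConvexHull
            pts = pts[ConvexHull(pts).vertices]
        except Exception:
            pass  # degenerate (collinear) masks: fall back to all points
    out = t.apply(pts)
    return out.min(axis=0), out.max(axis=0)


def apply_transform(q: Quadrant, t: RigidTransform, canvas_shape: tuple,
                    origin=(0.0, 0.0), image_cval: float = 1.0):
    """Resample a quadrant into canvas coordinates under a rigid transform.

    ``canvas_shape`` is (rows, cols); canvas pixel (j, i) corresponds to the
    common-frame point ``(j + origin_x, i + origin_y)``.  Intensities are
    interpolated bilinearly, the mask with nearest-neighbour; pixels outside
    the source are background (``image_cval`` / False).

    Raises
    ------
    DimensionError
        If the transformed tissue bounding box does not fit on the canvas.
    """
    rows, cols = int(canvas_shape[0]), int(canvas_shape[1])
    origin = np.asarray(origin, dtype=float)
    lo, hi = _mask_extent(q.mask, t)
    over_lo = origin - lo
    over_hi = hi - (origin + np.array([cols - 1, rows - 1]))
    if (over_lo > 0.5).any() or (over_hi > 0.5).any():
        raise DimensionError(
            f"canvas {cols}x{rows} at origin {origin.tolist()} cannot contain "
            f"transformed mask extent [{lo.tolist()}, {hi.tolist()}]"
        )

    A = np.linalg.inv(t.matrix())
    # scipy affine_transform maps output (row, col) indices to input indices
    mat = np.array([[A[1, 1], A[1, 0]], [A[0, 1], A[0, 0]]])
    ox, oy = origin
    off = np.array([
        A[1, 0] * ox + A[1, 1] * oy + A[1, 2],
        A[0, 0] * ox + A[0, 1] * oy + A[0, 2],
    ])
    img = ndimage.affine_transform(
        q.image.pixels, mat, offset=off, output_shape=(rows, cols),
        order=1, mode="grid-constant", cval=image_cval)
    msk = ndimage.affine_transform(
        q.mask.bits.astype(float), mat, offset=off, output_shape=(rows, cols),
        order=0, mode="grid-constant", cval=0.0) > 0.5
    return (GrayImage(np.clip(img, 0.0, 1.0), q.image.scale_um_per_px),
            TissueMask(msk))


@dataclass
class CompositeResult:
    """A rendered reconstruction plus the canvas origin in the common frame."""

    image: GrayImage
    mask: TissueMask
    origin: tuple  # (x, y) of canvas pixel (0, 0) in the common frame


def composite_section(qs: QuadrantSet, ts: TransformSet, margin: int = 8,
                      image_cval: float = 1.0) -> CompositeResult:
    """Render all four transformed quadrants onto one auto-sized canvas.

    Where masks overlap the later-drawn quadrant wins, in the fixed order
    ul, ur, ll, lr.
    """
    los, his = [], []
    for lbl in COMPOSITE_ORDER:
        lo, hi = _mask_extent(qs[lbl].mask, ts[lbl])
        los.append(lo)
        his.append(hi)
    lo = np.floor(np.min(los, axis=0)) - margin
    hi = np.ceil(np.max(his, axis=0)) + margin
    cols = int(hi[0] - lo[0]) + 1
    rows = int(hi[1] - lo[1]) + 1
    out_img = np.full((rows, cols), image_cval, dtype=float)
    out_msk = np.zeros((rows, cols), dtype=bool)
    scale = qs["ul"].image.scale_um_per_px
    for lbl in COMPOSITE_ORDER:
        img, msk = apply_transform(qs[lbl], ts[lbl], (rows, cols),
                                   origin=lo, image_cval=image_cval)
        out_img[msk.bits] = img.pixels[msk.bits]
        out_msk |= msk.bits
    return CompositeResult(GrayImage(out_img, scale), TissueMask(out_msk),
                           (float(lo[0]), float(lo[1])))


def build_pyramid(q: Quadrant, factors: Sequence[int]) -> Pyramid:
    """Anti-aliased multiresolution stack of one quadrant.

    ``factors`` run from coarsest to finest and must end at 1; masks are
    downsampled by local majority vote and re-binarized.
    """
    factors = [int(f) for f in factors]
    if not factors or factors[-1] != 1:
        raise ValueError("factors must end at 1")
    if any(a <= b for a, b in zip(factors, factors[1:])):
        raise ValueError("factors must be strictly decreasing")
    base_img = q.image.pixels
    base_msk = q.mask.bits
    rows, cols = base_img.shape
    levels = []
    for f in factors:
        if f == 1:
            levels.append((GrayImage(base_img.copy(), q.image.scale_um_per_px),
                           TissueMask(base_msk.copy()), 1))
            continue
        shape = (max(1, round(rows / f)), max(1, round(cols / f)))
        img = resize(base_img, shape, order=1, anti_aliasing=True,
                     preserve_range=True)
        msk = resize(base_msk.astype(float), shape, order=1,
                     anti_aliasing=False, preserve_range=True) >= 0.5
        levels.append((GrayImage(np.clip(img, 0.0, 1.0),
                                 q.image.scale_um_per_px * f),
                       TissueMask(msk), f))
    return Pyramid(levels)
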