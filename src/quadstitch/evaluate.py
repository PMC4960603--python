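"""Reconstruction scoring: fiducial errors and convex-hull Hausdorff distance.

A candidate reconstruction is compared to a reference reconstruction through
(a) automatically placed fiducials on the endpoints and midpoints of the four
stitch edges (ASF), (b) externally supplied landmark pairs (MSF), and (c) the
symmetric Hausdorff distance between the convex hulls of the two tissue
masks after optimal rigid alignment.  Each measure is reported in
micrometres and normalized by the average of the reference reconstruction's
width and height to give a percentage.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar
from scipy.spatial import ConvexHull, cKDTree

from .preprocess import ADJACENCIES, detect_corners_and_edges
from .raster_core import (
    QuadrantSet, RigidTransform, TissueMask, TransformSet, composite_section,
)


@dataclass
class FiducialPair:
    """One corresponding point pair, each leg in a quadrant-local frame."""

    label_a: str
    point_a: np.ndarray
    label_b: str
    point_b: np.ndarray
    source: str = "auto"


@dataclass
class EvalReport:
    """Aggregate reconstruction-quality report."""

    asf_um: float
    asf_pct: float
    msf_um: float
    msf_pct: float
    hausdorff_um: float
    hausdorff_pct: float
    ref_width_um: float
    ref_height_um: float
    n_fiducials: int

    def to_json(self) -> str:
        rec = {k: (None if v is None else float(v) if not isinstance(v, int)
                   else v) for k, v in asdict(self).items()}
        return json.dumps(rec, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "EvalReport":
        return cls(**json.loads(text))

    def to_csv_row(self) -> pd.DataFrame:
        return pd.DataFrame([asdict(self)])


def _normalizer_um(mask: TissueMask, scale_um_per_px: float) -> tuple:
    ys, xs = np.nonzero(mask.bits)
    width = (xs.max() - xs.min() + 1) * scale_um_per_px
    height = (ys.max() - ys.min() + 1) * scale_um_per_px
    return float(width), float(height)


def place_asf_fiducials(qs: QuadrantSet, ref_ts: TransformSet,
                        n_asf: int = 10, merge_radius_frac: float = 0.02):
    """Automatic fiducial anchors on the stitch edges of the reference.

    For each of the four stitch edges the two best-fit-line endpoints and the
    midpoint are taken in the reference frame; near-coincident central points
    are merged and the set is truncated to ``n_asf`` anchors, outermost
    first.  Each anchor is expressed in both adjacent quadrants' local
    coordinates so it can be mapped through any other transform set.
    """
    candidates = []
    for la, lb, orient in ADJACENCIES:
        qa = qs[la]
        if qa.edges is None:
            qa.edges = detect_corners_and_edges(qa)
        e = qa.edges.edges[orient]
        for pt in (e.c_out, e.midpoint(), e.c_in):
            common = ref_ts[la].apply(pt)[0]
            candidates.append((common, la, lb))
    pts = np.array([c[0] for c in candidates])
    center = pts.mean(axis=0)
    span = np.ptp(pts, axis=0).mean()
    radius = merge_radius_frac * max(span, 1.0)
    order = np.argsort(-np.linalg.norm(pts - center, axis=1))
    kept = []
    for i in order:
        if all(np.linalg.norm(pts[i] - pts[j]) > radius for j in kept):
            kept.append(i)
        if len(kept) == n_asf:
            break
    pairs = []
    inv = {lbl: ref_ts[lbl].inverse() for lbl in ("ul", "ur", "ll", "lr")}
    for i in kept:
        common, la, lb = candidates[i]
        pairs.append(FiducialPair(la, inv[la].apply(common)[0],
                                  lb, inv[lb].apply(common)[0], "auto"))
    return pairs


def map_fiducials(pairs, ts: TransformSet) -> np.ndarray:
    """Per-pair distances (px) after mapping both legs through ``ts``."""
    d = []
    for p in pairs:
        a = ts[p.label_a].apply(p.point_a)[0]
        b = ts[p.label_b].apply(p.point_b)[0]
        d.append(np.linalg.norm(a - b))
    return np.asarray(d)


def fiducial_error(distances_px, scale_um_per_px: float,
                   ref_dims_um: tuple) -> tuple:
    """(mean_um, normalized_pct) of fiducial pair distances.

    Normalization divides by the average of the reference reconstruction's
    width and height (in um).
    """
    distances_px = np.asarray(distances_px, dtype=float)
    if distances_px.size == 0:
        raise ValueError("no fiducial pairs")
    mean_um = float(distances_px.mean() * scale_um_per_px)
    denom = 0.5 * (ref_dims_um[0] + ref_dims_um[1])
    return mean_um, 100.0 * mean_um / denom


def _hull_chain(mask: TissueMask, spacing_px: float = 1.0) -> np.ndarray:
    """Convex hull of the foreground as a dense (N, 2) point chain."""
    ys, xs = np.nonzero(mask.bits)
    if xs.size == 0:
        raise ValueError("empty mask")
    pts = np.column_stack([xs, ys]).astype(float)
    hull = ConvexHull(pts)
    verts = pts[hull.vertices]
    chain = []
    nv = len(verts)
    for i in range(nv):
        a, b = verts[i], verts[(i + 1) % nv]
        seg = np.linalg.norm(b - a)
        k = max(1, int(np.ceil(seg / spacing_px)))
        t = np.arange(k) / k
        chain.append(a[None, :] * (1 - t[:, None]) + b[None, :] * t[:, None])
    return np.vstack(chain)


def _sym_hausdorff(a: np.ndarray, b: np.ndarray) -> float:
    da = cKDTree(b).query(a)[0].max()
    db = cKDTree(a).query(b)[0].max()
    return float(max(da, db))


def _rotate(pts: np.ndarray, theta_deg: float) -> np.ndarray:
    a = np.deg2rad(theta_deg)
    R = np.array([[np.cos(a), -np.sin(a)], [np.sin(a), np.cos(a)]])
    return pts @ R.T


def hull_hausdorff(mask_ref: TissueMask, mask_test: TissueMask,
                   scale_um_per_px: float, spacing_px: float = 1.0,
                   coarse_step_deg: float = 0.5, tol_px: float = 0.1):
    """Minimum symmetric Hausdorff distance between aligned convex hulls.

    Both hulls are resampled at ``spacing_px`` arc length, centered on their
    centroids, coarsely aligned by a rotation grid search, then refined by
    golden-section search on the angle and coordinate descent on the
    translation.  Returns ``(hausdorff_um, normalized_pct, (theta, tx, ty))``.
    """
    a = _hull_chain(mask_ref, spacing_px)
    b = _hull_chain(mask_test, spacing_px)
    ca, cb = a.mean(axis=0), b.mean(axis=0)
    a0 = a - ca
    b0 = b - cb

    def sub(pts, cap=256):
        if len(pts) <= cap:
            return pts
        idx = np.linspace(0, len(pts) - 1, cap).round().astype(int)
        return pts[np.unique(idx)]

    a_s, b_s = sub(a0), sub(b0)
    tree_a_s = cKDTree(a_s)
    angles = np.arange(0.0, 360.0, coarse_step_deg)
    best_ang, best_h = 0.0, np.inf
    for ang in angles:
        rb = _rotate(b_s, ang)
        h = max(cKDTree(rb).query(a_s)[0].max(), tree_a_s.query(rb)[0].max())
        if h < best_h:
            best_h, best_ang = h, ang

    theta = best_ang
    shift = np.zeros(2)

    def objective(th, sh):
        return _sym_hausdorff(a0, _rotate(b0, th) + sh)

    prev = np.inf
    for _ in range(20):
        res = minimize_scalar(lambda th: objective(th, shift),
                              bounds=(theta - coarse_step_deg,
                                      theta + coarse_step_deg),
                              method="bounded",
                              options={"xatol": 1e-3})
        theta = float(res.x)
        for axis in (0, 1):
            def f(v, axis=axis):
                s = shift.copy()
                s[axis] = v
                return objective(theta, s)
            res = minimize_scalar(f, bounds=(shift[axis] - 3.0,
                                             shift[axis] + 3.0),
                                  method="bounded", options={"xatol": 1e-3})
            shift[axis] = float(res.x)
        cur = objective(theta, shift)
        if prev - cur < tol_px:
            break
        prev = cur

    h_px = objective(theta, shift)
    w_um, h_um = _normalizer_um(mask_ref, scale_um_per_px)
    pct = 100.0 * h_px * scale_um_per_px / (0.5 * (w_um + h_um))
    tx, ty = (ca - cb) + shift
    return float(h_px * scale_um_per_px), float(pct), \
        (theta, float(tx), float(ty))


def load_msf_csv(path) -> list:
    """Read manual fiducial pairs: header ``ref_x,ref_y,test_x,test_y`` (px)."""
    df = pd.read_csv(path)
    required = {"ref_x", "ref_y", "test_x", "test_y"}
    if not required.issubset(df.columns):
        raise ValueError(f"MSF CSV must have columns {sorted(required)}")
    return df


def evaluate_reconstruction(qs: QuadrantSet, ref_ts: TransformSet,
                            test_ts: TransformSet, scale_um_per_px: float,
                            msf_pairs=None, n_asf: int = 10) -> EvalReport:
    """Full report comparing a test transform set to a reference.

    ``msf_pairs`` may be a list of :class:`FiducialPair` in quadrant-local
    coordinates (e.g. synthetic ground-truth landmarks); when omitted the MSF
    fields are ``None``.
    """
    ref_comp = composite_section(qs, ref_ts)
    test_comp = composite_section(qs, test_ts)
    ref_dims = _normalizer_um(ref_comp.mask, scale_um_per_px)

    asf = place_asf_fiducials(qs, ref_ts, n_asf=n_asf)
    asf_um, asf_pct = fiducial_error(map_fiducials(asf, test_ts),
                                     scale_um_per_px, ref_dims)

    msf_um = msf_pct = None
    if msf_pairs is not None:
        msf_um, msf_pct = fiducial_error(map_fiducials(msf_pairs, test_ts),
                                         scale_um_per_px, ref_dims)

    h_um, h_pct, _ = hull_hausdorff(ref_comp.mask, test_comp.mask,
                                    scale_um_per_px)
    return EvalReport(asf_um, asf_pct, msf_um, msf_pct, h_um, h_pct,
                      ref_dims[0], ref_dims[1], len(asf))


def landmarks_to_fiducials(landmarks: pd.DataFrame) -> list:
    """Convert a synthetic landmarks table into MSF-style fiducial pairs."""
    pairs = []
    for _, row in landmarks.iterrows():
        pairs.append(FiducialPair(
            row["label_a"], np.array([row["xa"], row["ya"]]),
            row["label_b"], np.array([row["xb"], row["yb"]]), "manual"))
    return pairs
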