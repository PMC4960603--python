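"""The two-component stitching cost: tissue dissimilarity + boundary misalignment.

Dissimilarity compares intensity histograms of square patches centered on
corresponding edge pixels across each stitch boundary; pixels without a
correspondent on the adjacent quadrant contribute the maximum dissimilarity
``phi``.  Misalignment is the weighted distance between the endpoints of the
facing edges' best-fit lines.  Both terms are averaged over the four adjacent
quadrant pairs and combined as ``w1 * D_tot + w2 * M_tot``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .preprocess import ADJACENCIES, detect_corners_and_edges
from .raster_core import GrayImage, Quadrant, QuadrantSet, RigidTransform, \
    TissueMask, TransformSet


@dataclass
class CostConfig:
    """Weights and sizes of the stitching cost.

    ``w1``/``w2 = 1 - w1`` weight dissimilarity vs. misalignment; ``w3``
    (inner) / ``w4 = 1 - w3`` (outer) weight the two endpoint pairs of the
    misalignment term.  ``p`` is the square patch side and ``tau`` the
    correspondence cutoff, both in base-resolution pixels (``tau=None``
    defaults to the patch radius at the current level); ``b`` is the
    histogram bin count.
    """

    w1: float = 0.989
    w3: float = 0.4
    p: int = 81
    b: int = 16
    tau: float = None
    max_edge_pixels: int = 200

    def __post_init__(self) -> None:
        if not (0.0 <= self.w1 <= 1.0 and 0.0 <= self.w3 <= 1.0):
            raise ValueError("weights must lie in [0, 1]")
        if self.b < 2:
            raise ValueError("need at least 2 histogram bins")
        if self.p < 1 or self.p % 2 == 0:
            raise ValueError("patch side p must be odd and >= 1")

    @property
    def w2(self) -> float:
        return 1.0 - self.w1

    @property
    def w4(self) -> float:
        return 1.0 - self.w3

    def p_at(self, factor: int) -> int:
        """Patch side at a pyramid level (constant real-world size)."""
        return max(1, round(self.p / factor))

    def phi_at(self, factor: int) -> float:
        """Maximum dissimilarity: 2 between histograms, 1 between pixels."""
        return 2.0 if self.p_at(factor) > 1 else 1.0

    def tau_at(self, factor: int) -> float:
        """Correspondence cutoff in base-resolution px."""
        if self.tau is not None:
            return float(self.tau)
        return max(1, self.p_at(factor) // 2) * factor


@dataclass
class IntensityHistogram:
    """Patch descriptor: a b-bin probability density, or one intensity."""

    values: np.ndarray  # (b,) normalized histogram, or scalar array in pixel mode
    mode: str           # "histogram" | "pixel"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.mode not in ("histogram", "pixel"):
            raise ValueError("mode must be 'histogram' or 'pixel'")


@dataclass
class CorrespondenceSet:
    """Matched edge-pixel pairs for one adjacency, in the common frame."""

    pairs: np.ndarray   # (n, 2, 2): pairs of (x, y) points
    n: int
    m: int


def patch_vector(img: GrayImage, mask: TissueMask, center, p: int, b: int):
    """Histogram (or pixel-mode) descriptor of the patch centered at ``center``.

    Background (non-tissue) pixels are excluded; a window with no tissue
    pixels returns ``None`` and the caller treats that edge pixel as
    non-corresponding.  ``p == 1`` switches to pixel mode.
    """
    x, y = int(round(center[0])), int(round(center[1]))
    if not (0 <= x < img.width and 0 <= y < img.height):
        raise ValueError(f"patch center {center} outside image")
    if p == 1:
        if not mask.bits[y, x]:
            return None
        return IntensityHistogram(np.float64(img.pixels[y, x]), "pixel")
    r = p // 2
    y0, y1 = max(0, y - r), min(img.height, y + r + 1)
    x0, x1 = max(0, x - r), min(img.width, x + r + 1)
    window = img.pixels[y0:y1, x0:x1]
    tissue = mask.bits[y0:y1, x0:x1]
    vals = window[tissue]
    if vals.size == 0:
        return None
    hist, _ = np.histogram(vals, bins=b, range=(0.0, 1.0))
    return IntensityHistogram(hist / hist.sum(), "histogram")


def l1_dissimilarity(v1: IntensityHistogram, v2: IntensityHistogram) -> float:
    """L1 distance between two patch descriptors; in [0, phi]."""
    if v1.mode != v2.mode:
        raise ValueError("descriptor modes differ")
    if v1.mode == "histogram" and v1.values.shape != v2.values.shape:
        raise ValueError("histogram bin counts differ")
    return float(np.abs(v1.values - v2.values).sum())


def _subsample(arr: np.ndarray, cap: int) -> np.ndarray:
    if len(arr) <= cap:
        return arr
    idx = np.linspace(0, len(arr) - 1, cap).round().astype(int)
    return arr[np.unique(idx)]


def _mutual_nn(ptsA: np.ndarray, ptsB: np.ndarray, tau: float):
    """Mutual-nearest-neighbour matching with distance cutoff ``tau``.

    Returns (idxA, idxB) of matched pairs.
    """
    if len(ptsA) == 0 or len(ptsB) == 0:
        return np.empty(0, int), np.empty(0, int)
    treeB = cKDTree(ptsB)
    dA, ab = treeB.query(ptsA)
    treeA = cKDTree(ptsA)
    dB, ba = treeA.query(ptsB)
    ia = np.arange(len(ptsA))
    mutual = (ba[ab] == ia) & (dA <= tau)
    return ia[mutual], ab[mutual]


def find_correspondences(qA: Quadrant, qB: Quadrant, tA: RigidTransform,
                         tB: RigidTransform, tau: float,
                         orientation: str = None,
                         max_edge_pixels: int = 200) -> CorrespondenceSet:
    """Corresponding edge pixels of two adjacent quadrants in the common frame.

    Facing-edge pixel lists are mapped through the quadrant transforms and
    matched by mutual nearest neighbour with cutoff ``tau``; ``m`` counts the
    edge pixels from both edges left unmatched.
    """
    if qA.edges is None or qB.edges is None:
        raise RuntimeError("edge geometry missing; run detect_corners_and_edges")
    if orientation is None:
        orientation = _facing_orientation(qA.label, qB.label)
    eA = _subsample(qA.edges.edges[orientation].pixels, max_edge_pixels)
    eB = _subsample(qB.edges.edges[orientation].pixels, max_edge_pixels)
    pA = tA.apply(eA)
    pB = tB.apply(eB)
    ia, ib = _mutual_nn(pA, pB, tau)
    pairs = np.stack([pA[ia], pB[ib]], axis=1) if len(ia) else \
        np.empty((0, 2, 2))
    n = len(ia)
    m = (len(pA) - n) + (len(pB) - n)
    return CorrespondenceSet(pairs, n, m)


def _facing_orientation(a: str, b: str) -> str:
    for la, lb, orient in ADJACENCIES:
        if {la, lb} == {a, b}:
            return orient
    raise ValueError(f"{a!r} and {b!r} are not adjacent")


class _EdgeDescriptors:
    """Precomputed per-edge data for fast repeated cost evaluation."""

    def __init__(self, q: Quadrant, orientation: str, factor: int,
                 cfg: CostConfig):
        edge = q.edges.edges[orientation]
        px = _subsample(edge.pixels, cfg.max_edge_pixels)
        p_level = cfg.p_at(factor)
        descs = []
        valid = np.zeros(len(px), dtype=bool)
        for i, (x, y) in enumerate(px):
            d = patch_vector(q.image, q.mask, (x, y), p_level, cfg.b)
            if d is not None:
                valid[i] = True
                descs.append(np.atleast_1d(d.values))
            else:
                descs.append(None)
        dim = 1 if p_level == 1 else cfg.b
        self.hist = np.zeros((len(px), dim))
        for i, d in enumerate(descs):
            if d is not None:
                self.hist[i] = d
        self.valid = valid
        self.coords_base = px * factor          # local frame, base-res px
        self.c_in_base = edge.c_in * factor
        self.c_out_base = edge.c_out * factor
        self.total = len(px)


class CostEvaluator:
    """Evaluates the stitching cost repeatedly at one pyramid level.

    Edge pixels, patch descriptors, and line endpoints are precomputed in each
    quadrant's local frame (patch content does not depend on the candidate
    pose); per candidate only coordinates are transformed and re-matched.
    All distances are kept in base-resolution pixels so the weights transfer
    unchanged across pyramid levels.
    """

    def __init__(self, level_qs: dict, factor: int, cfg: CostConfig = None):
        self.cfg = cfg or CostConfig()
        self.factor = int(factor)
        self.phi = self.cfg.phi_at(self.factor)
        self.tau = self.cfg.tau_at(self.factor)
        self.centers = {}
        self.desc = {}
        for lbl, q in level_qs.items():
            if q.edges is None:
                q.edges = detect_corners_and_edges(q)
            self.centers[lbl] = q.mask.centroid() * self.factor
            for orient in ("horizontal", "vertical"):
                self.desc[(lbl, orient)] = _EdgeDescriptors(
                    q, orient, self.factor, self.cfg)

    def transform_for(self, lbl: str, tx: float, ty: float,
                      theta: float) -> RigidTransform:
        return RigidTransform(tx, ty, theta, center=tuple(self.centers[lbl]))

    def pair_terms(self, la: str, lb: str, orient: str, ta: RigidTransform,
                   tb: RigidTransform):
        """(D_pair, M_pair) for one adjacency under candidate poses."""
        da = self.desc[(la, orient)]
        db = self.desc[(lb, orient)]
        pa = ta.apply(da.coords_base)
        pb = tb.apply(db.coords_base)
        ia, ib = _mutual_nn(pa[da.valid], pb[db.valid], self.tau)
        n = len(ia)
        m = (da.total - n) + (db.total - n)
        if n + m == 0:
            d_pair = self.phi
        else:
            if n:
                ha = da.hist[da.valid][ia]
                hb = db.hist[db.valid][ib]
                ssum = float(np.abs(ha - hb).sum())
            else:
                ssum = 0.0
            d_pair = (ssum + m * self.phi) / (n + m)
        cin_a = ta.apply(da.c_in_base)[0]
        cin_b = tb.apply(db.c_in_base)[0]
        cout_a = ta.apply(da.c_out_base)[0]
        cout_b = tb.apply(db.c_out_base)[0]
        m_pair = self.cfg.w3 * np.linalg.norm(cin_a - cin_b) \
            + self.cfg.w4 * np.linalg.norm(cout_a - cout_b)
        return d_pair, float(m_pair)

    def components(self, transforms: dict):
        """(D_tot, M_tot): means of the four pair terms."""
        ds, ms = [], []
        for la, lb, orient in ADJACENCIES:
            d, m = self.pair_terms(la, lb, orient, transforms[la],
                                   transforms[lb])
            ds.append(d)
            ms.append(m)
        return float(np.mean(ds)), float(np.mean(ms))

    def cost_of_transforms(self, transforms: dict) -> float:
        d_tot, m_tot = self.components(transforms)
        return self.cfg.w1 * d_tot + self.cfg.w2 * m_tot

    def transforms_from_vector(self, vec: np.ndarray) -> dict:
        """9-vector (tx, ty, theta for ur, ll, lr) -> transform dict."""
        vec = np.asarray(vec, dtype=float)
        t = {"ul": self.transform_for("ul", 0.0, 0.0, 0.0)}
        for i, lbl in enumerate(("ur", "ll", "lr")):
            tx, ty, th = vec[3 * i: 3 * i + 3]
            t[lbl] = self.transform_for(lbl, tx, ty, th)
        return t

    def cost(self, vec: np.ndarray) -> float:
        return self.cost_of_transforms(self.transforms_from_vector(vec))


def pair_dissimilarity(qA: Quadrant, qB: Quadrant, tA: RigidTransform,
                       tB: RigidTransform, cfg: CostConfig = None,
                       factor: int = 1) -> float:
    """Pooled dissimilarity of one adjacency.

    ``(sum of matched-pair L1 distances + m * phi) / (n + m)``; empty-patch
    pixels are treated as non-corresponding (maximally dissimilar).
    """
    cfg = cfg or CostConfig()
    ev = CostEvaluator({qA.label: qA, qB.label: qB}, factor, cfg)
    orient = _facing_orientation(qA.label, qB.label)
    d, _ = ev.pair_terms(qA.label, qB.label, orient, tA, tB)
    return d


def pair_misalignment(edgeA, edgeB, tA: RigidTransform, tB: RigidTransform,
                      cfg: CostConfig = None, factor: int = 1) -> float:
    """w3 * |C_in^1 - C_in^2| + w4 * |C_out^1 - C_out^2| in base-res px."""
    cfg = cfg or CostConfig()
    if edgeA.c_in is None or edgeB.c_in is None:
        raise RuntimeError("edge endpoints missing")
    cin_a = tA.apply(edgeA.c_in * factor)[0]
    cin_b = tB.apply(edgeB.c_in * factor)[0]
    cout_a = tA.apply(edgeA.c_out * factor)[0]
    cout_b = tB.apply(edgeB.c_out * factor)[0]
    return float(cfg.w3 * np.linalg.norm(cin_a - cin_b)
                 + cfg.w4 * np.linalg.norm(cout_a - cout_b))


def total_cost(qs: QuadrantSet, ts: TransformSet, cfg: CostConfig = None,
               factor: int = 1) -> float:
    """w1 * D_tot + w2 * M_tot over the four adjacent quadrant pairs."""
    cfg = cfg or CostConfig()
    ev = CostEvaluator(dict(qs.items()), factor, cfg)
    return ev.cost_of_transforms({lbl: ts[lbl] for lbl, _ in qs.items()})
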