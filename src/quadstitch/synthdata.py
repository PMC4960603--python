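"""Synthetic pseudo-histology phantoms with known ground truth.

The generator emulates the three properties that make fragment reassembly
hard: the four quadrants are cut from a single object so they never overlap;
a kerf-wide band of tissue is destroyed along each cut (incompleteness); and
the wavy cut boundaries do not interlock.  Each quadrant is then perturbed by
an independent rigid transform whose inverse is recorded as ground truth,
together with landmark pairs straddling each cut for fiducial-style scoring.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import imageio.v3 as iio
import pandas as pd
from scipy import ndimage

from .raster_core import (
    GrayImage, Quadrant, QuadrantSet, RigidTransform, TissueMask, TransformSet,
    apply_transform,
)


class GenerationError(RuntimeError):
    """A fragment specification destroyed too much tissue."""


@dataclass
class PhantomSpec:
    """Parameters of the uncut pseudo-tissue section.

    A dark textured ellipse (stroma) carries bright elliptical blobs (gland
    lumina) on a near-white background; a slowly varying intensity field makes
    patches from different regions distinguishable by their histograms.
    """

    seed: int = 0
    canvas_px: int = 512
    ellipse_axes_frac: tuple = (0.42, 0.34)  # of canvas, (x, y) semi-axes
    eccentricity_jitter: float = 0.03
    gland_density_per_1e4px2: float = 8.0
    gland_radius_px: tuple = (3, 10)
    background_intensity: float = 0.97
    tissue_intensity: float = 0.45
    texture_sigma: float = 0.06
    scale_um_per_px: float = 8.0

    def __post_init__(self) -> None:
        if self.canvas_px < 32:
            raise ValueError("canvas too small")
        if max(self.ellipse_axes_frac) >= 0.5:
            raise ValueError("tissue ellipse larger than canvas")
        if self.gland_density_per_1e4px2 < 0:
            raise ValueError("density must be >= 0")


@dataclass
class FragmentSpec:
    """Parameters of the cutting / perturbation process."""

    seed: int = 0
    cut_amplitude_px: float = 6.0
    cut_frequency: float = 2.0
    kerf_px: float = 0.0
    translation_range_px: float = 5.0
    rotation_range_deg: float = 3.0
    flip_probability: float = 0.0
    bite_count: int = 0
    bite_radius_px: float = 10.0
    landmarks_per_cut: int = 9
    pad_px: int = 8

    def __post_init__(self) -> None:
        if self.kerf_px < 0 or self.translation_range_px < 0 or \
                self.rotation_range_deg < 0:
            raise ValueError("ranges must be >= 0")


#: difficulty presets mirroring a spectrum from clean cuts to heavy tissue loss
PRESETS = {
    "easy": dict(kerf_px=0.0, translation_range_px=5.0, rotation_range_deg=3.0,
                 bite_count=0),
    "medium": dict(kerf_px=5.0, translation_range_px=10.0,
                   rotation_range_deg=8.0, bite_count=0),
    "hard": dict(kerf_px=12.0, translation_range_px=20.0,
                 rotation_range_deg=15.0, bite_count=3),
}


def preset_fragment_spec(name: str, seed: int = 0) -> FragmentSpec:
    if name not in PRESETS:
        raise KeyError(f"unknown preset {name!r}; choose from {sorted(PRESETS)}")
    return FragmentSpec(seed=seed, **PRESETS[name])


@dataclass
class GroundTruth:
    """True poses and landmark correspondences for one fragmented phantom."""

    transforms: TransformSet          # relative to ul (identity)
    ul_pose: RigidTransform           # ul local frame -> phantom frame
    cut_lines: dict                   # {"vertical": (N,2), "horizontal": (N,2)}
    landmarks: pd.DataFrame           # cut, label_a, xa, ya, label_b, xb, yb
    phantom_mask: TissueMask


def generate_phantom(spec: PhantomSpec):
    """Render the uncut phantom; returns (GrayImage, TissueMask)."""
    rng = np.random.default_rng(spec.seed)
    n = spec.canvas_px
    yy, xx = np.mgrid[0:n, 0:n]
    cx = cy = (n - 1) / 2.0
    ax = spec.ellipse_axes_frac[0] * n * \
        (1.0 + rng.uniform(-spec.eccentricity_jitter, spec.eccentricity_jitter))
    ay = spec.ellipse_axes_frac[1] * n * \
        (1.0 + rng.uniform(-spec.eccentricity_jitter, spec.eccentricity_jitter))
    mask = ((xx - cx) / ax) ** 2 + ((yy - cy) / ay) ** 2 <= 1.0

    img = np.full((n, n), spec.background_intensity)
    tissue = np.full((n, n), spec.tissue_intensity)
    # slowly varying field so different regions have distinct histograms
    slow = ndimage.gaussian_filter(rng.normal(0.0, 1.0, (n, n)), n / 12.0)
    denom = max(1e-9, float(np.abs(slow).max()))
    tissue += 0.12 * slow / denom
    # fine spatially correlated texture
    fine = ndimage.gaussian_filter(rng.normal(0.0, 1.0, (n, n)), 1.5)
    tissue += spec.texture_sigma * fine / max(1e-9, fine.std())

    area = float(mask.sum())
    n_glands = rng.poisson(spec.gland_density_per_1e4px2 * area / 1e4) \
        if spec.gland_density_per_1e4px2 > 0 else 0
    ys, xs = np.nonzero(mask)
    for _ in range(int(n_glands)):
        i = rng.integers(0, len(xs))
        gx, gy = xs[i], ys[i]
        r1 = rng.uniform(*spec.gland_radius_px)
        r2 = r1 * rng.uniform(0.6, 1.0)
        ang = rng.uniform(0, np.pi)
        dx, dy = xx - gx, yy - gy
        rx = dx * np.cos(ang) + dy * np.sin(ang)
        ry = -dx * np.sin(ang) + dy * np.cos(ang)
        blob = (rx / r1) ** 2 + (ry / r2) ** 2 <= 1.0
        tissue[blob] = rng.uniform(0.85, 0.95)

    img[mask] = tissue[mask]
    return GrayImage(np.clip(img, 0.0, 1.0), spec.scale_um_per_px), \
        TissueMask(mask)


def _cut_profiles(mask: TissueMask, spec: FragmentSpec, rng):
    """Wavy vertical and horizontal cut lines through the tissue centroid."""
    cx, cy = mask.centroid()
    rows, cols = mask.bits.shape
    ph_v, ph_h = rng.uniform(0, 2 * np.pi, 2)
    y = np.arange(rows)
    x = np.arange(cols)
    xcut = cx + spec.cut_amplitude_px * np.sin(
        2 * np.pi * spec.cut_frequency * y / rows + ph_v)
    ycut = cy + spec.cut_amplitude_px * np.sin(
        2 * np.pi * spec.cut_frequency * x / cols + ph_h)
    return xcut, ycut


def fragment_phantom(img: GrayImage, mask: TissueMask, spec: FragmentSpec):
    """Cut, damage and perturb the phantom; returns (QuadrantSet, GroundTruth).

    Two wavy cuts through the tissue centroid partition the section; a band of
    ``kerf_px`` is deleted along each cut; each quadrant is cropped, optionally
    bitten, and perturbed by a rigid transform sampled from the spec ranges.
    """
    rng = np.random.default_rng(spec.seed)
    rows, cols = mask.bits.shape
    yy, xx = np.mgrid[0:rows, 0:cols]
    xcut, ycut = _cut_profiles(mask, spec, rng)
    left = xx < xcut[yy]
    top = yy < ycut[xx]
    keep = np.ones_like(mask.bits)
    if spec.kerf_px > 0:
        keep &= np.abs(xx - xcut[yy]) >= spec.kerf_px / 2.0
        keep &= np.abs(yy - ycut[xx]) >= spec.kerf_px / 2.0

    regions = {
        "ul": top & left, "ur": top & ~left,
        "ll": ~top & left, "lr": ~top & ~left,
    }
    quadrants = {}
    poses = {}
    for lbl, region in regions.items():
        qmask = mask.bits & region & keep
        if spec.bite_count > 0:
            qmask = _apply_bites(qmask, spec, rng)
        if qmask.sum() < 50:
            raise GenerationError(
                f"quadrant {lbl!r} nearly destroyed (kerf/bites too large)")
        ys, xs = np.nonzero(qmask)
        pad = spec.pad_px
        y0, y1 = max(0, ys.min() - pad), min(rows, ys.max() + pad + 1)
        x0, x1 = max(0, xs.min() - pad), min(cols, xs.max() + pad + 1)
        cmask = qmask[y0:y1, x0:x1]
        cimg = np.where(cmask, img.pixels[y0:y1, x0:x1], 1.0)
        offset = np.array([x0, y0], dtype=float)

        # sample the perturbation applied to the scanned fragment
        dx, dy = rng.uniform(-spec.translation_range_px,
                             spec.translation_range_px, 2)
        dth = rng.uniform(-spec.rotation_range_deg, spec.rotation_range_deg)
        cq = Quadrant(lbl, GrayImage(cimg, img.scale_um_per_px),
                      TissueMask(cmask))
        centroid = cq.mask.centroid()
        pert = RigidTransform(dx, dy, dth, center=tuple(centroid))
        lo, hi = _extent(cq.mask, pert)
        g = np.floor(lo) - pad
        shape = (int(np.ceil(hi[1] - g[1])) + 1 + pad,
                 int(np.ceil(hi[0] - g[0])) + 1 + pad)
        rimg, rmask = apply_transform(cq, pert, shape, origin=g)

        # rendered (un-flipped) -> phantom: shift by render origin, invert the
        # perturbation, shift by crop offset; poses therefore apply to the
        # un-flipped frame and consumers must undo a recorded flip first
        M_pert_inv = np.linalg.inv(pert.matrix())
        T_g = np.eye(3); T_g[:2, 2] = g
        T_o = np.eye(3); T_o[:2, 2] = offset
        M = T_o @ M_pert_inv @ T_g
        rc = rmask.centroid()

        flipped = bool(rng.uniform() < spec.flip_probability)
        if flipped:
            rimg = GrayImage(np.fliplr(rimg.pixels), rimg.scale_um_per_px)
            rmask = TissueMask(np.fliplr(rmask.bits))

        quadrants[lbl] = Quadrant(lbl, rimg, rmask)
        poses[lbl] = RigidTransform.from_matrix(M, center=tuple(rc),
                                                flip_h=flipped)

    gt_ts = _relative_to_ul(quadrants, poses)
    landmarks = _sample_landmarks(mask, regions, keep, xcut, ycut, poses, spec)
    cut_lines = {
        "vertical": np.column_stack([xcut, np.arange(rows)]).astype(float),
        "horizontal": np.column_stack([np.arange(cols), ycut]).astype(float),
    }
    gt = GroundTruth(gt_ts, poses["ul"], cut_lines, landmarks, mask)
    return QuadrantSet(quadrants), gt


def _apply_bites(qmask: np.ndarray, spec: FragmentSpec, rng) -> np.ndarray:
    """Remove random disks of tissue near the fragment boundary."""
    out = qmask.copy()
    boundary = qmask & ~ndimage.binary_erosion(qmask, iterations=2)
    ys, xs = np.nonzero(boundary)
    if len(xs) == 0:
        return out
    yy, xx = np.mgrid[0:qmask.shape[0], 0:qmask.shape[1]]
    for _ in range(spec.bite_count):
        i = rng.integers(0, len(xs))
        r = spec.bite_radius_px * rng.uniform(0.5, 1.0)
        out &= (xx - xs[i]) ** 2 + (yy - ys[i]) ** 2 > r ** 2
    return out


def _relative_to_ul(quadrants: dict, poses: dict) -> TransformSet:
    """Express phantom-frame poses relative to the ul quadrant (identity)."""
    M_ul_inv = np.linalg.inv(poses["ul"].matrix())
    out = {}
    for lbl, q in quadrants.items():
        M = M_ul_inv @ poses[lbl].matrix()
        out[lbl] = RigidTransform.from_matrix(
            M, center=tuple(q.mask.centroid()), flip_h=poses[lbl].flip_h)
    out["ul"] = RigidTransform(center=out["ul"].center,
                               flip_h=poses["ul"].flip_h)
    return TransformSet(out, "ul")


def _sample_landmarks(mask, regions, keep, xcut, ycut, poses, spec):
    """Corresponding point pairs straddling each cut, in local quadrant frames."""
    rows, cols = mask.bits.shape
    gap = spec.kerf_px / 2.0 + 2.0
    inv = {lbl: np.linalg.inv(p.matrix()) for lbl, p in poses.items()}
    records = []

    def to_local(lbl, pt):
        v = inv[lbl] @ np.array([pt[0], pt[1], 1.0])
        if poses[lbl].flip_h:
            pass  # flips recorded but not sampled by default presets
        return v[:2]

    def valid(lbl, pt):
        x, y = int(round(pt[0])), int(round(pt[1]))
        return 0 <= x < cols and 0 <= y < rows and \
            mask.bits[y, x] and keep[y, x] and regions[lbl][y, x]

    # vertical cut: pairs (left, right); adjacency depends on y vs horiz cut
    for cut, n_axis in (("vertical", rows), ("horizontal", cols)):
        found = []
        for coord in np.linspace(5, n_axis - 6, 4 * spec.landmarks_per_cut):
            c = int(round(coord))
            if cut == "vertical":
                pa = (xcut[c] - gap, c)
                pb = (xcut[c] + gap, c)
                la = "ul" if c < ycut[int(round(xcut[c]))] else "ll"
                lb = "ur" if la == "ul" else "lr"
            else:
                pa = (c, ycut[c] - gap)
                pb = (c, ycut[c] + gap)
                la = "ul" if c < xcut[int(round(ycut[c]))] else "ur"
                lb = "ll" if la == "ul" else "lr"
            if valid(la, pa) and valid(lb, pb):
                a = to_local(la, pa)
                b = to_local(lb, pb)
                found.append((cut, la, a[0], a[1], lb, b[0], b[1]))
        if len(found) < spec.landmarks_per_cut:
            raise GenerationError(f"could not place {spec.landmarks_per_cut} "
                                  f"landmarks on the {cut} cut")
        idx = np.linspace(0, len(found) - 1,
                          max(spec.landmarks_per_cut, min(len(found), 12))
                          ).round().astype(int)
        for i in np.unique(idx):
            records.append(found[i])
    return pd.DataFrame(records, columns=[
        "cut", "label_a", "xa", "ya", "label_b", "xb", "yb"])


def _extent(mask: TissueMask, t: RigidTransform):
    ys, xs = np.nonzero(mask.bits)
    corners = np.array([
        [xs.min(), ys.min()], [xs.max(), ys.min()],
        [xs.min(), ys.max()], [xs.max(), ys.max()],
    ], dtype=float)
    out = t.apply(corners)
    return out.min(axis=0), out.max(axis=0)


def _to_uint16(img: GrayImage) -> np.ndarray:
    return np.round(img.pixels * 65535).astype(np.uint16)


def write_fixture(directory, qs: QuadrantSet, gt: GroundTruth,
                  meta: dict = None) -> dict:
    """Write a fixture directory: quadrant PNGs, truth JSON, landmarks CSV.

    Images are stored as 16-bit grayscale PNGs so a read round-trips the
    stored arrays exactly.  Returns the mapping of written paths.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {}
    for lbl, q in qs.items():
        p = directory / f"{lbl}.png"
        iio.imwrite(p, _to_uint16(q.image))
        pm = directory / f"{lbl}_mask.png"
        iio.imwrite(pm, (q.mask.bits.astype(np.uint8) * 255))
        paths[lbl] = p
    phantom_path = directory / "phantom_mask.png"
    iio.imwrite(phantom_path, gt.phantom_mask.bits.astype(np.uint8) * 255)
    truth = {
        "transforms": json.loads(gt.transforms.to_json()),
        "ul_pose": {
            "tx": gt.ul_pose.tx, "ty": gt.ul_pose.ty,
            "theta": gt.ul_pose.theta, "flip_h": gt.ul_pose.flip_h,
            "center": list(gt.ul_pose.center),
        },
    }
    (directory / "ground_truth.json").write_text(
        json.dumps(truth, indent=2, sort_keys=True))
    gt.landmarks.to_csv(directory / "landmarks.csv", index=False)
    if meta:
        (directory / "meta.json").write_text(
            json.dumps(meta, indent=2, sort_keys=True, default=str))
    paths["ground_truth"] = directory / "ground_truth.json"
    paths["landmarks"] = directory / "landmarks.csv"
    return paths


def make_fixture(phantom_spec: PhantomSpec = None,
                 fragment_spec: FragmentSpec = None):
    """Convenience: generate and fragment in one call."""
    phantom_spec = phantom_spec or PhantomSpec()
    fragment_spec = fragment_spec or FragmentSpec()
    img, mask = generate_phantom(phantom_spec)
    qs, gt = fragment_phantom(img, mask, fragment_spec)
    return img, mask, qs, gt
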