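"""Shared synthetic fixtures, generated programmatically at test time."""

import numpy as np
import pytest

import quadstitch as q


@pytest.fixture(scope="session")
def small_phantom():
    """A 256-px phantom image + mask (deterministic)."""
    return q.generate_phantom(q.PhantomSpec(seed=7, canvas_px=256))


@pytest.fixture(scope="session")
def easy_fixture(small_phantom):
    """Easy-preset fragmentation of the small phantom with ground truth."""
    img, mask = small_phantom
    qs, gt = q.fragment_phantom(img, mask, q.preset_fragment_spec("easy", seed=7))
    return qs, gt


@pytest.fixture(scope="session")
def clean_cut_fixture():
    """Kerf-0, zero-perturbation fragmentation (identity ground truth)."""
    img, mask = q.generate_phantom(q.PhantomSpec(seed=3, canvas_px=256))
    spec = q.FragmentSpec(seed=3, kerf_px=0.0, translation_range_px=0.0,
                          rotation_range_deg=0.0)
    qs, gt = q.fragment_phantom(img, mask, spec)
    return qs, gt


def worst_pose_error(transforms, gt):
    """Max centroid-displacement (px) and rotation (deg) error over movers."""
    worst_d = worst_t = 0.0
    for lbl in ("ur", "ll", "lr"):
        t_rec, t_true = transforms[lbl], gt.transforms[lbl]
        c = np.array(t_true.center)
        worst_d = max(worst_d,
                      float(np.linalg.norm(t_rec.apply(c) - t_true.apply(c))))
        worst_t = max(worst_t, abs(t_rec.theta - t_true.theta))
    return worst_d, worst_t
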