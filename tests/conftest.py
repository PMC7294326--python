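"""Shared fixtures: simulated lobules and derived pipeline products."""

from __future__ import annotations

import pytest

from lobulemorph import morphometry as M
from lobulemorph import segmentation as S
from lobulemorph import synthetic as Y
from lobulemorph import topology as T

N_SEEDS = 10


@pytest.fixture(scope="session")
def noise_free_case():
    """One noise-free rendered lobule with its ground truth (seed 0)."""
    lob, img, gt = Y.simulate_lobule(seed=0, noise_sd=0.0)
    return lob, img, gt


@pytest.fixture(scope="session")
def ten_lobules():
    """Default-condition lobules (rendered with imaging noise), seeds 0-9."""
    return [Y.simulate_lobule(seed=seed) for seed in range(N_SEEDS)]


def frame_of(lob):
    return M.LobuleFrame(cv_centroid=lob.cv_centroid, boundary=lob.lobule_radius)


@pytest.fixture(scope="session")
def ten_gt_profiles(ten_lobules):
    """Ground-truth radial profiles for the ten default lobules."""
    out = []
    for lob, _, gt in ten_lobules:
        out.append(M.radial_profile(gt.objects, gt.branch_points, gt.masks,
                                    frame_of(lob), n_bins=10))
    return out


@pytest.fixture(scope="session")
def ten_detected_branch_points(ten_lobules):
    """Branch points detected by the full pipeline on the noisy renders."""
    out = []
    for lob, img, _ in ten_lobules:
        masks = S.segment_classes(img, "auto", scale=lob.scale)
        skel = T.skeletonize_vessels(masks.vessel, scale=lob.scale)
        out.append(T.detect_branch_points(skel, merge_radius=5.0))
    return out
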