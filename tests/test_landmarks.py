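import itertools

import numpy as np
import pytest

from conftest import digital_ball
from ctmorph.landmarks import (
    LandmarkSet,
    detect_lenses,
    find_landmarks,
    label_regions,
    similarity_from_landmarks,
    sphericity,
)
from ctmorph.preprocess import BinaryMask, compute_body_mask
from ctmorph.register import AffineTransform
from ctmorph.volio import Volume3D


def test_single_ball_is_one_highly_spherical_region():
    mask = BinaryMask(digital_ball(12))
    regions = label_regions(mask)
    assert len(regions) == 1
    assert regions[0].sphericity >= 0.97
    assert regions[0].voxel_count == int(mask.data.sum())


def test_cube_sphericity_matches_analytic():
    cube = np.pad(np.ones((20, 20, 20), bool), 2)
    regions = label_regions(BinaryMask(cube))
    analytic = np.pi ** (1 / 3) * 6 ** (2 / 3) / 6  # 0.806
    assert regions[0].sphericity == pytest.approx(analytic, abs=0.05)


def test_two_balls_two_regions_with_exact_voxel_volumes():
    grid = np.zeros((40, 24, 24), bool)
    b1 = digital_ball(6, pad=2)
    b2 = digital_ball(4, pad=2)
    grid[1 : 1 + b1.shape[0], 2 : 2 + b1.shape[1], 2 : 2 + b1.shape[2]] = b1
    grid[25 : 25 + b2.shape[0], 5 : 5 + b2.shape[1], 5 : 5 + b2.shape[2]] = b2
    regions = sorted(label_regions(BinaryMask(grid)), key=lambda r: -r.voxel_count)
    assert len(regions) == 2
    assert regions[0].voxel_count == int(b1.sum())
    assert regions[1].voxel_count == int(b2.sum())


def test_sphericity_of_digitised_convex_bodies_bounded():
    for r in (6, 9, 12):
        regions = label_regions(BinaryMask(digital_ball(r)))
        assert regions[0].sphericity <= 1.02


def _lens_scene(extra_objects=True):
    """Body block with two equal dark spheres and optional decoys (a larger
    dark sphere and an elongated dark tube)."""
    data = np.full((60, 48, 48), 120.0)
    truth = {}

    def carve_ball(c, r, tag):
        zz, yy, xx = np.indices(data.shape)
        m = (zz - c[0]) ** 2 + (yy - c[1]) ** 2 + (xx - c[2]) ** 2 <= r**2
        data[m] = 20.0
        truth[tag] = m

    carve_ball((15, 12, 24), 6, "lens_a")
    carve_ball((15, 36, 24), 6, "lens_b")
    if extra_objects:
        carve_ball((40, 14, 14), 9, "decoy_ball")
        zz, yy, xx = np.indices(data.shape)
        tube = ((yy - 36) ** 2 + (xx - 36) ** 2 <= 3**2) & (zz > 30) & (zz < 55)
        data[tube] = 20.0
    vol = Volume3D(np.pad(data, 2, constant_values=0.0))
    body = BinaryMask(np.pad(np.ones((60, 48, 48), bool), 2))
    return vol, body, truth


def brute_force_lens_pair(candidates):
    """Oracle: exhaustive scoring of all candidate pairs by volume
    self-similarity, tie-broken by sphericity sum."""
    best = None
    for a, b in itertools.combinations(candidates, 2):
        s = abs(a.volume - b.volume) / (a.volume + b.volume)
        key = (round(s, 12), -round(a.sphericity + b.sphericity, 12))
        if best is None or key < best[0]:
            best = (key, (a, b))
    return best[1]


def test_detect_lenses_picks_equal_spheres_over_decoys():
    vol, body, truth = _lens_scene()
    left, right = detect_lenses(vol, body)
    assert left.centroid[1] < right.centroid[1]
    for r, tag in ((left, "lens_a"), (right, "lens_b")):
        c = np.asarray(r.centroid) - 2  # padding offset
        assert np.linalg.norm(c - np.argwhere(truth[tag]).mean(axis=0)) < 1.0


def test_detect_lenses_matches_exhaustive_pair_oracle():
    vol, body, _ = _lens_scene()
    from ctmorph.preprocess import otsu_threshold

    t = otsu_threshold(vol)
    water = (vol.data <= t) & body.data
    regions = label_regions(BinaryMask(water))
    candidates = [r for r in regions if r.sphericity >= 0.85 and r.voxel_count >= 100]
    expect = brute_force_lens_pair(candidates)
    got = detect_lenses(vol, body)
    assert {g.centroid for g in got} == {e.centroid for e in expect}


def test_detect_lenses_twins_only():
    vol, body, _ = _lens_scene(extra_objects=False)
    left, right = detect_lenses(vol, body)
    assert abs(left.volume - right.volume) / (left.volume + right.volume) < 0.01


def test_detect_lenses_single_candidate_errors():
    data = np.full((40, 32, 32), 120.0)
    zz, yy, xx = np.indices(data.shape)
    data[(zz - 15) ** 2 + (yy - 16) ** 2 + (xx - 16) ** 2 <= 36] = 20.0
    vol = Volume3D(np.pad(data, 2, constant_values=0.0))
    body = BinaryMask(np.pad(np.ones(data.shape, bool), 2))
    with pytest.raises(ValueError, match="lenses not found"):
        detect_lenses(vol, body)


def test_find_landmarks_on_phantom(small_phantom, small_spec):
    vol, labels = small_phantom
    mask = compute_body_mask(vol)
    lms = find_landmarks(vol, mask)
    # lens centroids match the generator's ground truth within a voxel
    for lid, point in ((1, lms.lens_left), (2, lms.lens_right)):
        truth = np.argwhere(labels.data == lid).mean(axis=0)
        assert np.linalg.norm(np.asarray(point) - truth) < 1.0
    # tail point lies in the posterior 30% slab
    zs = np.flatnonzero(mask.data.any(axis=(1, 2)))
    assert lms.tail[0] >= zs[-1] - 0.30 * (zs[-1] - zs[0]) - 1
    # deterministic across calls
    again = find_landmarks(vol, mask)
    assert lms.as_array() == pytest.approx(again.as_array())


def test_landmarks_translate_with_the_volume(small_phantom):
    vol, _ = small_phantom
    mask = compute_body_mask(vol)
    lms = find_landmarks(vol, mask)
    def shift_z(arr, fill):  # shift posteriorly by 2 (fits the z margin)
        out = np.full_like(arr, fill)
        out[2:] = arr[:-2]
        return out

    shifted_vol = Volume3D(shift_z(vol.data, 0.0), vol.spacing)
    shifted_mask = BinaryMask(shift_z(mask.data, False), mask.spacing)
    shifted = find_landmarks(shifted_vol, shifted_mask)
    np.testing.assert_allclose(
        shifted.as_array() - lms.as_array(),
        np.tile([2.0 * vol.spacing[0], 0, 0], (3, 1)),
        atol=0.6,
    )


def _lm(points):
    return LandmarkSet(tuple(points[0]), tuple(points[1]), tuple(points[2]))


def test_similarity_identity_for_equal_landmarks():
    lms = _lm([(10, 5, 5), (10, 25, 5), (60, 15, 6)])
    t = similarity_from_landmarks(lms, lms)
    np.testing.assert_allclose(t.linear, np.eye(3), atol=1e-12)
    np.testing.assert_allclose(t.translation, 0, atol=1e-12)
    assert t.residual_rms == pytest.approx(0.0, abs=1e-12)


def test_similarity_recovers_constructed_transform():
    src = _lm([(10, 5, 5), (10, 25, 5), (60, 15, 6)])
    truth = AffineTransform.from_rigid(
        (np.pi / 2, 0, 0), (10.0, 0.0, 0.0), scale=2.0
    )
    pts = truth.apply(src.as_array())
    dst = LandmarkSet(tuple(pts[0]), tuple(pts[1]), tuple(pts[2]))
    est = similarity_from_landmarks(src, dst)
    np.testing.assert_allclose(est.linear, truth.linear, atol=1e-9)
    np.testing.assert_allclose(est.translation, truth.translation, atol=1e-9)
    assert est.residual_rms < 1e-9
    # closure: applying the estimate to the source reproduces the targets
    np.testing.assert_allclose(est.apply(src.as_array()), pts, atol=1e-9)


def test_similarity_agrees_with_independent_estimator():
    """Cross-check against scikit-image's similarity estimator."""
    from skimage.transform import SimilarityTransform

    rng = np.random.default_rng(4)
    src_pts = rng.uniform(0, 50, (3, 3))
    src_pts[2, 0] += 100  # make the tail posterior
    src = _lm(src_pts)
    truth = AffineTransform.from_rigid((0.2, -0.1, 0.3), (5, -3, 2), scale=1.2)
    pts = truth.apply(src.as_array())
    dst = _lm(pts)
    est = similarity_from_landmarks(src, dst)
    sk = SimilarityTransform(dimensionality=3)
    assert sk.estimate(src.as_array(), pts)
    np.testing.assert_allclose(est.linear, sk.params[:3, :3], atol=1e-8)
    np.testing.assert_allclose(est.translation, sk.params[:3, 3], atol=1e-8)


def test_similarity_collinear_points_rejected():
    src = _lm([(0, 0, 0), (10, 0, 0), (20, 0, 0)])
    with pytest.raises(ValueError, match="degenerate"):
        similarity_from_landmarks(src, src)


def test_landmark_set_invariants():
    with pytest.raises(ValueError, match="distinct"):
        LandmarkSet((1, 2, 3), (1, 2, 3), (50, 2, 3))
    with pytest.raises(ValueError, match="posterior"):
        LandmarkSet((50, 2, 3), (50, 20, 3), (10, 10, 3))


def test_sphericity_formula():
    # ball of volume V has area (36 pi V^2)^(1/3): psi == 1 exactly
    V = 1000.0
    A = (36 * np.pi * V**2) ** (1 / 3)
    assert sphericity(V, A) == pytest.approx(1.0, rel=1e-12)
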