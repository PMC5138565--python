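"""Feature extractor oracles: brute-force recomputation of every statistic."""

import numpy as np
import pytest
from oracles import haralick_oracle, random_glcm

from nodulehash import features as F
from nodulehash.synthetic import NoduleImage, NoduleParams, generate_nodule


def make_img(pixels, mask=None, label=0, image_id="t"):
    pixels = np.asarray(pixels, dtype=float)
    mask = np.ones_like(pixels, bool) if mask is None else np.asarray(mask, bool)
    return NoduleImage(pixels=pixels, mask=mask, label=label, id=image_id)


def disk_mask(radius, size=None):
    size = size or int(4 * radius + 8)
    c = (size - 1) / 2.0
    rows, cols = np.mgrid[0:size, 0:size].astype(float)
    return np.hypot(rows - c, cols - c) <= radius


# ---------------------------------------------------------------------------
# gray (f1-f3)


def test_gray_constant_image_has_zero_variance_and_entropy():
    img = make_img(np.full((6, 6), 0.4))
    mean, var, ent = F.gray_features(img, k_levels=16)
    assert mean == pytest.approx(0.4)
    assert var == pytest.approx(0.0, abs=1e-30)
    assert ent == 0.0


def test_gray_two_equiprobable_levels_give_one_bit():
    px = np.zeros((4, 4))
    px[:2] = 0.99  # half at the top bin, half at the bottom
    _, _, ent = F.gray_features(make_img(px), k_levels=8)
    assert ent == pytest.approx(1.0)


def test_gray_entropy_matches_histogram_oracle(rng):
    px = rng.random((8, 8))
    k = 16
    _, _, ent = F.gray_features(make_img(px), k_levels=k)
    counts = [0] * k
    for v in px.ravel():
        counts[min(int(v * k), k - 1)] += 1
    expected = -sum(
        (c / 64) * np.log2(c / 64) for c in counts if c > 0
    )
    assert ent == pytest.approx(expected, abs=1e-12)


def test_gray_rejects_bad_quantization():
    with pytest.raises(ValueError):
        F.gray_features(make_img(np.zeros((3, 3))), k_levels=1)


# ---------------------------------------------------------------------------
# Hu moments (f4-f10)


def test_hu_rotation_and_translation_invariance():
    img = generate_nodule(1, NoduleParams(seed=9))
    base = F.hu_moments(img.mask)
    assert np.allclose(base, F.hu_moments(np.rot90(img.mask)), atol=1e-6)
    shifted = np.roll(img.mask, (5, -4), axis=(0, 1))
    assert np.allclose(base, F.hu_moments(shifted), atol=1e-12)


def test_hu_scale_invariance_on_upsampled_mask():
    mask = disk_mask(10) | np.roll(disk_mask(10), (0, 7), axis=(0, 1))
    big = np.kron(mask, np.ones((4, 4), bool))
    assert np.allclose(F.hu_moments(mask)[:4], F.hu_moments(big)[:4], atol=1e-2)


def test_hu_phi1_matches_raw_moment_sums_on_cross():
    cross = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], float)
    phi = F.hu_moments(cross.astype(bool))
    # direct raw-moment computation over the 5 foreground pixels
    ys, xs = np.nonzero(cross)
    m00 = len(xs)
    cy, cx = ys.mean(), xs.mean()
    mu20 = ((ys - cy) ** 2).sum()
    mu02 = ((xs - cx) ** 2).sum()
    eta20, eta02 = mu20 / m00**2, mu02 / m00**2
    assert phi[0] == pytest.approx(eta20 + eta02, abs=1e-12)


def test_hu_empty_mask_errors():
    with pytest.raises(ValueError):
        F.hu_moments(np.zeros((4, 4), bool))


# ---------------------------------------------------------------------------
# geometry (f11-f15)


def test_large_disk_roundness_near_one():
    per, area, _, _, roundness = F.geometric_features(disk_mask(32))
    assert 0.9 <= roundness <= 1.1
    assert area == pytest.approx(np.pi * 32**2, rel=0.05)


def test_filled_square_rectangularity_exactly_one():
    mask = np.zeros((20, 20), bool)
    mask[4:16, 6:17] = True
    rect = F.geometric_features(mask)[3]
    assert rect == pytest.approx(1.0, abs=1e-9)


def test_l_shape_max_diameter_matches_pairwise_oracle():
    mask = np.zeros((6, 6), bool)
    pix = [(1, 1), (2, 1), (3, 1), (4, 1), (4, 2), (4, 3), (4, 4)]
    for r, c in pix:
        mask[r, c] = True
    _, area, maxd, _, _ = F.geometric_features(mask)
    assert area == 7
    brute = max(
        np.hypot(a[0] - b[0], a[1] - b[1]) for a in pix for b in pix
    )
    assert maxd == pytest.approx(brute, abs=1e-12)


def test_multi_component_mask_rejected():
    mask = np.zeros((8, 8), bool)
    mask[1, 1] = mask[6, 6] = True
    with pytest.raises(ValueError):
        F.geometric_features(mask)


def test_roundness_decreases_with_irregularity():
    rounds = []
    for irr in (0.0, 0.2, 0.4):
        vals = [
            F.geometric_features(
                generate_nodule(1, NoduleParams(irregularity=irr, seed=s)).mask
            )[4]
            for s in range(12)
        ]
        rounds.append(np.mean(vals))
    assert rounds[0] > rounds[1] > rounds[2]


# ---------------------------------------------------------------------------
# medical signs (f16-f19)


def test_signs_all_midgray_are_zero():
    img = make_img(np.full((5, 5), 0.5))
    th = F.SignThresholds(tau_cal=0.8, tau_cav=0.2)
    assert F.medical_signs(img, th) == (0.0, 0.0, 0.0, 0.0)


def test_signs_saturated_image_fully_calcified():
    img = make_img(np.ones((5, 5)))
    assert F.medical_signs(img)[1] == 1.0


def test_signs_counting_on_toy_image():
    px = np.full((5, 5), 0.5)
    px[0, :3] = 0.95  # 3 calcified pixels
    mask = np.zeros((5, 5), bool)
    mask.ravel()[:20] = True  # 20 mask pixels
    calc_area, calc_deg, cav_area, cav_ratio = F.medical_signs(
        make_img(px, mask), F.SignThresholds(tau_cal=0.9, tau_cav=0.1)
    )
    assert (calc_area, calc_deg) == (3.0, pytest.approx(0.15))
    assert (cav_area, cav_ratio) == (0.0, 0.0)


def test_sign_threshold_order_enforced():
    with pytest.raises(ValueError):
        F.SignThresholds(tau_cal=0.2, tau_cav=0.8)


# ---------------------------------------------------------------------------
# Fourier descriptor (f20)


def test_disk_descriptor_is_tiny():
    assert F.fourier_descriptor(disk_mask(24)) < 0.05


def test_descriptor_scale_invariance():
    img = generate_nodule(1, NoduleParams(seed=3))
    small = F.fourier_descriptor(img.mask)
    big = F.fourier_descriptor(np.kron(img.mask, np.ones((2, 2), bool)))
    assert abs(small - big) < 0.02


def test_descriptor_grows_with_irregularity():
    for seed in range(6):
        lo = F.fourier_descriptor(
            generate_nodule(1, NoduleParams(irregularity=0.0, seed=seed)).mask
        )
        hi = F.fourier_descriptor(
            generate_nodule(1, NoduleParams(irregularity=0.3, seed=seed)).mask
        )
        assert hi > lo


def test_short_boundary_rejected():
    mask = np.zeros((4, 4), bool)
    mask[1, 1] = True
    with pytest.raises(ValueError, match="boundary"):
        F.fourier_descriptor(mask)


# ---------------------------------------------------------------------------
# GLCM (f21-f104)


def test_glcm_constant_image_single_diagonal_entry():
    g = F.compute_glcm(make_img(np.full((6, 6), 0.5)), k_levels=4, angle=0)
    expected = np.zeros((4, 4))
    expected[2, 2] = 1.0
    assert np.allclose(g.G, expected)


@pytest.mark.parametrize("angle", [0, 45, 90, 135])
def test_glcm_symmetric_and_normalized(angle):
    img = generate_nodule(1, NoduleParams(seed=4))
    g = F.compute_glcm(img, k_levels=8, angle=angle)
    assert np.allclose(g.G, g.G.T)
    assert g.G.sum() == pytest.approx(1.0)


def test_glcm_matches_hand_count_on_two_level_image():
    # 4x4 binary-intensity image, 0 deg, distance 1: enumerate pairs by hand.
    lv = np.array(
        [[0, 0, 1, 1], [0, 1, 1, 0], [1, 1, 0, 0], [0, 0, 0, 1]]
    )
    img = make_img(np.where(lv == 1, 0.8, 0.2))
    g = F.compute_glcm(img, k_levels=2, angle=0, distance=1)
    counts = np.zeros((2, 2))
    for r in range(4):
        for c in range(3):
            counts[lv[r, c], lv[r, c + 1]] += 1
            counts[lv[r, c + 1], lv[r, c]] += 1
    assert np.allclose(g.G, counts / counts.sum())


def test_glcm_no_valid_pair_errors():
    mask = np.zeros((5, 5), bool)
    mask[2, 2] = True  # a single pixel admits no offset pair
    with pytest.raises(ValueError):
        F.compute_glcm(make_img(np.full((5, 5), 0.5), mask), k_levels=4, angle=0)


def test_haralick_degenerate_single_entry():
    P = np.zeros((4, 4))
    P[1, 1] = 1.0
    asm, con, cor, var, idm, *_ = F.glcm_features(P)
    ent = F.glcm_features(P)[8]
    assert (asm, con, idm, ent) == (1.0, 0.0, 1.0, 0.0)


def test_haralick_uniform_asm_closed_form():
    k = 5
    P = np.full((k, k), 1.0 / k**2)
    assert F.glcm_features(P)[0] == pytest.approx(1.0 / k**2)


def test_haralick_matches_double_loop_oracle(rng):
    for _ in range(10):
        P = random_glcm(rng, k=4)
        got = F.glcm_features(P)
        exp = haralick_oracle(P)
        assert np.allclose(got, exp, atol=1e-10), np.abs(got - exp).max()


def test_haralick_rejects_unnormalized():
    with pytest.raises(ValueError):
        F.glcm_features(np.ones((3, 3)))


def test_texture_block_layout_and_recomputed_means():
    img = generate_nodule(1, NoduleParams(seed=6))
    block = F.texture_block(img, k_levels=8)
    assert block.shape == (84,)
    per_angle = block[:56].reshape(4, 14)
    assert np.allclose(block[56:70], per_angle.mean(axis=0))
    assert np.allclose(block[70:84], per_angle.var(axis=0))


def test_texture_block_constant_image_has_zero_variances():
    img = make_img(np.full((12, 12), 0.5), disk_mask(4, 12))
    block = F.texture_block(img, k_levels=8)
    assert np.allclose(block[70:84], 0.0)


# ---------------------------------------------------------------------------
# assembly & standardizer


def test_feature_vector_assembly_matches_pieces():
    img = generate_nodule(0, NoduleParams(seed=13))
    cfg = F.FeatureConfig()
    fv = F.assemble_feature_vector(img, cfg)
    assert fv.values.shape == (104,)
    assert np.all(np.isfinite(fv.values))
    assert fv.names[0] == "f1" and fv.names[-1] == "f104"
    gray = F.gray_features(img, cfg.k_levels)
    assert np.allclose(fv.values[:3], gray)
    assert np.allclose(fv.values[3:10], F.hu_moments(img.mask))
    assert np.allclose(fv.values[10:15], F.geometric_features(img.mask))
    assert np.allclose(fv.values[15:19], F.medical_signs(img, cfg.thresholds))
    assert fv.values[19] == pytest.approx(F.fourier_descriptor(img.mask))
    assert np.allclose(fv.values[20:], F.texture_block(img, cfg.k_levels, cfg.distance))
    fv2 = F.assemble_feature_vector(img, cfg)
    assert np.array_equal(fv.values, fv2.values)


def test_standardizer_round_trip_and_constant_guard(rng):
    X = rng.normal(size=(30, 6))
    X[:, 2] = 7.0  # constant component
    st = F.fit_standardizer(X)
    Z = st.apply(X)
    assert np.allclose(Z.mean(axis=0), 0.0, atol=1e-12)
    live = [0, 1, 3, 4, 5]
    assert np.allclose(Z[:, live].std(axis=0), 1.0, atol=1e-12)
    assert np.allclose(Z[:, 2], 0.0)  # centred, not blown up
    assert np.allclose(st.invert(Z), X, atol=1e-10)
    # already standardized data: identity within float error
    st2 = F.fit_standardizer(Z[:, live])
    assert np.allclose(st2.apply(Z[:, live]), Z[:, live], atol=1e-12)


def test_standardizer_needs_two_rows():
    with pytest.raises(ValueError):
        F.fit_standardizer(np.ones((1, 4)))
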