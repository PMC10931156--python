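"""Calibration, spot extraction, ΔRGB signatures and differential maps."""

import numpy as np
import pytest

from optonose.imaging import (
    CalibrationMap,
    DeltaSignature,
    SpotGrid,
    delta_signature,
    extract_spot_rgb,
    fit_calibration,
    locate_grid,
    render_differential_map,
    signature_from_pair,
)
from optonose.synth import (
    ArrayImage,
    SceneParams,
    canonical_scene,
    grid_centers,
    render_array_image,
)


# --- calibration -------------------------------------------------------

def test_calibration_of_reference_image_is_identity(blank_image):
    cal = fit_calibration(blank_image)
    assert cal.is_identity or (np.allclose(cal.gain, 1.0, atol=0.02)
                               and np.allclose(cal.offset, 0.0, atol=2.0))


def test_two_point_affine_solution():
    # measured black 10 and white 200 against references 0/255 give
    # gain 255/190 and offset -10 * 255/190 per channel
    px = np.full((60, 60, 3), 128, dtype=np.uint8)
    px[5:15, 5:15] = 200   # white patch
    px[5:15, 45:55] = 10   # black patch
    img = ArrayImage(pixels=px, spot_centers=grid_centers(60),
                     white_patch_box=(5, 5, 15, 15), black_patch_box=(5, 45, 15, 55))
    cal = fit_calibration(img, reference_black=(0, 0, 0), reference_white=(255, 255, 255))
    assert np.allclose(cal.gain, 255.0 / 190.0)
    assert np.allclose(cal.offset, -10.0 * 255.0 / 190.0)


def test_degenerate_lighting_rejected():
    px = np.full((60, 60, 3), 128, dtype=np.uint8)
    px[5:15, 5:15] = 10    # "white" darker than black
    px[5:15, 45:55] = 200
    img = ArrayImage(pixels=px, spot_centers=grid_centers(60),
                     white_patch_box=(5, 5, 15, 15), black_patch_box=(5, 45, 15, 55))
    with pytest.raises(ValueError, match="degenerate lighting"):
        fit_calibration(img)


def test_calibration_undoes_known_channel_gain(library):
    # gains below ~1.05 keep every spot channel off the 255 ceiling, so the
    # two-point affine map is exactly invertible
    gains = (1.05, 0.85, 0.9)
    canonical = render_array_image(library, {}, canonical_scene(), seed=31)
    lit = render_array_image(library, {}, SceneParams(illumination_gain=gains), seed=31)
    restored = fit_calibration(lit).apply(lit)
    ref = extract_spot_rgb(canonical)
    got = extract_spot_rgb(restored)
    assert np.abs(got - ref).max() <= 2.0


def test_calibration_is_idempotent(library):
    lit = render_array_image(library, {}, SceneParams(illumination_gain=(1.3, 0.9, 1.0)),
                             seed=32)
    once = fit_calibration(lit).apply(lit)
    second = fit_calibration(once)
    assert np.allclose(second.gain, 1.0, atol=0.02)
    assert np.allclose(second.offset, 0.0, atol=3.0)


# --- spot extraction ---------------------------------------------------

def test_uniform_image_extracts_uniform_color():
    px = np.full((120, 120, 3), 77, dtype=np.uint8)
    img = ArrayImage(pixels=px, spot_centers=grid_centers(120),
                     white_patch_box=(4, 4, 14, 14), black_patch_box=(4, 106, 14, 116))
    rgb = extract_spot_rgb(img, SpotGrid(centers=grid_centers(120), sampling_radius=4.0))
    assert np.allclose(rgb, 77.0)


def test_zero_radius_degenerates_to_single_pixel(blank_image):
    grid = SpotGrid(centers=blank_image.spot_centers, sampling_radius=0.0)
    rgb = extract_spot_rgb(blank_image, grid)
    for i, (r, c) in enumerate(blank_image.spot_centers):
        assert np.array_equal(rgb[i], blank_image.pixels[int(round(r)), int(round(c))])


def test_center_outside_raster_rejected(blank_image):
    centers = blank_image.spot_centers.copy()
    centers[0] = (-30.0, 10.0)  # stays separated, but off the raster
    grid = SpotGrid(centers=centers, sampling_radius=3.0)
    with pytest.raises(ValueError, match="raster"):
        extract_spot_rgb(blank_image, grid)


def test_grid_requires_separated_centers():
    centers = grid_centers(120)
    with pytest.raises(ValueError, match="separated"):
        SpotGrid(centers=centers, sampling_radius=20.0)


def test_locate_grid_recovers_canonical_lattice(blank_image):
    grid = locate_grid(blank_image)
    assert np.abs(grid.centers - blank_image.spot_centers).max() <= 1.5


# --- delta signatures --------------------------------------------------

def test_identical_pre_post_gives_zero_signature():
    rgb = np.full((25, 3), 100.0)
    sig = delta_signature(rgb, rgb)
    assert np.all(sig.ed_per_spot == 0.0) and sig.total_ed == 0.0


def test_single_spot_345_triangle():
    pre = np.full((25, 3), 100.0)
    post = pre.copy()
    post[7] += (3.0, 4.0, 0.0)
    sig = delta_signature(pre, post)
    assert sig.ed_per_spot[7] == pytest.approx(5.0)
    assert sig.total_ed == pytest.approx(5.0)


def test_ed_of_1_2_2_is_3():
    pre = np.zeros((25, 3))
    post = np.zeros((25, 3))
    post[0] = (1.0, 2.0, 2.0)
    assert delta_signature(pre, post).ed_per_spot[0] == pytest.approx(3.0)


def test_length_mismatch_rejected():
    with pytest.raises(ValueError, match=r"\(25, 3\)"):
        delta_signature(np.zeros((24, 3)), np.zeros((25, 3)))


def test_total_ed_modes():
    pre = np.zeros((25, 3))
    post = np.zeros((25, 3))
    post[0] = (3.0, 4.0, 0.0)
    post[1] = (0.0, 0.0, 12.0)
    assert delta_signature(pre, post, total_mode="sum").total_ed == pytest.approx(17.0)
    assert delta_signature(pre, post, total_mode="rss").total_ed == pytest.approx(13.0)
    with pytest.raises(ValueError, match="total_mode"):
        DeltaSignature(delta_rgb=post - pre, total_mode="median")


def test_ed_invariant_to_consistent_spot_permutation(rng):
    pre = rng.uniform(0, 255, size=(25, 3))
    post = rng.uniform(0, 255, size=(25, 3))
    perm = rng.permutation(25)
    a = delta_signature(pre, post)
    b = delta_signature(pre[perm], post[perm])
    assert a.total_ed == pytest.approx(b.total_ed)
    assert np.allclose(np.sort(a.ed_per_spot), np.sort(b.ed_per_spot))


def test_ed_invariant_under_gain_plus_calibration(library):
    # total ED of a canonical pair is recovered after a per-channel gain
    # followed by two-point calibration, within 2 counts per spot
    gas = {"ethanol": 150.0}
    pre_c = render_array_image(library, {}, canonical_scene(), seed=41)
    post_c = render_array_image(library, gas, canonical_scene(), seed=42)
    ref = signature_from_pair(pre_c, post_c)
    scene = SceneParams(illumination_gain=(1.02, 0.9, 0.85))  # non-clipping
    pre_g = render_array_image(library, {}, scene, seed=41)
    post_g = render_array_image(library, gas, scene, seed=42)
    cal = signature_from_pair(pre_g, post_g, calibrate=True)
    assert np.abs(cal.ed_per_spot - ref.ed_per_spot).max() <= 2.0 * np.sqrt(3)


# --- differential maps -------------------------------------------------

@pytest.mark.parametrize("mag,expected", [(10.0, 255), (3.0, 0), (6.5, 128),
                                          (0.0, 0), (50.0, 255)])
def test_differential_map_range_expansion(mag, expected):
    delta = np.zeros((25, 3))
    delta[0, 0] = mag
    sig = DeltaSignature(delta_rgb=delta)
    raster = render_differential_map(sig, tile=4)
    assert raster.shape == (20, 20, 3)
    assert raster[0, 0, 0] == expected


def test_differential_map_uses_magnitudes():
    delta = np.zeros((25, 3))
    delta[3, 1] = -10.0  # negative shift renders like +10
    sig = DeltaSignature(delta_rgb=delta)
    raster = render_differential_map(sig, tile=2)
    # spot 3 sits at grid position (0, 3)
    assert raster[0, 6, 1] == 255


def test_differential_map_rejects_bad_range():
    sig = DeltaSignature(delta_rgb=np.zeros((25, 3)))
    with pytest.raises(ValueError, match="in_range"):
        render_differential_map(sig, in_range=(10.0, 3.0))
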