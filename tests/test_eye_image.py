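"""Rendering, polarity reversal, level transforms and colorimetry."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from gazepolarity import eye_image as ei

from conftest import max_delta_e


# --- independent CIELAB oracle (published sRGB / CIELAB equations) ---------

_M_RGB2XYZ = np.array(
    [
        [0.4124564, 0.3575761, 0.1804375],
        [0.2126729, 0.7151522, 0.0721750],
        [0.0193339, 0.1191920, 0.9503041],
    ]
)
_WHITE_D65 = np.array([0.95047, 1.0, 1.08883])


def _oracle_srgb_to_lab(rgb):
    v = np.asarray(rgb, dtype=float) / 255.0
    lin = np.where(v <= 0.04045, v / 12.92, ((v + 0.055) / 1.055) ** 2.4)
    xyz = _M_RGB2XYZ @ lin / _WHITE_D65

    def f(t):
        eps = (6 / 29) ** 3
        return np.where(t > eps, np.cbrt(t), t / (3 * (6 / 29) ** 2) + 4 / 29)

    fx, fy, fz = f(xyz)
    return np.array([116 * fy - 16, 500 * (fx - fy), 200 * (fy - fz)])


@pytest.mark.parametrize(
    "rgb",
    [
        (255, 255, 255),
        (0, 0, 0),
        (128, 128, 128),
        (200, 30, 60),
        (12, 200, 240),
        (90, 140, 20),
    ],
)
def test_srgb_to_lab_matches_published_equations(rgb):
    got = ei.srgb_to_lab(rgb)
    want = _oracle_srgb_to_lab(rgb)
    assert np.allclose(got.as_array(), want, atol=5e-3)


def test_white_and_black_anchor_points():
    white = ei.srgb_to_lab((255, 255, 255))
    assert white.L == pytest.approx(100, abs=1e-3)
    assert abs(white.a) < 0.01 and abs(white.b) < 0.01
    black = ei.srgb_to_lab((0, 0, 0))
    assert black.as_array() == pytest.approx([0, 0, 0], abs=1e-6)


@given(
    st.tuples(
        st.integers(0, 255), st.integers(0, 255), st.integers(0, 255)
    )
)
def test_lab_roundtrip_within_one_count(rgb):
    lab = ei.srgb_to_lab(rgb)
    back, clipped = ei.lab_to_srgb(lab)
    assert not clipped
    assert max(abs(a - b) for a, b in zip(rgb, back)) <= 1


def test_lab_color_rejects_out_of_range_lightness():
    with pytest.raises(ValueError):
        ei.LabColor(L=120.0)


def test_out_of_gamut_is_flagged_and_clipped():
    rgb, clipped = ei.lab_to_srgb(ei.LabColor(50.0, 120.0, -120.0))
    assert clipped
    assert all(0 <= c <= 255 for c in rgb)


# --- rendering --------------------------------------------------------------


@pytest.mark.parametrize("species", ["human", "chimpanzee"])
def test_render_masks_are_consistent(both_stimuli, species):
    img, masks = both_stimuli[species]
    masks.validate()
    assert img.width_px == img.height_px == 400
    assert masks.iris_mask.sum() > 0 and masks.sclera_mask.sum() > 0


def test_front_gaze_iris_is_centered(human_stimulus):
    _, masks = human_stimulus
    cols = np.flatnonzero(masks.iris_mask.any(axis=0))
    center = (cols[0] + cols[-1]) / 2.0
    assert center == pytest.approx((400 - 1) / 2.0, abs=0.5)


def test_iris_mask_diameter_is_sixteen(human_stimulus):
    _, masks = human_stimulus
    cols = np.flatnonzero(masks.iris_mask.any(axis=0))
    assert abs(int(cols[-1] - cols[0] + 1) - 16) <= 1


@pytest.mark.parametrize("species", ["human", "chimpanzee"])
def test_averted_gaze_displaces_iris_by_shift(species):
    app = ei.default_appearance(species)
    imgs = {
        g: ei.render_eye_stimulus(ei.default_geometry(species, g), app) for g in ("front", "right", "left")
    }

    def centroid_x(masks):
        ys, xs = np.nonzero(masks.iris_mask | _pupil(masks))
        return xs.mean()

    def _pupil(masks):
        # pupil pixels = eyeball minus iris minus sclera (hole in the iris)
        return masks.eyeball_mask & ~masks.iris_mask & ~masks.sclera_mask

    cf = centroid_x(imgs["front"][1])
    assert centroid_x(imgs["right"][1]) - cf == pytest.approx(6.0, abs=0.3)
    assert cf - centroid_x(imgs["left"][1]) == pytest.approx(6.0, abs=0.3)


def test_geometry_invariants_are_enforced():
    with pytest.raises(ValueError):
        ei.EyeGeometry(iris_diameter_px=60.0, eye_outline_semiaxes_px=(24.0, 9.0))
    with pytest.raises(ValueError):
        ei.EyeGeometry(shift_px=30.0)
    with pytest.raises(ValueError):
        ei.EyeGeometry(gaze="up")  # type: ignore[arg-type]


def test_training_shift_angles_are_self_consistent():
    assert ei.shift_for_angle(20.0) == 6
    assert ei.shift_for_angle(30.0) == 9
    assert ei.shift_for_angle(38.0) == 11


# --- polarity reversal ------------------------------------------------------


@pytest.mark.parametrize("species", ["human", "chimpanzee"])
def test_polarity_reversal_is_an_involution(both_stimuli, species):
    img, masks = both_stimuli[species]
    twice = ei.reverse_polarity(
        ei.reverse_polarity(img, masks.eyeball_mask), masks.eyeball_mask
    )
    assert max_delta_e(img, twice) <= 1.0


@pytest.mark.parametrize("species", ["human", "chimpanzee"])
def test_reversal_preserves_iris_sclera_difference(both_stimuli, species):
    img, masks = both_stimuli[species]
    rev = ei.reverse_polarity(img, masks.eyeball_mask)
    before = ei.measure_colorimetry(img, masks).iris_sclera_difference
    after = ei.measure_colorimetry(rev, masks).iris_sclera_difference
    assert abs(before - after) <= 0.5


@pytest.mark.parametrize("species", ["human", "chimpanzee"])
def test_reversal_preserves_chromaticity(both_stimuli, species):
    img, masks = both_stimuli[species]
    rev = ei.reverse_polarity(img, masks.eyeball_mask)
    lab0 = ei.image_to_lab(img.pixels)[masks.eyeball_mask]
    lab1 = ei.image_to_lab(rev.pixels)[masks.eyeball_mask]
    assert np.abs(lab0[:, 1] - lab1[:, 1]).mean() <= 1.0
    assert np.abs(lab0[:, 2] - lab1[:, 2]).mean() <= 1.0


def test_reversal_leaves_outside_pixels_untouched(human_stimulus):
    img, masks = human_stimulus
    rev = ei.reverse_polarity(img, masks.eyeball_mask)
    outside = ~masks.eyeball_mask
    assert np.array_equal(img.pixels[outside], rev.pixels[outside])


def test_near_white_sclera_becomes_near_black(human_stimulus):
    img, masks = human_stimulus
    rev = ei.reverse_polarity(img, masks.eyeball_mask)
    sclera_l_before = ei.image_to_lab(img.pixels)[masks.sclera_mask][:, 0].mean()
    sclera_l_after = ei.image_to_lab(rev.pixels)[masks.sclera_mask][:, 0].mean()
    assert sclera_l_after == pytest.approx(100.0 - sclera_l_before, abs=1.5)


def test_reversal_mask_mismatch_raises(human_stimulus):
    img, _ = human_stimulus
    with pytest.raises(ValueError):
        ei.reverse_polarity(img, np.zeros((10, 10), dtype=bool))


def test_grayscale_mode_inverts_luma(human_stimulus):
    img, masks = human_stimulus
    rev = ei.reverse_polarity(img, masks.eyeball_mask, mode="grayscale")
    luma = img.pixels[masks.eyeball_mask].astype(float) @ np.array([0.299, 0.587, 0.114])
    luma_rev = rev.pixels[masks.eyeball_mask].astype(float) @ np.array([0.299, 0.587, 0.114])
    assert np.abs((255.0 - luma) - luma_rev).mean() <= 2.0


# --- levels -----------------------------------------------------------------


def test_level_table_matches_design():
    rows = [(s.level, s.width_px, s.brightness_fraction) for s in ei.StimulusLevel.table()]
    assert rows == [
        (1.0, 400, 1.00),
        (1.5, 300, 0.75),
        (2.0, 200, 0.50),
        (2.5, 150, 0.42),
        (3.0, 100, 0.33),
        (3.5, 75, 0.29),
        (4.0, 50, 0.25),
    ]


def test_level_one_is_identity(human_stimulus):
    img, _ = human_stimulus
    out = ei.apply_level(img, 1.0)
    assert np.array_equal(out.pixels, img.pixels)


@pytest.mark.parametrize("level,width", [(4.0, 50), (2.5, 150), (2.0, 200)])
def test_level_rescales_width(human_stimulus, level, width):
    img, _ = human_stimulus
    out = ei.apply_level(img, level)
    assert out.width_px == width
    assert out.height_px == width  # square stays square


def test_level_luminance_strictly_decreases(human_stimulus):
    img, _ = human_stimulus
    lum = [ei.mean_luminance(ei.apply_level(img, lv)) for lv in (1.0, 2.0, 3.0, 4.0)]
    assert all(a > b for a, b in zip(lum, lum[1:]))


def test_unknown_level_raises(human_stimulus):
    with pytest.raises(ValueError):
        ei.apply_level(human_stimulus[0], 5.0)


def test_srgb_scaling_darkens_more_than_linear_light(human_stimulus):
    # gamma encoding is concave, so scaling encoded values by f cuts
    # perceived lightness harder than scaling linear light by f
    img, _ = human_stimulus
    srgb = ei.apply_level(img, 4.0, space="srgb")
    lin = ei.apply_level(img, 4.0, space="linear")
    assert ei.mean_luminance(srgb) < ei.mean_luminance(lin)


# --- normalization / cropping ----------------------------------------------


def test_normalize_by_iris_halves_double_geometry():
    geo = ei.EyeGeometry(
        canvas_px=800,
        iris_diameter_px=32.0,
        pupil_diameter_px=16.0,
        eye_outline_semiaxes_px=(48.0, 18.0),
    )
    img, masks = ei.render_eye_stimulus(geo, ei.default_appearance("human"))
    norm_img, norm_masks = ei.normalize_by_iris(img, masks)
    cols = np.flatnonzero(norm_masks.iris_mask.any(axis=0))
    assert abs(int(cols[-1] - cols[0] + 1) - 16) <= 1
    assert norm_img.width_px == 400

    ref_img, ref_masks = ei.render_eye_stimulus(
        ei.default_geometry("human"), ei.default_appearance("human")
    )
    rep_norm = ei.measure_colorimetry(norm_img, norm_masks)
    rep_ref = ei.measure_colorimetry(ref_img, ref_masks)
    assert rep_norm.iris_area_px == pytest.approx(rep_ref.iris_area_px, rel=0.10)
    assert rep_norm.sclera_area_px == pytest.approx(rep_ref.sclera_area_px, rel=0.10)


def test_normalize_identity_when_already_sixteen(human_stimulus):
    img, masks = human_stimulus
    out_img, out_masks = ei.normalize_by_iris(img, masks)
    assert np.array_equal(out_img.pixels, img.pixels)
    assert np.array_equal(out_masks.iris_mask, masks.iris_mask)


def test_normalize_empty_iris_raises(human_stimulus):
    img, masks = human_stimulus
    empty = ei.RoiMasks(
        np.zeros_like(masks.iris_mask),
        masks.sclera_mask,
        masks.eyeball_mask,
    )
    with pytest.raises(ValueError):
        ei.normalize_by_iris(img, empty)


def test_crop_eye_region_four_to_one(human_stimulus):
    img, masks = human_stimulus
    crop, crop_masks = ei.crop_eye_region(img, masks)
    assert (crop.width_px, crop.height_px) == (400, 100)
    assert crop_masks.eyeball_mask.sum() == masks.eyeball_mask.sum()


def test_crop_is_idempotent(human_stimulus):
    img, masks = human_stimulus
    once_img, once_masks = ei.crop_eye_region(img, masks)
    twice_img, twice_masks = ei.crop_eye_region(once_img, once_masks)
    assert np.array_equal(once_img.pixels, twice_img.pixels)
    assert np.array_equal(once_masks.eyeball_mask, twice_masks.eyeball_mask)


# --- colorimetry ------------------------------------------------------------


def test_equal_roi_colors_give_zero_difference():
    img = ei.RasterImage(np.full((20, 20, 3), 90, dtype=np.uint8))
    masks = ei.RoiMasks(
        np.eye(20, dtype=bool),
        np.rot90(np.eye(20, dtype=bool)) & ~np.eye(20, dtype=bool),
        np.ones((20, 20), dtype=bool),
    )
    rep = ei.measure_colorimetry(img, masks)
    assert rep.iris_sclera_difference == pytest.approx(0.0, abs=1e-9)


def test_pure_lightness_difference():
    iris_rgb, _ = ei.lab_to_srgb(ei.LabColor(30.0))
    sclera_rgb, _ = ei.lab_to_srgb(ei.LabColor(90.0))
    img = np.zeros((10, 10, 3), dtype=np.uint8)
    iris = np.zeros((10, 10), dtype=bool)
    sclera = np.zeros((10, 10), dtype=bool)
    iris[:5], sclera[5:] = True, True
    img[iris] = iris_rgb
    img[sclera] = sclera_rgb
    rep = ei.measure_colorimetry(
        ei.RasterImage(img), ei.RoiMasks(iris, sclera, iris | sclera)
    )
    assert rep.iris_sclera_difference == pytest.approx(60.0, abs=0.5)


def test_colorimetry_matches_pixel_loop_oracle(chimp_stimulus):
    img, masks = chimp_stimulus
    rep = ei.measure_colorimetry(img, masks)
    lab = ei.image_to_lab(img.pixels)
    # deliberately scalar per-pixel accumulation, independent of the module path
    sums, count = np.zeros(3), 0
    for r in range(img.height_px):
        for c in range(img.width_px):
            if masks.iris_mask[r, c]:
                sums += lab[r, c]
                count += 1
    assert rep.iris_mean.as_array() == pytest.approx(sums / count, abs=1e-6)
    assert rep.iris_area_px == count


def test_colorimetry_empty_roi_raises(human_stimulus):
    img, masks = human_stimulus
    bad = ei.RoiMasks(
        np.zeros_like(masks.iris_mask), masks.sclera_mask, masks.eyeball_mask
    )
    with pytest.raises(ValueError):
        ei.measure_colorimetry(img, bad)


def test_masks_stay_consistent_after_transforms(human_stimulus):
    img, masks = human_stimulus
    for im2, m2 in (
        ei.normalize_by_iris(*ei.render_eye_stimulus(
            ei.EyeGeometry(canvas_px=800, iris_diameter_px=32.0, pupil_diameter_px=16.0,
                           eye_outline_semiaxes_px=(48.0, 18.0)),
            ei.default_appearance("human"))),
        ei.crop_eye_region(img, masks),
    ):
        m2.validate()
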