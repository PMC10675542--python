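import numpy as np
import pytest
from skimage.color import rgb2hsv

from slideaug import (
    ArtifactOverlay,
    AugmentationConfig,
    ParameterError,
    TransformParams,
    add_scratches,
    apply_chain,
    hue_set,
    intensity_scale,
    mirror_overlay,
    perlin_fade,
    rotate_overlay,
    sample_params,
    scale_overlay,
    strength_field,
)
from slideaug.noise import normalized_perlin, perlin_field

from conftest import random_overlay


def assert_overlays_equal(a, b):
    assert np.array_equal(a.patch, b.patch)
    assert np.array_equal(a.mask, b.mask)


def assert_valid(overlay):
    assert overlay.patch.shape[:2] == overlay.mask.shape
    assert overlay.mask.any()
    assert set(np.unique(overlay.mask)) <= {0, 255}
    assert (overlay.patch[overlay.mask == 0] == 255).all()


class TestScale:
    def test_factor_one_is_identity(self, felt_pen_overlay):
        assert_overlays_equal(scale_overlay(felt_pen_overlay, 1.0),
                              felt_pen_overlay)

    def test_rounding_rule_half_up(self, rng):
        ov = random_overlay(rng, dims=(10, 10))
        assert scale_overlay(ov, 0.75).mask.shape == (8, 8)  # 7.5 -> 8
        assert scale_overlay(ov, 1.25).mask.shape == (13, 13)  # 12.5 -> 13

    def test_tiny_factor_clamps_dims_to_one(self, rng):
        ov = random_overlay(rng, dims=(10, 10))
        scaled = scale_overlay(ov, 0.01)
        assert scaled.mask.shape == (1, 1)
        assert_valid(scaled)

    def test_nonpositive_factor_rejected(self, felt_pen_overlay):
        with pytest.raises(ParameterError):
            scale_overlay(felt_pen_overlay, 0.0)

    @pytest.mark.parametrize("factor", [0.75, 0.9, 1.1, 1.25])
    def test_output_valid_for_sampled_range(self, felt_pen_overlay, factor):
        assert_valid(scale_overlay(felt_pen_overlay, factor))


class TestRotate:
    def test_angle_zero_is_identity(self, any_overlay):
        assert_overlays_equal(rotate_overlay(any_overlay, 0), any_overlay)

    def test_90_degrees_matches_index_permutation_oracle(self, rng):
        ov = random_overlay(rng, dims=(15, 9))
        rotated = rotate_overlay(ov, 90)
        assert rotated.mask.shape == (9, 15)
        h, w = ov.mask.shape
        # oracle: output[r, c] = input[c, w-1-r] for a CCW quarter turn
        for r in range(w):
            for c in range(h):
                assert rotated.mask[r, c] == ov.mask[c, w - 1 - r]
                assert (rotated.patch[r, c] == ov.patch[c, w - 1 - r]).all()
        assert rotated.area == ov.area

    def test_180_twice_is_identity(self, any_overlay):
        twice = rotate_overlay(rotate_overlay(any_overlay, 180), 180)
        assert_overlays_equal(twice, any_overlay)

    def test_general_angle_expands_canvas_and_stays_valid(self, felt_pen_overlay):
        rotated = rotate_overlay(felt_pen_overlay, 37)
        assert rotated.mask.shape[0] >= felt_pen_overlay.mask.shape[0]
        assert_valid(rotated)

    def test_angle_out_of_range_rejected(self, felt_pen_overlay):
        with pytest.raises(ParameterError):
            rotate_overlay(felt_pen_overlay, 360)


class TestMirror:
    @pytest.mark.parametrize("axis", ["horizontal", "vertical", "both"])
    def test_involution(self, any_overlay, axis):
        twice = mirror_overlay(mirror_overlay(any_overlay, axis), axis)
        assert_overlays_equal(twice, any_overlay)

    def test_both_equals_horizontal_then_vertical(self, felt_pen_overlay):
        both = mirror_overlay(felt_pen_overlay, "both")
        chained = mirror_overlay(
            mirror_overlay(felt_pen_overlay, "horizontal"), "vertical"
        )
        assert_overlays_equal(both, chained)

    def test_mask_area_invariant(self, any_overlay):
        for axis in ("horizontal", "vertical", "both"):
            assert mirror_overlay(any_overlay, axis).area == any_overlay.area

    def test_invalid_axis_rejected(self, felt_pen_overlay):
        with pytest.raises(ParameterError):
            mirror_overlay(felt_pen_overlay, "diagonal")


class TestHue:
    def test_saturation_and_value_preserved_within_one_level(
        self, felt_pen_overlay
    ):
        out = hue_set(felt_pen_overlay, 133)
        fg = felt_pen_overlay.mask > 0
        before = rgb2hsv(felt_pen_overlay.patch / 255.0)
        after = rgb2hsv(out.patch / 255.0)
        for channel in (1, 2):
            delta = np.abs(before[..., channel][fg] - after[..., channel][fg])
            assert (delta * 255.0 <= 1.0 + 1e-9).all()

    def test_hue_actually_replaced(self, felt_pen_overlay):
        out = hue_set(felt_pen_overlay, 30)
        fg = felt_pen_overlay.mask > 0
        hues = rgb2hsv(out.patch / 255.0)[..., 0][fg] * 180.0
        sats = rgb2hsv(out.patch / 255.0)[..., 1][fg]
        # only meaningfully-saturated pixels carry a defined hue
        defined = sats > 0.1
        assert np.abs(hues[defined] - 30.0).max() < 2.0

    def test_pixels_outside_mask_untouched(self, felt_pen_overlay):
        out = hue_set(felt_pen_overlay, 90)
        bg = felt_pen_overlay.mask == 0
        assert np.array_equal(out.patch[bg], felt_pen_overlay.patch[bg])

    def test_gray_pixels_unchanged_for_any_hue(self):
        patch = np.full((4, 4, 3), 120, dtype=np.uint8)  # saturation 0
        mask = np.full((4, 4), 255, dtype=np.uint8)
        ov = ArtifactOverlay(patch=patch, mask=mask, category="felt_pen")
        for hue in (0, 45, 90, 180):
            assert np.array_equal(hue_set(ov, hue).patch, patch)

    def test_reapplying_same_hue_is_stable(self, felt_pen_overlay):
        once = hue_set(felt_pen_overlay, 77)
        twice = hue_set(once, 77)
        assert np.abs(
            once.patch.astype(int) - twice.patch.astype(int)
        ).max() <= 1

    def test_hue_out_of_range_rejected(self, felt_pen_overlay):
        with pytest.raises(ParameterError):
            hue_set(felt_pen_overlay, 181)


class TestScratch:
    def test_count_zero_is_identity(self, felt_pen_overlay, rng):
        assert_overlays_equal(
            add_scratches(felt_pen_overlay, 0, rng), felt_pen_overlay
        )

    def test_pixels_outside_mask_bit_identical(self, felt_pen_overlay, rng):
        out = add_scratches(felt_pen_overlay, 5, rng)
        bg = felt_pen_overlay.mask == 0
        assert np.array_equal(out.patch[bg], felt_pen_overlay.patch[bg])

    def test_strength_never_increases(self, felt_pen_overlay, rng):
        out = add_scratches(felt_pen_overlay, 8, rng)
        assert (strength_field(out) <= strength_field(felt_pen_overlay)).all()

    def test_zero_factor_line_erases_core_strength(self):
        # toy 5x5 field: full-strength artifact everywhere, one horizontal
        # line with factor 0 -> blurred factor is 0 on the whole band, so
        # the line core ends at intensity 255 (strength 0)
        patch = np.zeros((5, 5, 3), dtype=np.uint8)
        mask = np.full((5, 5), 255, dtype=np.uint8)
        ov = ArtifactOverlay(patch=patch, mask=mask, category="felt_pen")
        # force a horizontal line by trying seeds until one connects
        # left and right edges on the middle row
        for seed in range(200):
            rng = np.random.default_rng(seed)
            out = add_scratches(ov, 1, rng, factors=0.0)
            diff = strength_field(out) != strength_field(ov)
            if diff.any():
                core = np.nonzero(diff.all(axis=2))
                assert (strength_field(out)[core] == 0).all()
                break
        else:
            pytest.fail("no scratch intersected the mask in 200 seeds")

    def test_negative_count_rejected(self, felt_pen_overlay, rng):
        with pytest.raises(ParameterError):
            add_scratches(felt_pen_overlay, -1, rng)


class TestPerlinFade:
    def test_weight_zero_is_identity(self, felt_pen_overlay, rng):
        assert_overlays_equal(
            perlin_fade(felt_pen_overlay, 0.0, rng=rng), felt_pen_overlay
        )

    def test_fading_only_lightens(self, felt_pen_overlay, rng):
        out = perlin_fade(felt_pen_overlay, 0.8, rng=rng)
        fg = felt_pen_overlay.mask > 0
        assert (out.patch[fg].astype(int)
                >= felt_pen_overlay.patch[fg].astype(int)).all()

    def test_pixels_outside_mask_untouched(self, felt_pen_overlay, rng):
        out = perlin_fade(felt_pen_overlay, 0.6, rng=rng)
        bg = felt_pen_overlay.mask == 0
        assert np.array_equal(out.patch[bg], felt_pen_overlay.patch[bg])

    def test_same_seed_gives_identical_output(self, felt_pen_overlay):
        a = perlin_fade(felt_pen_overlay, 0.5, rng=np.random.default_rng(9))
        b = perlin_fade(felt_pen_overlay, 0.5, rng=np.random.default_rng(9))
        assert_overlays_equal(a, b)

    def test_weight_out_of_range_rejected(self, felt_pen_overlay, rng):
        with pytest.raises(ParameterError):
            perlin_fade(felt_pen_overlay, 1.2, rng=rng)

    def test_noise_field_properties(self):
        rng = np.random.default_rng(4)
        field = normalized_perlin((32, 48), cells=4.0, rng=rng)
        assert field.shape == (32, 48)
        assert field.min() >= 0.0 and field.max() <= 1.0
        thresholded = normalized_perlin(
            (32, 48), cells=4.0, rng=np.random.default_rng(4), threshold=0.5
        )
        assert ((thresholded == 0) | (thresholded >= 0.5)).all()

    def test_raw_field_deterministic_and_smooth(self):
        a = perlin_field((20, 20), 3.0, np.random.default_rng(1))
        b = perlin_field((20, 20), 3.0, np.random.default_rng(1))
        assert np.array_equal(a, b)
        # gradient noise is continuous: neighbouring pixels stay close
        assert np.abs(np.diff(a, axis=0)).max() < 0.5


class TestIntensityScale:
    def test_factor_one_is_identity(self, felt_pen_overlay):
        assert_overlays_equal(
            intensity_scale(felt_pen_overlay, 1.0), felt_pen_overlay
        )

    def test_worked_arithmetic_example(self):
        patch = np.full((3, 3, 3), 55, dtype=np.uint8)  # strength 200
        mask = np.full((3, 3), 255, dtype=np.uint8)
        ov = ArtifactOverlay(patch=patch, mask=mask, category="felt_pen")
        out = intensity_scale(ov, 0.5)
        assert (out.patch == 155).all()  # 255 - 0.5 * 200

    def test_factor_out_of_range_rejected(self, felt_pen_overlay):
        for bad in (0.0, -0.5, 1.5):
            with pytest.raises(ParameterError):
                intensity_scale(felt_pen_overlay, bad)


class TestSampleParams:
    def test_disabled_transforms_give_identity_params(self):
        cfg = AugmentationConfig()
        for cat_cfg in cfg.categories.values():
            cat_cfg.scale = None
            cat_cfg.rotation = None
            cat_cfg.mirror = False
            cat_cfg.hue = None
            cat_cfg.scratch_count = None
            cat_cfg.perlin_weight = None
            cat_cfg.intensity_u = None
        params = sample_params(cfg, "felt_pen", np.random.default_rng(0))
        assert params.is_identity()

    @pytest.mark.parametrize("category", ["bubble", "dirt", "brand_mark"])
    def test_content_transforms_forced_identity_off_felt_pen(self, category):
        cfg = AugmentationConfig()
        # even if a range is configured, non-felt-pen draws stay identity
        cfg.categories[category].hue = (0, 180)
        cfg.categories[category].perlin_weight = (0.5, 1.0)
        params = sample_params(cfg, category, np.random.default_rng(1))
        assert params.hue_value is None
        assert params.scratch_count == 0
        assert params.perlin_weight == 0.0
        assert params.intensity_factor == 1.0

    def test_fixed_seed_reproduces_draw(self):
        cfg = AugmentationConfig()
        a = sample_params(cfg, "felt_pen", np.random.default_rng(33))
        b = sample_params(cfg, "felt_pen", np.random.default_rng(33))
        assert a == b

    def test_sampled_ranges_conform(self):
        cfg = AugmentationConfig()
        rng = np.random.default_rng(2)
        for _ in range(500):
            p = sample_params(cfg, "felt_pen", rng)
            assert 0.75 <= p.scale_factor <= 1.25
            assert 0 <= p.rotation_angle <= 359
            assert 0 <= p.hue_value <= 180
            assert 1 <= p.scratch_count <= 10
            assert 0.0 <= p.scratch_factor <= 0.2
            assert 0.0 <= p.perlin_weight <= 1.0
            assert np.sqrt(0.3) <= p.intensity_factor <= np.sqrt(0.7)


class TestApplyChain:
    def test_identity_params_return_equal_overlay(self, any_overlay):
        out = apply_chain(any_overlay, TransformParams())
        assert_overlays_equal(out, any_overlay)
        assert out is not any_overlay

    def test_geometric_chain_preserves_masked_hue_multiset(self, felt_pen_overlay):
        params = TransformParams(rotation_angle=90, mirror_axis="horizontal")
        out = apply_chain(felt_pen_overlay, params)
        before = np.sort(
            rgb2hsv(felt_pen_overlay.patch / 255.0)[..., 0][
                felt_pen_overlay.mask > 0
            ]
        )
        after = np.sort(rgb2hsv(out.patch / 255.0)[..., 0][out.mask > 0])
        assert np.allclose(before, after)

    def test_output_valid_over_random_params(self, felt_pen_overlay):
        cfg = AugmentationConfig()
        rng = np.random.default_rng(6)
        for _ in range(15):
            params = sample_params(cfg, "felt_pen", rng)
            assert_valid(apply_chain(felt_pen_overlay, params))

    def test_chain_bit_identical_across_runs(self, felt_pen_overlay):
        params = sample_params(
            AugmentationConfig(), "felt_pen", np.random.default_rng(8)
        )
        a = apply_chain(felt_pen_overlay, params)
        b = apply_chain(felt_pen_overlay, params)
        assert_overlays_equal(a, b)

    def test_content_params_rejected_for_other_categories(self, bubble_overlay):
        with pytest.raises(ParameterError):
            apply_chain(bubble_overlay, TransformParams(hue_value=30))
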