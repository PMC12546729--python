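"""Tile preprocessing: levels, tessellation, QC, Macenko, augmentation."""

import numpy as np
import pytest

from slidemil import preprocess as pp
from slidemil.synthetic import EOSIN_OD, HEMATOXYLIN_OD


def two_stain_image(rng, n=60, m=100, ch_max=1.2, ce_max=1.0, gains=(1, 1)):
    """RGB image composed from the known H/E OD vectors (ground truth)."""
    ch = rng.uniform(0, ch_max, n * m) * gains[0]
    ce = rng.uniform(0, ce_max, n * m) * gains[1]
    od = ch[:, None] * HEMATOXYLIN_OD + ce[:, None] * EOSIN_OD
    rgb = np.clip(256 * 10.0 ** (-od) - 1, 0, 255)
    return rgb.reshape(n, m, 3).astype(np.uint8)


def angle_deg(u, v):
    return np.degrees(np.arccos(np.clip(np.dot(u, v), -1.0, 1.0)))


class TestResolutionLevels:
    @pytest.mark.parametrize("r,mpp,thresh", [(0, 2, 80), (1, 4, 40),
                                              (2, 8, 20), (3, 16, 10)])
    def test_level_mapping_and_gate(self, r, mpp, thresh):
        level = pp.ResolutionLevel(r)
        assert level.microns_per_pixel == mpp
        assert level.downsample_factor == 8 * 2**r
        assert pp.min_tile_threshold(level) == thresh

    def test_invalid_level_rejected(self):
        with pytest.raises(ValueError):
            pp.ResolutionLevel(4)


class TestDownsample:
    def test_integer_factor_dimensions(self):
        img = np.zeros((1024, 1024, 3), dtype=np.uint8)
        out = pp.downsample_to_level(img, 2.0, pp.ResolutionLevel(1))
        assert out.shape == (512, 512, 3)

    def test_box_filter_preserves_constants(self):
        img = np.full((512, 512, 3), 137, dtype=np.uint8)
        out = pp.downsample_to_level(img, 2.0, pp.ResolutionLevel(1))
        assert (out == 137).all()

    def test_checkerboard_averages_to_midpoint(self):
        img = np.zeros((4, 4), dtype=float)
        img[::2, 1::2] = 255.0
        img[1::2, ::2] = 255.0
        out = pp.downsample_to_level(img, 2.0, pp.ResolutionLevel(1))
        assert out == pytest.approx(np.full((2, 2), 127.5))

    def test_non_integer_factor(self):
        img = np.zeros((300, 300), dtype=np.uint8)
        out = pp.downsample_to_level(img, 3.0, pp.ResolutionLevel(1))
        assert out.shape == (225, 225)  # floor(300 / (4/3))

    def test_upsampling_rejected(self):
        with pytest.raises(ValueError):
            pp.downsample_to_level(np.zeros((64, 64)), 8.0, pp.ResolutionLevel(0))


class TestTessellate:
    def test_regular_grid_origins(self, level2):
        tiles = pp.tessellate(np.zeros((512, 512, 3), dtype=np.uint8), level2)
        assert [t.origin for t in tiles] == [(0, 0), (256, 0), (0, 256), (256, 256)]

    @pytest.mark.parametrize("size,count", [(600, 4), (256, 1), (255, 0),
                                            (1024, 16)])
    def test_edge_remainders_dropped(self, size, count, level2):
        tiles = pp.tessellate(np.zeros((size, size, 3), dtype=np.uint8), level2)
        assert len(tiles) == (size // 256) ** 2 == count

    def test_tiles_disjoint_within_bounds(self, level2):
        img = np.arange(600 * 600 * 3).reshape(600, 600, 3) % 255
        tiles = pp.tessellate(img.astype(np.uint8), level2)
        seen = set()
        for t in tiles:
            x, y = t.origin
            assert 0 <= x <= 600 - 256 and 0 <= y <= 600 - 256
            assert (x, y) not in seen
            seen.add((x, y))
            assert t.pixels.shape == (256, 256, 3)


class TestBackgroundFilter:
    def test_all_white_rejected(self):
        tile = np.full((256, 256, 3), 255, dtype=np.uint8)
        assert pp.background_fraction(tile) == 1.0

    def test_all_tissue_kept(self):
        tile = np.full((256, 256, 3), (180, 120, 160), dtype=np.uint8)
        assert pp.background_fraction(tile) == 0.0

    def test_half_white_is_half(self):
        tile = np.full((256, 256, 3), (180, 120, 160), dtype=np.uint8)
        tile[:128] = 255
        assert pp.background_fraction(tile) == 0.5

    def test_monotone_under_whitening(self, rng):
        tile = rng.integers(0, 200, (256, 256, 3)).astype(np.uint8)
        f0 = pp.background_fraction(tile)
        tile[:64] = 255
        assert pp.background_fraction(tile) >= f0


class TestInformativeness:
    def test_uniform_tile_fails(self):
        assert not pp.is_informative(np.full((256, 256, 3), 150, dtype=np.uint8))

    def test_checkerboard_passes(self):
        tile = np.zeros((256, 256, 3), dtype=np.uint8)
        tile[::16].fill(255)
        assert pp.is_informative(tile)

    def test_texture_passes_blur_fails(self, tumour_slide, level2):
        from scipy import ndimage
        img, _, _ = tumour_slide
        tile = img[:256, :256]
        blurred = ndimage.gaussian_filter(tile.astype(float), (8, 8, 0))
        assert pp.is_informative(tile)
        assert not pp.is_informative(blurred.astype(np.uint8))


class TestFilterSlide:
    def _tiles(self, n, pixels, level):
        return [pp.Tile(pixels=pixels, grid_row=0, grid_col=i,
                        origin=(256 * i, 0), level=level) for i in range(n)]

    def test_gate_is_strict_below_threshold(self):
        level = pp.ResolutionLevel(0)
        tile = np.zeros((256, 256, 3), dtype=np.uint8)
        tile[::8].fill(255)  # edgy, non-background
        _, report = pp.filter_slide(self._tiles(79, tile, level), level)
        assert report.n_valid == 79 and not report.slide_accepted
        _, report = pp.filter_slide(self._tiles(80, tile, level), level)
        assert report.slide_accepted

    def test_r3_accepts_ten_valid_tiles(self):
        level = pp.ResolutionLevel(3)
        tile = np.zeros((256, 256, 3), dtype=np.uint8)
        tile[::8].fill(255)
        _, report = pp.filter_slide(self._tiles(10, tile, level), level)
        assert report.slide_accepted

    def test_all_white_slide_rejected(self, level2):
        white = np.full((256, 256, 3), 255, dtype=np.uint8)
        valid, report = pp.filter_slide(self._tiles(30, white, level2), level2)
        assert report.n_valid == 0 and not report.slide_accepted
        assert report.n_background_rejected == 30
        assert valid == []


class TestMacenko:
    def test_recovers_known_stain_vectors(self, rng, level2):
        img = two_stain_image(rng)
        profile = pp.macenko_fit(img, level2)
        assert angle_deg(profile.stain_matrix[:, 0], HEMATOXYLIN_OD) < 5
        assert angle_deg(profile.stain_matrix[:, 1], EOSIN_OD) < 5

    def test_white_image_rejected(self, level2):
        with pytest.raises(ValueError):
            pp.macenko_fit(np.full((64, 64, 3), 255, dtype=np.uint8), level2)

    def test_fit_is_deterministic(self, rng, level2):
        img = two_stain_image(rng)
        p1, p2 = pp.macenko_fit(img, level2), pp.macenko_fit(img, level2)
        assert np.array_equal(p1.stain_matrix, p2.stain_matrix)
        assert np.array_equal(p1.max_concentrations, p2.max_concentrations)

    def test_self_normalization_near_identity(self, rng, level2):
        img = two_stain_image(rng)
        profile = pp.macenko_fit(img, level2)
        out = pp.macenko_normalize(img, profile, source=profile)
        assert np.abs(out.astype(float) - img.astype(float)).mean() < 5

    def test_concentration_scaled_pair_converges(self, rng, level2):
        seed_rng = np.random.default_rng(42)
        a = two_stain_image(seed_rng)
        seed_rng = np.random.default_rng(42)
        b = two_stain_image(seed_rng, gains=(1.6, 1.3))
        ref = pp.macenko_fit(a, level2)
        na = pp.macenko_normalize(a, ref, source=pp.macenko_fit(a, level2))
        nb = pp.macenko_normalize(b, ref, source=pp.macenko_fit(b, level2))
        before = np.abs(a.astype(float) - b.astype(float)).mean()
        after = np.abs(na.astype(float) - nb.astype(float)).mean()
        assert after < before / 4
        assert after < 8

    def test_idempotence(self, rng, level2):
        img = two_stain_image(rng)
        ref = pp.macenko_fit(two_stain_image(np.random.default_rng(9)), level2)
        once = pp.macenko_normalize(img, ref, source=pp.macenko_fit(img, level2))
        twice = pp.macenko_normalize(once, ref, source=pp.macenko_fit(once, level2))
        assert np.abs(twice.astype(float) - once.astype(float)).mean() < 4

    def test_profile_serialization_reproduces_output(self, rng, level2, tmp_path):
        img = two_stain_image(rng)
        ref = pp.macenko_fit(img, level2)
        ref.to_json(tmp_path / "profile.json")
        reloaded = pp.StainProfile.from_json(tmp_path / "profile.json")
        src = pp.macenko_fit(img, level2)
        out1 = pp.macenko_normalize(img, ref, source=src)
        out2 = pp.macenko_normalize(img, reloaded, source=src)
        assert np.array_equal(out1, out2)

    def test_level_mismatch_rejected(self, rng, level2):
        img = two_stain_image(rng)
        ref = pp.macenko_fit(img, level2)
        src = pp.macenko_fit(img, pp.ResolutionLevel(1))
        with pytest.raises(ValueError):
            pp.macenko_normalize(img, ref, source=src)


class TestAugment:
    def test_deterministic_for_fixed_seed(self, tumour_slide):
        tile = tumour_slide[0][:256, :256]
        assert np.array_equal(pp.augment(tile, 5), pp.augment(tile, 5))

    def test_geometric_only_preserves_pixel_multiset(self, tumour_slide):
        tile = tumour_slide[0][:256, :256]
        out = pp.augment(tile, 3, photometric=False)
        assert sorted(tile.reshape(-1, 3).sum(1)) == sorted(out.reshape(-1, 3).sum(1))

    def test_mean_shift_bounded_by_jitter(self, tumour_slide):
        tile = tumour_slide[0][:256, :256].astype(float) / 255.0
        rng = np.random.default_rng(0)
        ratios = []
        for _ in range(200):
            out = pp.augment(tile, rng, geometric=False)
            ratios.append(out.mean() / tile.mean())
        assert 0.93 <= np.mean(ratios) <= 1.07
        assert max(ratios) <= 1.12 and min(ratios) >= 0.88


class TestStandardize:
    def test_paper_means_map_to_zero(self):
        px = np.array(pp.DEFAULT_STANDARDIZATION.channel_means) * 255.0
        tile = np.broadcast_to(px, (2, 2, 3))
        out = pp.standardize(tile)
        assert np.allclose(out, 0.0, atol=1e-12)

    def test_mean_plus_std_maps_to_one(self):
        params = pp.DEFAULT_STANDARDIZATION
        px = (np.array(params.channel_means) + np.array(params.channel_stds)) * 255
        out = pp.standardize(np.broadcast_to(px, (2, 2, 3)))
        assert np.allclose(out, 1.0, atol=1e-12)

    def test_round_trip_within_quantization(self, rng):
        tile = rng.integers(0, 256, (16, 16, 3)).astype(np.uint8)
        back = pp.unstandardize(pp.standardize(tile))
        assert np.abs(back.astype(int) - tile.astype(int)).max() <= 1

    def test_zero_std_rejected(self):
        with pytest.raises(ValueError):
            pp.StandardizationParams((0.5, 0.5, 0.5), (0.1, 0.0, 0.1))
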