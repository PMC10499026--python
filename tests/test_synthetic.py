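"""Generator correctness: packing, patterns, renderers, tessellations,
textures, tracks, and correlated image pairs."""

import numpy as np
import pytest
from scipy import ndimage

from planarpol.conventions import angle_from_vector, angular_difference, wrap_angle
from planarpol.synthetic import (CapacityError, PatternSpec, gen_cell_tessellation,
                                 gen_coloc_pair, gen_follicle_positions,
                                 gen_orientation_pattern, gen_stripe_texture,
                                 gen_tracks, make_scene, render_placode_image)


class TestFolliclePositions:
    def test_single_point_inside_extent(self):
        p = gen_follicle_positions(1, (50, 40), seed=3)
        assert p.shape == (1, 2)
        assert 0 <= p[0, 0] <= 50 and 0 <= p[0, 1] <= 40

    def test_infeasible_packing_raises_capacity_error(self):
        with pytest.raises(CapacityError):
            gen_follicle_positions(4, (100, 100), min_spacing=200, seed=0)

    def test_min_spacing_by_exhaustive_pairwise_scan(self):
        p = gen_follicle_positions(200, (1000, 1000), min_spacing=15, seed=1)
        # O(n^2) oracle
        for i in range(len(p)):
            for j in range(i + 1, len(p)):
                assert np.hypot(*(p[i] - p[j])) >= 15.0

    def test_deterministic_for_fixed_seed(self):
        a = gen_follicle_positions(50, (300, 300), 10, seed=7)
        b = gen_follicle_positions(50, (300, 300), 10, seed=7)
        assert np.array_equal(a, b)


class TestOrientationPattern:
    def test_uniform_no_noise_gives_exact_base_angle(self):
        pos = gen_follicle_positions(20, (200, 200), seed=0)
        spec = PatternSpec(kind="uniform", base_angle=0.0, angular_noise_sd=0.0)
        recs = gen_orientation_pattern(pos, spec, seed=1)
        assert all(r.angle == 0.0 for r in recs)

    def test_reversed_patch_center_is_reversed(self):
        spec = PatternSpec(kind="reversed_patch", patch_center=(50.0, 50.0),
                           patch_radius=30.0, angular_noise_sd=0.0)
        recs = gen_orientation_pattern(np.array([[50.0, 50.0]]), spec, seed=0)
        assert recs[0].angle == pytest.approx(180.0)

    def test_whorl_matches_analytic_tangent_at_16_compass_points(self):
        cx, cy = 100.0, 100.0
        spec = PatternSpec(kind="whorl", patch_center=(cx, cy),
                           patch_radius=50.0, angular_noise_sd=0.0)
        for k in range(16):
            phi = 2 * np.pi * k / 16
            # compass position in image coordinates
            x = cx + 40 * np.cos(phi)
            y = cy + 40 * np.sin(phi)
            rec = gen_orientation_pattern(np.array([[x, y]]), spec, seed=0)[0]
            # analytic tangential oracle: radial biological angle + 90
            radial = angle_from_vector(x - cx, y - cy)
            assert abs(angular_difference(rec.angle, radial + 90.0)) < 1e-9

    def test_unpolarized_fraction_rounded_count(self):
        pos = gen_follicle_positions(40, (400, 400), seed=2)
        spec = PatternSpec(kind="uniform", unpolarized_fraction=0.25)
        recs = gen_orientation_pattern(pos, spec, seed=3)
        assert sum(not r.polarized for r in recs) == 10
        assert all(np.isnan(r.angle) for r in recs if not r.polarized)

    def test_unknown_kind_rejected(self):
        with pytest.raises(ValueError):
            PatternSpec(kind="spiral")


def _intensity_centroid(img):
    h, w = img.shape
    ys, xs = np.mgrid[0:h, 0:w]
    tot = img.sum()
    return (xs * img).sum() / tot, (ys * img).sum() / tot


class TestPlacodeRender:
    def test_polarized_centroid_offset_along_orientation(self):
        from planarpol.follicles import FollicleRecord
        rec = [FollicleRecord(0, 60.0, 60.0, 0.0, True)]
        img = render_placode_image(rec, (120, 120), blob_offset=6, noise_sd=0)
        ax, ay = _intensity_centroid(img[0])
        bx, by = _intensity_centroid(img[1])
        v = np.array([ax - bx, ay - by])
        assert np.hypot(*v) == pytest.approx(12.0, abs=0.5)
        assert abs(angular_difference(angle_from_vector(*v), 0.0)) < 1.0

    def test_unpolarized_channels_concentric(self):
        from planarpol.follicles import FollicleRecord
        rec = [FollicleRecord(0, 60.0, 60.0, polarized=False)]
        img = render_placode_image(rec, (120, 120), noise_sd=0)
        ax, ay = _intensity_centroid(img[0])
        bx, by = _intensity_centroid(img[1])
        assert np.hypot(ax - bx, ay - by) < 0.5

    def test_close_follicles_warn_not_error(self):
        from planarpol.follicles import FollicleRecord
        recs = [FollicleRecord(0, 50.0, 50.0, 0.0, True),
                FollicleRecord(1, 53.0, 50.0, 0.0, True)]
        with pytest.warns(UserWarning, match="blob_sigma"):
            render_placode_image(recs, (100, 100), blob_sigma=4, noise_sd=0)


class TestTessellation:
    def test_label_count_conserved(self):
        mask = gen_cell_tessellation(37, (200, 200), seed=1)
        labs = np.unique(mask)
        assert set(labs) == set(range(38))  # 0 background + 1..37

    def test_two_cells_split_by_one_boundary(self):
        mask = gen_cell_tessellation(2, (120, 60), seed=0)
        assert set(np.unique(mask)) == {0, 1, 2}

    def test_each_label_connected_by_flood_fill_oracle(self):
        mask = gen_cell_tessellation(60, (250, 250), seed=4)
        for lab in range(1, 61):
            comp, n = ndimage.label(mask == lab)
            assert n == 1

    def test_background_only_on_border_frame(self):
        mask = gen_cell_tessellation(20, (100, 100), seed=5)
        assert (mask[1:-1, 1:-1] > 0).all()
        assert (mask[0, :] == 0).all() and (mask[:, 0] == 0).all()


class TestStripeTexture:
    def test_angle_zero_rows_constant_along_anterior_axis(self):
        img = gen_stripe_texture((64, 64), angle=0.0, period=8)
        assert np.allclose(img, img[:, [0]])  # constant along x

    def test_rotating_request_by_90_transposes_anisotropy(self):
        a = gen_stripe_texture((64, 64), angle=0.0, period=8)
        b = gen_stripe_texture((64, 64), angle=90.0, period=8)
        assert np.allclose(np.ptp(a, axis=1), 0, atol=1e-9)
        assert np.allclose(np.ptp(b, axis=0), 0, atol=1e-9)

    def test_fft_peak_perpendicular_to_stripe_axis(self):
        angle = 30.0
        img = gen_stripe_texture((128, 128), angle=angle, period=16)
        spec = np.abs(np.fft.fftshift(np.fft.fft2(img - img.mean())))
        ky, kx = np.unravel_index(np.argmax(spec), spec.shape)
        ky -= 64
        kx -= 64
        # spectral oracle: wave vector along the stripe normal
        normal = angle_from_vector(kx, ky)
        d = abs(angular_difference(normal, angle + 90.0))
        assert min(d, abs(d - 180.0)) < 3.0


class TestTracks:
    def test_static_zero_noise_no_displacement(self):
        trs, _ = gen_tracks("static", n_cells=10, n_timepoints=20, seed=1)
        for tr in trs:
            assert np.ptp(tr.x) == 0 and np.ptp(tr.y) == 0

    def test_reversed_is_mirror_of_counter_rotational_track_by_track(self):
        c, _ = gen_tracks("counter_rotational", seed=3, extent=(200, 200))
        r, _ = gen_tracks("reversed", seed=3, extent=(200, 200))
        for tc, tr in zip(c, r):
            assert np.allclose(200 - tc.x, tr.x)
            assert np.allclose(tc.y, tr.y)

    def test_posterior_cells_converge_anteriorly_in_counter_rotation(self):
        trs, info = gen_tracks("counter_rotational", seed=5, extent=(200, 200))
        cx = info["center"][0]
        post = [tr for tr in trs if tr.x[0] > cx]
        disp = np.mean([tr.x[-1] - tr.x[0] for tr in post])
        assert disp < 0  # toward anterior (-x)


class TestColocPair:
    @pytest.mark.parametrize("r", [-0.8, 0.0, 0.5, 0.95])
    def test_target_correlation_achieved(self, r):
        from planarpol.intensity import masked_pearson
        a, b, nuc = gen_coloc_pair((200, 200), target_r=r, seed=7)
        got = masked_pearson(a, b, nuc).pearson_r
        assert got == pytest.approx(r, abs=0.02)

    def test_perfect_correlation_is_affine_image(self):
        from planarpol.intensity import masked_pearson
        a, b, nuc = gen_coloc_pair((128, 128), target_r=1.0, seed=1)
        assert masked_pearson(a, b, nuc).pearson_r == pytest.approx(1.0, abs=1e-6)


def test_scene_determinism_bit_exact():
    pat = PatternSpec(kind="reversed_patch", patch_center=(150, 150),
                      patch_radius=80)
    s1 = make_scene(pat, n=30, extent=(300, 300), min_spacing=20, seed=9)
    s2 = make_scene(pat, n=30, extent=(300, 300), min_spacing=20, seed=9)
    assert np.array_equal(s1.images["pcad"], s2.images["pcad"])
    assert np.array_equal(s1.images["sox9"], s2.images["sox9"])
    for a, b in zip(s1.follicles, s2.follicles):
        assert (a.x, a.y, a.polarized) == (b.x, b.y, b.polarized)
        assert a.angle == b.angle or (np.isnan(a.angle) and np.isnan(b.angle))
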