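"""Order-parameter anchors, brute-force equivalence, and invariances."""

import numpy as np
import pytest

from planarpol.follicles import FollicleRecord
from planarpol.order import (NeighborhoodSpec, local_order,
                             mean_min_neighbor_distance, minmax_rescale,
                             order_color, order_heatmap)


def brute_force_local_order(positions, angles, polarized, radius):
    """Independent O(n^2) oracle: all unordered pairs of polarized
    follicles within `radius` of each focal follicle."""
    out = []
    for i in range(len(positions)):
        if not polarized[i]:
            out.append(np.nan)
            continue
        hood = [j for j in range(len(positions))
                if polarized[j]
                and np.hypot(*(positions[i] - positions[j])) <= radius]
        if len(hood) < 2:
            out.append(np.nan)
            continue
        cosines = []
        for a in range(len(hood)):
            for b in range(a + 1, len(hood)):
                d = np.deg2rad(angles[hood[a]] - angles[hood[b]])
                cosines.append(np.cos(d))
        out.append((1.0 + np.mean(cosines)) / 2.0)
    return np.array(out)


def _records(positions, angles, polarized=None):
    polarized = polarized if polarized is not None else [True] * len(positions)
    return [FollicleRecord(i, positions[i][0], positions[i][1],
                           angles[i] if polarized[i] else float("nan"),
                           polarized[i])
            for i in range(len(positions))]


class TestMeanMinNeighborDistance:
    def test_square_grid_equals_spacing(self):
        xs, ys = np.meshgrid(np.arange(5) * 7.0, np.arange(5) * 7.0)
        pos = np.column_stack([xs.ravel(), ys.ravel()])
        assert mean_min_neighbor_distance(pos) == pytest.approx(7.0)

    def test_two_points(self):
        assert mean_min_neighbor_distance([[0, 0], [3, 4]]) == pytest.approx(5.0)

    def test_matches_exhaustive_oracle(self):
        rng = np.random.default_rng(1)
        pos = rng.uniform(0, 500, (300, 2))
        d = np.full(300, np.inf)
        for i in range(300):
            for j in range(300):
                if i != j:
                    d[i] = min(d[i], np.hypot(*(pos[i] - pos[j])))
        assert mean_min_neighbor_distance(pos) == pytest.approx(d.mean(), abs=1e-9)

    def test_single_point_rejected(self):
        with pytest.raises(ValueError):
            mean_min_neighbor_distance([[1, 2]])


class TestLocalOrder:
    def test_parallel_field_order_one_any_angle(self):
        for theta in [0.0, 67.0, -120.0]:
            pos = np.random.default_rng(0).uniform(0, 100, (20, 2))
            recs = _records(pos, [theta] * 20)
            orders = local_order(recs, NeighborhoodSpec("postnatal",
                                                        fixed_radius=500))
            assert all(o.order == pytest.approx(1.0) for o in orders)

    def test_antiparallel_pair_order_zero(self):
        recs = _records([[0, 0], [10, 0]], [0.0, 180.0])
        orders = local_order(recs, NeighborhoodSpec("postnatal", fixed_radius=50))
        assert all(o.order == pytest.approx(0.0, abs=1e-12) for o in orders)

    def test_orthogonal_pair_order_half(self):
        recs = _records([[0, 0], [10, 0]], [0.0, 90.0])
        orders = local_order(recs, NeighborhoodSpec("postnatal", fixed_radius=50))
        assert all(o.order == pytest.approx(0.5) for o in orders)

    def test_matches_brute_force_oracle_on_random_field(self):
        rng = np.random.default_rng(3)
        pos = rng.uniform(0, 300, (150, 2))
        ang = rng.uniform(-180, 180, 150)
        pol = rng.random(150) > 0.1
        radius = float(rng.uniform(30, 120))
        recs = _records(pos, ang, list(pol))
        got = np.array([o.order for o in local_order(
            recs, NeighborhoodSpec("postnatal", fixed_radius=radius))])
        want = brute_force_local_order(pos, ang, pol, radius)
        assert np.allclose(got[np.isfinite(want)], want[np.isfinite(want)],
                           atol=1e-9)
        assert np.array_equal(np.isnan(got), np.isnan(want))

    def test_global_rotation_invariance(self):
        rng = np.random.default_rng(4)
        pos = rng.uniform(0, 200, (50, 2))
        ang = rng.uniform(-180, 180, 50)
        spec = NeighborhoodSpec("postnatal", fixed_radius=80)
        base = [o.order for o in local_order(_records(pos, ang), spec)]
        shifted = [o.order for o in local_order(_records(pos, ang + 77.0), spec)]
        assert np.allclose(base, shifted, atol=1e-9)

    def test_permutation_invariance(self):
        rng = np.random.default_rng(5)
        pos = rng.uniform(0, 200, (40, 2))
        ang = rng.uniform(-180, 180, 40)
        spec = NeighborhoodSpec("postnatal", fixed_radius=60)
        a = {o.follicle_id: o.order for o in local_order(_records(pos, ang), spec)}
        perm = rng.permutation(40)
        recs = [_records(pos, ang)[i] for i in perm]
        b = {o.follicle_id: o.order for o in local_order(recs, spec)}
        for k in a:
            assert a[k] == pytest.approx(b[k], abs=1e-12)

    def test_sentinel_when_fewer_than_two_polarized_members(self):
        recs = _records([[0, 0], [200, 200]], [0.0, 10.0])
        orders = local_order(recs, NeighborhoodSpec("postnatal", fixed_radius=10))
        assert all(np.isnan(o.order) for o in orders)

    def test_random_angles_mean_order_near_half(self):
        # dense uniform-random directions: mean pairwise cosine -> 0
        rng = np.random.default_rng(6)
        pos = rng.uniform(0, 100, (400, 2))
        ang = rng.uniform(-180, 180, 400)
        orders = local_order(_records(pos, ang),
                             NeighborhoodSpec("postnatal", fixed_radius=150))
        vals = np.array([o.order for o in orders])
        # neighborhoods hold ~hundreds of pairs; SE of the mean order is small
        assert abs(vals.mean() - 0.5) < 0.05

    def test_focal_pairs_variant_agrees_on_anchors(self):
        recs = _records([[0, 0], [10, 0]], [0.0, 180.0])
        spec = NeighborhoodSpec("postnatal", fixed_radius=50)
        assert all(o.order == pytest.approx(0.0, abs=1e-12)
                   for o in local_order(recs, spec, pairs="focal"))
        recs2 = _records([[0, 0], [10, 0], [5, 5]], [42.0] * 3)
        assert all(o.order == pytest.approx(1.0)
                   for o in local_order(recs2, spec, pairs="focal"))


class TestReversalRing:
    def test_low_order_ring_surrounds_reversed_patch(self, reversed_patch_field):
        pos, recs, pat = reversed_patch_field
        d = mean_min_neighbor_distance(pos)
        orders = local_order(recs, NeighborhoodSpec("embryonic"))
        o = np.array([x.order for x in orders])
        r = np.hypot(pos[:, 0] - 500, pos[:, 1] - 500)
        deep_in = r < 300 - 3 * d
        deep_out = r > 300 + 3 * d
        assert np.nanmin(o[deep_in]) > 0.9
        assert np.nanmin(o[deep_out]) > 0.9
        # contiguous low-order ring: every angular sector of the boundary
        # band contains a follicle with order < 0.5
        band = np.abs(r - 300) < d
        theta = np.arctan2(pos[:, 1] - 500, pos[:, 0] - 500)
        sectors = ((theta + np.pi) / (2 * np.pi) * 8).astype(int) % 8
        for s in range(8):
            sel = band & (sectors == s)
            assert sel.any()
            assert np.nanmin(o[sel]) < 0.5


class TestHeatmap:
    def test_order_one_is_white_and_sentinel_black(self):
        assert order_color(1.0)[:3] == pytest.approx((1.0, 0.96, 0.94), abs=0.05)
        assert order_color(float("nan")) == (0.0, 0.0, 0.0, 1.0)

    def test_redness_monotone_in_order(self):
        # redness = deficit of the non-red channels (white -> 0, red -> 1)
        reds = [1.0 - np.mean(order_color(o)[1:3])
                for o in np.linspace(0, 1, 21)]
        assert all(reds[i] >= reds[i + 1] - 1e-12 for i in range(20))

    def test_heatmap_raster_shapes_and_black_sentinels(self):
        recs = _records([[10, 10], [40, 40], [10, 40]], [0.0, 0.0, 0.0])
        orders = local_order(recs, NeighborhoodSpec("postnatal", fixed_radius=100))
        img = order_heatmap(orders, recs, (50, 50))
        assert img.shape == (50, 50, 4)

    def test_minmax_rescale_spans_unit_interval(self):
        out = minmax_rescale(np.array([0.2, 0.5, 0.9, np.nan]))
        assert np.nanmin(out) == 0.0 and np.nanmax(out) == 1.0
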