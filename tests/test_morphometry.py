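import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from nucleomech import morphometry as mo, synth
from nucleomech.errors import InsufficientSignalError, ValidationError
from nucleomech.stacks import LabelMask

from conftest import polygon_arc_length


def regular_polygon(n, r=1.0, cx=0.0, cy=0.0):
    th = np.linspace(0, 2 * np.pi, n, endpoint=False)
    return np.c_[cx + r * np.cos(th), cy + r * np.sin(th)]


class TestEopPolygon:
    def test_convex_is_one(self):
        geom = mo.compute_eop_polygon(regular_polygon(64))
        assert geom.eop == pytest.approx(1.0, abs=1e-12)

    def test_unit_square_slit_closed_form(self):
        # slit of length 0.25 traversed twice: eop = (4 + 0.5)/4 = 1.125
        square = np.array([[0.0, 0.0], [1.0, 0.0], [1.0, 1.0], [0.0, 1.0]])
        slit = np.array([[0.5, 1.0], [0.5, 0.75], [0.5, 1.0]])
        geom = mo.compute_eop_polygon(square, [slit])
        assert geom.eop == pytest.approx(1.125, rel=1e-12)

    @settings(max_examples=30, deadline=None)
    @given(st.integers(min_value=3, max_value=100), st.integers(min_value=0, max_value=10**6))
    def test_matches_arc_length_oracle(self, n, seed):
        rng = np.random.default_rng(seed)
        # star-shaped polygon: strictly increasing angles, random radii
        th = np.sort(rng.uniform(0, 2 * np.pi, n))
        if len(np.unique(th)) < 3:
            return
        r = rng.uniform(0.5, 2.0, len(th))
        poly = np.c_[r * np.cos(th), r * np.sin(th)]
        from scipy.spatial import ConvexHull

        try:
            geom = mo.compute_eop_polygon(poly)
        except ValidationError:
            return  # degenerate random polygon
        hull = ConvexHull(poly)
        oracle = polygon_arc_length(poly) / polygon_arc_length(poly[hull.vertices])
        assert geom.eop == pytest.approx(oracle, rel=1e-12)

    def test_rigid_motion_and_scale_invariance(self):
        square = np.array([[0.0, 0.0], [1.0, 0.0], [1.0, 1.0], [0.0, 1.0]])
        slit = np.array([[0.5, 1.0], [0.5, 0.6]])
        base = mo.compute_eop_polygon(square, [slit]).eop
        th = 0.61
        R = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
        for scale in (0.1, 3.7):
            sq2 = scale * square @ R.T + [5.0, -2.0]
            sl2 = scale * slit @ R.T + [5.0, -2.0]
            assert mo.compute_eop_polygon(sq2, [sl2]).eop == pytest.approx(base, rel=1e-9)

    def test_monotone_in_internal_length(self):
        square = np.array([[0.0, 0.0], [1.0, 0.0], [1.0, 1.0], [0.0, 1.0]])
        eops = [
            mo.compute_eop_polygon(square, [np.array([[0.5, 1.0], [0.5, 1.0 - d]])]).eop
            for d in (0.1, 0.2, 0.4)
        ]
        assert eops[0] < eops[1] < eops[2]

    def test_degenerate_outline_errors(self):
        with pytest.raises(ValidationError):
            mo.compute_eop_polygon(np.array([[0.0, 0.0], [1.0, 0.0], [2.0, 0.0]]))


class TestEopSkeleton:
    def test_convex_circle_is_one(self):
        mask, skel, _, _ = synth.synth_nucleus(semi_axes_um=(6.0, 6.0), invaginations=[])
        geom = mo.compute_eop_skeleton(skel, mask.labels > 0, 0.1)
        assert geom.eop == pytest.approx(1.0, abs=0.01)

    @pytest.mark.parametrize("depth", [1.0, 2.0, 3.0])
    def test_recovers_generator_truth_within_3pct(self, depth):
        mask, skel, _, gt = synth.synth_nucleus(
            semi_axes_um=(8.0, 5.0),
            invaginations=[(30.0, depth, 0.4), (200.0, 1.2, 0.4)],
            pixel_size_um=0.1,
        )
        geom = mo.compute_eop_skeleton(skel, mask.labels > 0, 0.1)
        assert geom.eop == pytest.approx(gt["eop"], rel=0.03)

    def test_missing_ring_warns_and_uses_boundary(self):
        mask, skel, _, _ = synth.synth_nucleus(semi_axes_um=(5.0, 5.0), invaginations=[])
        with pytest.warns(UserWarning, match="ring"):
            geom = mo.compute_eop_skeleton(np.zeros_like(skel), mask.labels > 0, 0.1)
        assert geom.eop == pytest.approx(1.0, abs=0.01)

    def test_empty_mask_errors(self):
        with pytest.raises(ValidationError):
            mo.compute_eop_skeleton(np.zeros((8, 8)), np.zeros((8, 8)))


class TestOrientFront:
    def make_mask(self):
        m = np.zeros((21, 21), dtype=np.int32)
        m[8:13, 8:13] = 1
        return LabelMask(m)  # centroid (10, 10)

    def test_golgi_due_east_identity(self):
        assert mo.orient_front(self.make_mask(), golgi_centroid=(18.0, 10.0)) == pytest.approx(0.0)

    def test_golgi_due_north_quarter_turn(self):
        # image y grows downward; "north" in array coordinates is -y
        angle = mo.orient_front(self.make_mask(), golgi_centroid=(10.0, 2.0))
        assert angle == pytest.approx(-np.pi / 2)

    def test_coincident_centroids_error(self):
        with pytest.raises(ValidationError):
            mo.orient_front(self.make_mask(), golgi_centroid=(10.0, 10.0))

    def test_pattern_axis_sign_from_golgi(self):
        angle = mo.orient_front(
            self.make_mask(), golgi_centroid=(2.0, 10.0), pattern_axis=(1.0, 0.0)
        )
        assert angle == pytest.approx(np.pi)  # golgi west flips the axis

    def test_random_orientations_map_golgi_to_positive_x(self):
        cells, _ = synth.synth_polarized_cell(0.7, n_cells=30, seed=5)
        for cell in cells:
            angle = mo.orient_front(cell["mask"], golgi_centroid=cell["golgi_centroid"])
            mask = cell["mask"].labels > 0
            yy, xx = np.nonzero(mask)
            gx, gy = cell["golgi_centroid"]
            dx, dy = gx - xx.mean(), gy - yy.mean()
            rotated_x = np.cos(-angle) * dx - np.sin(-angle) * dy
            assert rotated_x > 0


class TestPolarityMap:
    def test_exact_top_quantile_count(self):
        rng = np.random.default_rng(0)
        mask = np.zeros((20, 20), dtype=bool)
        mask[3:17, 3:17] = True
        signal = rng.random((20, 20))
        ty, tx = mo.top_quantile_pixels(signal, mask, quantile=0.80)
        assert len(ty) == int(np.ceil(0.2 * mask.sum()))

    def test_tie_break_by_intensity_then_raster(self):
        mask = np.ones((3, 3), dtype=bool)
        signal = np.array([[5.0, 5.0, 5.0], [1.0, 1.0, 1.0], [1.0, 1.0, 1.0]])
        ty, tx = mo.top_quantile_pixels(signal, mask, quantile=0.70)
        # ceil(0.3 * 9) = 3 pixels, all from the tied top row in raster order
        assert list(zip(ty, tx)) == [(0, 0), (0, 1), (0, 2)]

    def test_front_fraction_one_all_samples_positive(self):
        cells, _ = synth.synth_polarized_cell(1.0, n_cells=10, seed=2)
        for c in cells:
            c["front_angle_rad"] = mo.orient_front(c["mask"], golgi_centroid=c["golgi_centroid"])
        pmap = mo.polarity_map(cells)
        assert np.all(pmap.pooled_axis_samples > 0)

    def test_uniform_nuclei_symmetric_occupancy(self):
        cells, _ = synth.synth_polarized_cell(0.5, n_cells=100, image_shape=(48, 48), seed=8)
        for c in cells:
            c["front_angle_rad"] = mo.orient_front(c["mask"], golgi_centroid=c["golgi_centroid"])
        pmap = mo.polarity_map(cells, grid_shape=(32, 32))
        front = pmap.grid[:, 16:].mean()
        rear = pmap.grid[:, :16].mean()
        pooled = pmap.pooled_axis_samples
        se = 2.0 * pooled.std() / np.sqrt(len(pooled))
        assert abs(pooled.mean()) < se
        assert abs(front - rear) < 0.05

    def test_small_mask_skipped(self, caplog):
        good = {
            "signal": np.random.default_rng(0).random((30, 30)),
            "mask": np.pad(np.ones((12, 12), dtype=int), 9),
            "front_angle_rad": 0.0,
        }
        tiny = {
            "signal": np.ones((30, 30)),
            "mask": np.pad(np.ones((2, 2), dtype=int), 14),
            "front_angle_rad": 0.0,
        }
        with caplog.at_level("WARNING"):
            pmap = mo.polarity_map([good, tiny])
        assert pmap.n_cells == 1

    def test_occupancy_bounds(self):
        cells, _ = synth.synth_polarized_cell(0.7, n_cells=20, seed=4)
        for c in cells:
            c["front_angle_rad"] = mo.orient_front(c["mask"], golgi_centroid=c["golgi_centroid"])
        pmap = mo.polarity_map(cells)
        assert pmap.grid.min() >= 0.0 and pmap.grid.max() <= 1.0
        assert np.all(np.abs(pmap.pooled_axis_samples) <= 1.0)


class TestFrontRearTest:
    def test_symmetric_sample_statistic_zero(self):
        a = np.random.default_rng(0).uniform(0.1, 1.0, 20)
        x = np.concatenate([a, -a])  # exactly mirror-symmetric multiset
        stat, p = mo.front_rear_test(x)
        assert stat == 0.0
        assert p == pytest.approx(1.0)

    def test_all_positive_statistic_one(self):
        stat, _ = mo.front_rear_test(np.linspace(0.1, 1.0, 50))
        assert stat == 1.0

    def test_label_swap_symmetry(self):
        rng = np.random.default_rng(7)
        x = rng.normal(0.1, 0.5, 400)
        s1, p1 = mo.front_rear_test(x)
        s2, p2 = mo.front_rear_test(-x)
        assert s1 == s2 and p1 == p2

    def test_too_few_samples(self):
        with pytest.raises(InsufficientSignalError):
            mo.front_rear_test(np.array([0.1, -0.2, 0.3]))

    def test_null_calibration_quick(self):
        # smoke-level calibration (full 1000-replicate version is in acceptance)
        rng = np.random.default_rng(0)
        rej = sum(mo.front_rear_test(rng.normal(size=400))[1] < 0.05 for _ in range(200))
        assert 0.01 <= rej / 200 <= 0.10

    def test_detects_bias(self):
        rng = np.random.default_rng(1)
        stat, p = mo.front_rear_test(rng.normal(0.3, 1.0, 1000))
        assert p < 0.01


class TestConditionTest:
    def test_identical_samples_high_p(self):
        x = np.linspace(-1, 1, 100)
        stat, p = mo.condition_test(x, x.copy())
        assert p > 0.5

    def test_disjoint_supports_large_statistic(self):
        a = np.linspace(-1.0, -0.5, 100)
        b = np.linspace(0.5, 1.0, 100)
        stat_far, p = mo.condition_test(a, b)
        stat_same, _ = mo.condition_test(a, a.copy())
        assert stat_far > 10 * max(stat_same, 1e-6)
        assert p < 0.01

    def test_power_against_shifted_fraction(self):
        hits = 0
        for rep in range(20):
            cells_a, _ = synth.synth_polarized_cell(0.7, n_cells=50, image_shape=(48, 48), seed=rep)
            cells_b, _ = synth.synth_polarized_cell(
                0.5, n_cells=50, image_shape=(48, 48), seed=1000 + rep
            )
            for c in cells_a + cells_b:
                c["front_angle_rad"] = mo.orient_front(
                    c["mask"], golgi_centroid=c["golgi_centroid"]
                )
            pa = mo.polarity_map(cells_a, grid_shape=(32, 32))
            pb = mo.polarity_map(cells_b, grid_shape=(32, 32))
            _, p = mo.condition_test(pa, pb)
            hits += p < 0.05
        assert hits >= 18

    def test_too_few_samples(self):
        with pytest.raises(InsufficientSignalError):
            mo.condition_test(np.arange(5.0), np.arange(20.0))
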