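import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from brachykerma import (StructureMask, cumulative_dvh, dhi,
                         evaluate_metric, rasterize_structure)
from brachykerma.errors import (EmptyStructureError,
                                InsufficientVolumeError,
                                UndefinedMetricError)


def _mask(shape=(10, 1, 1), on=None):
    m = np.zeros(shape, bool)
    if on is None:
        m[:] = True
    else:
        m[on] = True
    return StructureMask("S", m)


class TestRasterization:
    def test_square_contour_counts_covered_centers(self):
        # 10x10 grid of 1 mm voxels with centers at 0..9; a square from
        # -0.5 to 4.5 covers exactly the 5x5 centers 0..4
        poly = np.array([[-0.5, -0.5], [4.5, -0.5], [4.5, 4.5],
                         [-0.5, 4.5]])
        s = rasterize_structure("sq", [(0.0, poly)], (10, 10, 1),
                                (1.0, 1.0, 1.0), (0.0, 0.0, 0.0))
        assert s.n_voxels == 25
        assert s.volume_cm3(0.001) == pytest.approx(0.025)
        assert np.all(s.mask[:5, :5, 0])

    def test_contour_enclosing_no_centers(self):
        poly = np.array([[0.1, 0.1], [0.4, 0.1], [0.4, 0.4], [0.1, 0.4]])
        s = rasterize_structure("tiny", [(0.0, poly)], (5, 5, 1),
                                (1.0, 1.0, 1.0), (0.0, 0.0, 0.0))
        assert s.n_voxels == 0

    def test_center_on_contour_edge_is_inside(self):
        poly = np.array([[0.0, 0.0], [2.0, 0.0], [2.0, 2.0], [0.0, 2.0]])
        s = rasterize_structure("edge", [(0.0, poly)], (5, 5, 1),
                                (1.0, 1.0, 1.0), (0.0, 0.0, 0.0))
        # corners and edge centers (e.g. (1, 0)) count as inside
        assert s.mask[1, 0, 0] and s.mask[0, 0, 0] and s.mask[2, 2, 0]

    def test_random_polygons_match_point_in_polygon_oracle(self):
        """Rasterization must equal an independent per-center point test
        (shapely ``covers``, which is inside-or-boundary) on random
        star-shaped polygons."""
        from shapely.geometry import Point, Polygon

        rng = np.random.default_rng(14)
        for _ in range(50):
            nv = rng.integers(3, 12)
            ang = np.sort(rng.uniform(0, 2 * np.pi, nv))
            rad = rng.uniform(1.0, 6.0, nv)
            cx, cy = rng.uniform(2, 10, 2)
            poly = np.column_stack([cx + rad * np.cos(ang),
                                    cy + rad * np.sin(ang)])
            s = rasterize_structure("p", [(0.0, poly)], (14, 14, 1),
                                    (1.0, 1.0, 1.0), (0.0, 0.0, 0.0))
            shp = Polygon(poly)
            for i in range(14):
                for j in range(14):
                    assert s.mask[i, j, 0] == shp.covers(Point(i, j)), \
                        (poly, i, j)

    def test_self_intersecting_contour_warns_but_rasterizes(self):
        bowtie = np.array([[0.0, 0.0], [3.0, 3.0], [3.0, 0.0], [0.0, 3.0]])
        with pytest.warns(UserWarning, match="self-intersecting"):
            s = rasterize_structure("bt", [(0.0, bowtie)], (5, 5, 1),
                                    (1.0, 1.0, 1.0), (0.0, 0.0, 0.0),
                                    check_self_intersection=True)
        assert s.mask.any()


class TestDVHCurve:
    def test_uniform_dose_step_curve(self):
        d = np.full((10, 1, 1), 34.0)
        curve = cumulative_dvh(d, _mask(), prescription=34.0)
        assert curve.fraction_at(33.9) == 1.0
        assert curve.fraction_at(34.0) == 1.0  # >= convention
        assert curve.fraction_at(34.1) == 0.0

    def test_quartile_doses_v100(self):
        d = np.array([17.0, 34.0, 51.0, 68.0]).reshape(4, 1, 1)
        curve = cumulative_dvh(d, _mask((4, 1, 1)), prescription=34.0)
        assert curve.fraction_at(34.0) == pytest.approx(0.75)

    def test_empty_structure_rejected(self):
        empty = StructureMask("E", np.zeros((2, 2, 2), bool))
        with pytest.raises(EmptyStructureError):
            cumulative_dvh(np.ones((2, 2, 2)), empty, prescription=1.0)

    def test_curve_consistent_with_metric_evaluation(self):
        rng = np.random.default_rng(2)
        d = rng.gamma(3.0, 10.0, (50, 1, 1))
        curve = cumulative_dvh(d, _mask((50, 1, 1)), prescription=34.0)
        doses = d.ravel()
        for x in (50, 90, 100, 150):
            assert curve.fraction_at(x / 100 * 34.0) * 100 == \
                pytest.approx(evaluate_metric(doses, f"V{x}%", 34.0))


class TestMetrics:
    def test_all_voxels_at_ninety_percent(self):
        doses = np.full(1000, 0.9 * 34.0)
        assert evaluate_metric(doses, "V90%", 34.0) == 100.0
        assert evaluate_metric(doses, "V100%", 34.0) == 0.0

    def test_d01cc_is_order_statistic(self):
        doses = np.arange(1.0, 201.0)  # 200 voxels of 1 mm^3
        got = evaluate_metric(doses, "D0.1cm3", 100.0,
                              voxel_volume_cm3=0.001)
        # hottest 100 voxels are 101..200; their minimum is 101
        assert got == pytest.approx(101.0)

    def test_structure_smaller_than_volume_rejected(self):
        with pytest.raises(InsufficientVolumeError):
            evaluate_metric(np.ones(5), "D0.1cm3", 1.0,
                            voxel_volume_cm3=0.001)

    @pytest.mark.parametrize("trial", range(10))
    def test_metrics_match_sorted_list_oracle(self, trial):
        """V_x, D_x and D_v must equal brute-force definitions applied to
        the sorted dose list."""
        rng = np.random.default_rng(100 + trial)
        n = int(rng.integers(50, 2000))
        doses = rng.gamma(2.0, 15.0, n)
        presc = 34.0
        vv = 0.001
        srt = np.sort(doses)[::-1]
        for x in rng.uniform(5, 195, 4):
            level = x / 100 * presc
            assert evaluate_metric(doses, f"V{x}%", presc) == \
                pytest.approx(np.sum(srt >= level) / n * 100)
        for x in rng.uniform(5, 99, 4):
            kk = int(np.ceil(x / 100 * n))
            assert evaluate_metric(doses, f"D{x}%", presc) == \
                pytest.approx(srt[kk - 1] / presc * 100)
        v = 0.1
        kk = int(np.ceil(v / vv))
        if kk <= n:
            assert evaluate_metric(doses, f"D{v}cm3", presc,
                                   voxel_volume_cm3=vv) == \
                pytest.approx(srt[kk - 1] / presc * 100)

    @settings(derandomize=True, max_examples=40, deadline=None)
    @given(st.lists(st.floats(0.0, 200.0), min_size=1, max_size=200))
    def test_v_metric_ordering_invariant(self, doses):
        doses = np.asarray(doses)
        v90 = evaluate_metric(doses, "V90%", 34.0)
        v100 = evaluate_metric(doses, "V100%", 34.0)
        v200 = evaluate_metric(doses, "V200%", 34.0)
        assert v90 >= v100 >= v200
        assert 0.0 <= v200 and v90 <= 100.0


class TestDHI:
    def test_arithmetic(self):
        # 25 of 50 voxels above 150%: DHI = 1 - 25/50 = 0.5
        d = np.concatenate([np.full(25, 1.2), np.full(25, 1.6)])
        g = d.reshape(50, 1, 1)
        assert dhi(g, _mask((50, 1, 1)), prescription=1.0) == \
            pytest.approx(0.5)

    def test_limits(self):
        hot = np.full((10, 1, 1), 2.0)
        assert dhi(hot, _mask(), 1.0) == 0.0
        mild = np.full((10, 1, 1), 1.2)
        assert dhi(mild, _mask(), 1.0) == 1.0

    def test_undefined_without_coverage(self):
        cold = np.full((10, 1, 1), 0.5)
        with pytest.raises(UndefinedMetricError):
            dhi(cold, _mask(), 1.0)
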