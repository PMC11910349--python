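import numpy as np
import pytest

from brachykerma import (DoseGrid, DwellPlan, Material, Scheme,
                         VoxelPhantom, build_phantom, load_materials,
                         run_simulation, trace_ray, type_a_uncertainty)
from brachykerma._kernel import MEC2_KEV, _init_stream, _sample_kn
from brachykerma.errors import (EmptySelectionError, InvalidInputError)


class TestTraceRay:
    def test_axis_aligned_unit_chords(self, water_phantom):
        idx, chords = trace_ray(water_phantom, (-55.5, 0.0, 0.0),
                                (1.0, 0.0, 0.0), 3.0)
        np.testing.assert_allclose(chords, [1.0, 1.0, 1.0])
        assert np.all(idx[:, 0] == [0, 1, 2])

    def test_diagonal_through_voxel_corner(self):
        hu = np.zeros((1, 1, 1))
        ph = build_phantom(hu, (1.0,) * 3, (0.5, 0.5, 0.5),
                           scheme=Scheme.WATER_UNBOUND)
        idx, chords = trace_ray(ph, (0.0, 0.0, 0.5),
                                (1 / np.sqrt(2), 1 / np.sqrt(2), 0.0), 10.0)
        assert chords.sum() == pytest.approx(np.sqrt(2.0), abs=1e-9)

    def test_random_rays_chord_sums_match_path_integration(self,
                                                           water_phantom):
        """Chord sums must equal the geometric in-grid path length, and
        each chord midpoint must map back to its claimed voxel (sampling
        oracle)."""
        rng = np.random.default_rng(21)
        lo = water_phantom.origin - 0.5
        hi = lo + 111.0
        for _ in range(30):
            o = rng.uniform(-80, 80, 3)
            d = rng.normal(size=3)
            d /= np.linalg.norm(d)
            max_len = rng.uniform(10, 300)
            idx, chords = trace_ray(water_phantom, o, d, max_len)
            # independent slab-clipping oracle for total in-grid length
            t0, t1 = 0.0, max_len
            for ax in range(3):
                if d[ax] != 0:
                    ta = (lo[ax] - o[ax]) / d[ax]
                    tb = (hi[ax] - o[ax]) / d[ax]
                    t0 = max(t0, min(ta, tb))
                    t1 = min(t1, max(ta, tb))
                elif not lo[ax] < o[ax] < hi[ax]:
                    t0, t1 = 0.0, 0.0
            expect = max(0.0, t1 - t0)
            assert chords.sum() == pytest.approx(expect, abs=1e-6)
            # midpoints of chords must land in the reported voxels
            t = t0
            for (i, j, k), c in zip(idx, chords):
                p = o + (t + 0.5 * c) * d
                np.testing.assert_array_equal(
                    np.floor((p - lo) / 1.0).astype(int), (i, j, k))
                t += c

    def test_zero_direction_rejected(self, water_phantom):
        with pytest.raises(InvalidInputError):
            trace_ray(water_phantom, (0, 0, 0), (0, 0, 0), 10.0)


class TestKleinNishina:
    def test_mean_scattered_energy_matches_quadrature(self):
        """Mean E'/E of sampled 662 keV Compton scatters must match the
        numerically integrated Klein-Nishina differential cross section
        within 0.5%."""
        k = 662.0 / MEC2_KEV
        mu = np.linspace(-1.0, 1.0, 20001)
        eps = 1.0 / (1.0 + k * (1.0 - mu))
        dsig = eps ** 2 * (eps + 1.0 / eps - (1.0 - mu ** 2))
        mean_eps_quad = np.trapezoid(dsig * eps, mu) / np.trapezoid(dsig, mu)
        st = np.zeros(1, np.uint64)
        _init_stream(st, 123, 0)
        n = 100_000
        acc = 0.0
        for _ in range(n):
            e, _c = _sample_kn(st, k)
            acc += e
        assert acc / n == pytest.approx(mean_eps_quad, rel=5e-3)

    def test_scatter_kinematics_consistent(self):
        st = np.zeros(1, np.uint64)
        _init_stream(st, 5, 9)
        k = 300.0 / MEC2_KEV
        for _ in range(200):
            eps, cos_t = _sample_kn(st, k)
            # Compton relation between energy ratio and angle
            assert eps == pytest.approx(1.0 / (1.0 + k * (1.0 - cos_t)),
                                        rel=1e-10)
            assert 1.0 / (1.0 + 2.0 * k) - 1e-12 <= eps <= 1.0 + 1e-12


class TestSimulation:
    def test_inverse_square_in_negligible_attenuation(self, spectrum):
        """Air-filled grid: kerma ratio at 10 vs 20 mm is 4 within the MC
        3-sigma band (attenuation over 20 mm of air is ~0.1%)."""
        hu = np.full((81, 81, 81), -1000.0)
        ph = build_phantom(hu, (1.0,) * 3, (-40.0, -40.0, -40.0),
                           scheme=Scheme.HETEROGENEOUS)
        plan = DwellPlan([[0.0, 0.0, 0.0]], [10.0])
        grid = run_simulation(ph, plan, spectrum, 400_000, n_batches=10,
                              seed=3, per_decay=True)
        x = ph.voxel_centers(0)
        X, Y, Z = np.meshgrid(x, x, x, indexing="ij")
        r = np.sqrt(X ** 2 + Y ** 2 + Z ** 2)
        se = grid.standard_error()
        m10, m20 = (np.abs(r - 10) < 0.5), (np.abs(r - 20) < 0.5)
        # dose * r^2 is flat under the inverse-square law, so the shell
        # means compare without the finite-shell-width weighting bias
        f10 = np.mean(grid.dose[m10] * r[m10] ** 2)
        f20 = np.mean(grid.dose[m20] * r[m20] ** 2)
        s10 = np.sqrt(np.sum((se[m10] * r[m10] ** 2) ** 2)) / m10.sum()
        s20 = np.sqrt(np.sum((se[m20] * r[m20] ** 2) ** 2)) / m20.sum()
        ratio = 4.0 * f10 / f20
        sigma = ratio * np.sqrt((s10 / f10) ** 2 + (s20 / f20) ** 2)
        assert abs(ratio - 4.0) < max(3 * sigma, 0.02)

    def test_same_seed_is_bit_identical(self, water_phantom,
                                        single_dwell_plan, spectrum):
        a = run_simulation(water_phantom, single_dwell_plan, spectrum,
                           50_000, n_batches=5, seed=42)
        b = run_simulation(water_phantom, single_dwell_plan, spectrum,
                           50_000, n_batches=5, seed=42)
        np.testing.assert_array_equal(a.dose, b.dose)
        np.testing.assert_array_equal(a.batch_sum_squares,
                                      b.batch_sum_squares)

    def test_dose_linear_in_dwell_time(self, water_phantom, spectrum):
        plan1 = DwellPlan([[0.0, 0.0, 0.0]], [10.0])
        plan2 = plan1.scaled_times(2.0)
        a = run_simulation(water_phantom, plan1, spectrum, 50_000,
                           n_batches=5, seed=8)
        b = run_simulation(water_phantom, plan2, spectrum, 50_000,
                           n_batches=5, seed=8)
        np.testing.assert_allclose(b.dose, 2.0 * a.dose, rtol=1e-12)

    def test_dose_nonnegative_and_finite(self, primary_water_dose):
        assert np.all(np.isfinite(primary_water_dose.dose))
        assert np.all(primary_water_dose.dose >= 0.0)

    def test_unbound_water_exceeds_finite_phantom_near_interface(
            self, spectrum):
        """A dwell 10 mm below a water/air interface: the unbound phantom
        restores the missing backscatter, so its dose at the interface
        region exceeds the finite water phantom's (scatter deficit)."""
        mats = load_materials()
        shape = (61, 61, 61)
        idx = np.ones(shape, np.int16)  # air
        rho = np.full(shape, 0.0012)
        idx[:, :, :41] = 0              # water below z-index 41
        rho[:, :, :41] = 1.0
        finite = VoxelPhantom(
            idx, rho, ("water", "air"),
            {"water": mats["water"], "air": mats["air"]},
            (1.0, 1.0, 1.0), (-30.0, -30.0, -30.0), Scheme.HETEROGENEOUS)
        unbound = build_phantom(np.zeros(shape), (1.0,) * 3,
                                (-30.0, -30.0, -30.0),
                                scheme=Scheme.WATER_UNBOUND)
        plan = DwellPlan([[0.0, 0.0, 0.0]], [10.0])  # 10 mm below surface
        # last water layer before the interface, where the missing
        # backscatter is largest (~2% for this geometry)
        roi = (slice(25, 36), slice(25, 36), slice(40, 41))
        d_fin = run_simulation(finite, plan, spectrum, 300_000,
                               n_batches=5, seed=4).dose[roi].mean()
        d_unb = run_simulation(unbound, plan, spectrum, 300_000,
                               n_batches=5, seed=4).dose[roi].mean()
        assert d_unb > d_fin * 1.01

    def test_invalid_configuration_rejected(self, water_phantom,
                                            single_dwell_plan, spectrum):
        with pytest.raises(InvalidInputError):
            run_simulation(water_phantom, single_dwell_plan, spectrum,
                           1000, n_batches=1)
        with pytest.raises(InvalidInputError):
            run_simulation(water_phantom, single_dwell_plan, spectrum,
                           3, n_batches=5)


class TestTypeAUncertainty:
    def _grid(self, dose, sums, sumsq, nb):
        one = np.ones((1, 1, 1))
        return DoseGrid(dose * one, sums * one, sumsq * one, nb, 1000,
                        "D_w,w", np.ones(3), np.zeros(3), 0)

    def test_identical_batches_give_zero(self):
        # 5 batches each contributing exactly 2.0
        g = self._grid(10.0, 10.0, 5 * 4.0, 5)
        assert type_a_uncertainty(g, 10.0) == pytest.approx(0.0, abs=1e-9)

    def test_hand_computed_standard_error(self):
        vals = np.array([1.0, 2.0, 3.0, 2.0])
        g = self._grid(vals.sum(), vals.sum(), np.sum(vals ** 2), 4)
        s2 = np.var(vals, ddof=1)
        expect = np.sqrt(4 * s2) / vals.sum() * 100.0
        assert type_a_uncertainty(g, vals.sum()) == pytest.approx(expect)

    def test_uncertainty_shrinks_like_sqrt_n(self, water_phantom,
                                             single_dwell_plan, spectrum):
        """Quadrupling histories should halve the Type A uncertainty,
        within 30% of the ideal factor 2."""
        kw = dict(n_batches=10, per_decay=True)
        a = run_simulation(water_phantom, single_dwell_plan, spectrum,
                           100_000, seed=31, **kw)
        b = run_simulation(water_phantom, single_dwell_plan, spectrum,
                           400_000, seed=32, **kw)
        ref = a.dose[55 + 20, 55, 55]
        ua = type_a_uncertainty(a, ref, band=0.02)
        ub = type_a_uncertainty(b, ref, band=0.02)
        assert ua / ub == pytest.approx(2.0, rel=0.3)

    def test_empty_band_rejected(self):
        g = self._grid(1.0, 1.0, 0.25, 4)
        with pytest.raises(EmptySelectionError):
            type_a_uncertainty(g, 1e6)
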