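import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from brachykerma import (ADIPOSE_GLAND_MIX, CalibrationCurve, Material,
                         Scheme, build_material_table, build_phantom,
                         classify_hu, hu_to_density, lookup_muen,
                         mix_materials)
from brachykerma.errors import (InvalidInputError, InvalidMixtureError,
                                ValidationError)


class TestMixMaterials:
    def test_identity_mixture(self, materials):
        out = mix_materials([materials["adipose"]], [1.0])
        assert out.elemental_composition == \
            materials["adipose"].elemental_composition
        assert out.nominal_density == materials["adipose"].nominal_density

    def test_equal_mix_averages_fractions(self):
        a = Material("a", {"H": 0.10, "O": 0.90}, 1.0)
        b = Material("b", {"H": 0.12, "O": 0.88}, 1.0)
        out = mix_materials([a, b], [0.5, 0.5])
        assert out.elemental_composition["H"] == pytest.approx(0.11)

    def test_density_is_mass_weighted_harmonic_mean(self):
        a = Material("a", {"H": 1.0}, 0.5)
        b = Material("b", {"O": 1.0}, 1.0)
        out = mix_materials([a, b], [0.5, 0.5])
        # equal masses: total volume 0.5/0.5 + 0.5/1.0 per unit mass
        assert out.nominal_density == pytest.approx(1.0 / (1.0 + 0.5))

    def test_mixture_muen_obeys_bragg_additivity(self, materials):
        """Mass energy-absorption of the 50/50 adipose-gland mixture must
        equal the mass-weighted mean of the component coefficients at
        every grid energy (Bragg additivity oracle)."""
        mix = mix_materials([materials["adipose"], materials["gland"]],
                            [0.5, 0.5], name=ADIPOSE_GLAND_MIX)
        t_mix = build_material_table(mix)
        t_a = build_material_table(materials["adipose"])
        t_g = build_material_table(materials["gland"])
        np.testing.assert_allclose(
            t_mix.mu_en, 0.5 * t_a.mu_en + 0.5 * t_g.mu_en, rtol=1e-10)
        # spot-check through the interpolating lookup as well (log-log
        # interpolation is only approximately linear in the coefficients)
        for e in (50.0, 316.51, 1000.0):
            assert lookup_muen(t_mix, e) == pytest.approx(
                0.5 * lookup_muen(t_a, e) + 0.5 * lookup_muen(t_g, e),
                rel=2e-4)

    def test_bad_fractions_rejected(self, materials):
        with pytest.raises(InvalidMixtureError):
            mix_materials([materials["adipose"], materials["gland"]],
                          [0.6, 0.6])
        with pytest.raises(InvalidInputError):
            mix_materials([], [])

    @settings(derandomize=True, max_examples=30, deadline=None)
    @given(w=st.floats(0.01, 0.99))
    def test_mixture_fractions_sum_to_one(self, w):
        a = Material("a", {"H": 0.3, "C": 0.7}, 0.9)
        b = Material("b", {"C": 0.5, "O": 0.5}, 1.1)
        out = mix_materials([a, b], [w, 1.0 - w])
        assert sum(out.elemental_composition.values()) == \
            pytest.approx(1.0, abs=1e-9)


class TestCalibrationCurve:
    def test_density_at_anchor(self, curve):
        hu, rho, _ = curve.anchors[2]
        assert hu_to_density(hu, curve) == pytest.approx(rho)

    def test_linear_midpoint(self):
        c = CalibrationCurve(((-1000.0, 0.0012, "air"), (0.0, 1.0, "water")))
        assert hu_to_density(-500.0, c) == pytest.approx(0.5006)

    def test_clamped_outside_anchors(self, curve):
        assert hu_to_density(-5000.0, curve) == curve.anchors[0][1]
        assert hu_to_density(9000.0, curve) == curve.anchors[-1][1]

    @settings(derandomize=True, max_examples=30, deadline=None)
    @given(st.lists(st.floats(-1200, 2500), min_size=2, max_size=20))
    def test_density_monotone_when_anchors_monotone(self, curve, hus):
        hus = sorted(hus)
        rho = hu_to_density(np.array(hus), curve)
        assert np.all(np.diff(rho) >= -1e-12)

    def test_extreme_and_water_classes(self, curve):
        assert classify_hu(-1000.0, curve) == "air"
        assert classify_hu(0.0, curve) == "soft_tissue"

    def test_classification_matches_interval_scan_oracle(self, curve):
        """Vectorized classification must agree with a per-HU linear scan
        over the midpoint class intervals."""
        rng = np.random.default_rng(5)
        hus = rng.uniform(-1100, 2100, 500)
        # independent oracle: walk the anchor list, build boundaries, scan
        bounds, classes = [], [curve.anchors[0][2]]
        for (h0, _, m0), (h1, _, m1) in zip(curve.anchors,
                                            curve.anchors[1:]):
            if m1 != m0:
                bounds.append(0.5 * (h0 + h1))
                classes.append(m1)
        for hu in hus:
            expected = classes[0]
            for b, cls in zip(bounds, classes[1:]):
                if hu >= b:
                    expected = cls
            assert classify_hu(hu, curve) == expected

    def test_non_monotone_anchors_rejected(self):
        with pytest.raises(ValidationError):
            CalibrationCurve(((0.0, 1.0, "a"), (0.0, 1.1, "b")))


class TestBuildPhantom:
    def test_water_scheme_ignores_hu_content(self, curve):
        rng = np.random.default_rng(0)
        hu = rng.uniform(-1000, 1500, (6, 6, 6))
        ph = build_phantom(hu, (1.0,) * 3, (0.0,) * 3, curve=curve,
                           scheme=Scheme.WATER_UNBOUND)
        assert np.all(ph.density == 1.0)
        assert ph.material_names == ("water",)
        ph2 = build_phantom(np.zeros((6, 6, 6)), (1.0,) * 3, (0.0,) * 3,
                            curve=curve, scheme=Scheme.WATER_UNBOUND)
        np.testing.assert_array_equal(ph.density, ph2.density)
        np.testing.assert_array_equal(ph.material_index, ph2.material_index)

    def test_uniform_air_volume(self, curve):
        hu = np.full((4, 4, 4), -1000.0)
        ph = build_phantom(hu, (1.0,) * 3, (0.0,) * 3, curve=curve,
                           scheme=Scheme.HETEROGENEOUS)
        assert all(ph.material_names[i] == "air"
                   for i in np.unique(ph.material_index))

    def test_glandular_mask_gets_mixture_material(self, curve, materials):
        hu = np.full((5, 5, 5), -60.0)
        breast = np.zeros((5, 5, 5), bool)
        breast[1:4, 1:4, 1:4] = True
        gland = np.zeros((5, 5, 5), bool)
        gland[2, 2, 2] = True
        ph = build_phantom(hu, (1.0,) * 3, (0.0,) * 3, curve=curve,
                           scheme=Scheme.HETEROGENEOUS,
                           breast_mask=breast, glandular_mask=gland)
        # voxelwise oracle: every breast voxel adipose except the gland one
        mix = mix_materials([materials["adipose"], materials["gland"]],
                            [0.5, 0.5])
        name = np.array(ph.material_names)[ph.material_index]
        assert name[2, 2, 2] == ADIPOSE_GLAND_MIX
        assert np.all(name[breast & ~gland] == "adipose")
        got = ph.materials[ADIPOSE_GLAND_MIX]
        for el, frac in mix.elemental_composition.items():
            assert got.elemental_composition[el] == pytest.approx(frac)

    def test_mask_shape_mismatch_rejected(self, curve):
        with pytest.raises(InvalidInputError):
            build_phantom(np.zeros((4, 4, 4)), (1.0,) * 3, (0.0,) * 3,
                          curve=curve, breast_mask=np.zeros((3, 3, 3)))
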