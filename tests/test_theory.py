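"""Theory layer: closed-form values, quadrature equivalence, and parameter
recovery on synthetic curves."""

import math

import numpy as np
import pytest

from brushsim.builder import SyntheticCurveSpec, synth_force_curve
from brushsim.theory import (BrushPopulationTheory, adg_pressure,
                             adg_sphere_force, compare_fits,
                             fit_force_profile, multi_brush_force,
                             normalize_curve)


class TestPressure:
    def test_contact_separation_zero(self):
        pop = BrushPopulationTheory(L=10.0, s=1.0)
        assert adg_pressure(20.0, pop) == 0.0

    def test_beyond_contact_zero(self):
        pop = BrushPopulationTheory(L=10.0, s=1.0)
        assert adg_pressure(25.0, pop) == 0.0

    def test_direct_evaluation(self):
        # 2^{9/4} - 2^{-3/4} = 4.7568... - 0.5946... = 4.1622...
        pop = BrushPopulationTheory(L=10.0, s=1.0)
        expected = 2 ** 2.25 - 2 ** -0.75
        assert adg_pressure(10.0, pop) == pytest.approx(expected, rel=1e-12)
        assert expected == pytest.approx(4.162, abs=1e-3)

    def test_positive_inside_contact(self):
        pop = BrushPopulationTheory(L=10.0, s=1.0)
        h = np.linspace(0.5, 19.9, 200)
        assert np.all(adg_pressure(h, pop) > 0)

    def test_spacing_scaling(self):
        a = BrushPopulationTheory(L=10.0, s=1.0)
        b = BrushPopulationTheory(L=10.0, s=2.0)
        assert adg_pressure(5.0, a) == pytest.approx(8 * adg_pressure(5.0, b))

    def test_domain_error(self):
        pop = BrushPopulationTheory(L=10.0, s=1.0)
        with pytest.raises(ValueError):
            adg_pressure(0.0, pop)
        with pytest.raises(ValueError):
            adg_pressure(-1.0, pop)

    def test_invalid_population(self):
        with pytest.raises(ValueError):
            BrushPopulationTheory(L=-1.0)


class TestSphereForce:
    def test_zero_beyond_contact(self):
        pop = BrushPopulationTheory(L=10.0, s=1.0)
        assert adg_sphere_force(20.0, pop) == 0.0
        assert adg_sphere_force(50.0, pop) == 0.0

    def test_quadrature_matches_closed_form(self):
        pop = BrushPopulationTheory(L=10.0, s=1.1)
        h = np.linspace(1.0, 19.5, 40)
        closed = adg_sphere_force(h, pop, method="closed")
        quad = adg_sphere_force(h, pop, method="quad")
        np.testing.assert_allclose(quad, closed, rtol=1e-8)

    def test_brute_force_trapezoid(self):
        pop = BrushPopulationTheory(L=8.0, s=1.0)
        h0 = 3.0
        u = np.linspace(h0, 16.0, 1_000_001)
        brute = 2 * math.pi * np.trapezoid(adg_pressure(u, pop), u)
        assert adg_sphere_force(h0, pop) == pytest.approx(brute, rel=1e-6)

    def test_monotone_decreasing(self):
        pop = BrushPopulationTheory(L=10.0, s=1.0)
        h = np.linspace(0.5, 25.0, 300)
        f = adg_sphere_force(h, pop)
        assert np.all(np.diff(f) <= 1e-12)

    def test_soft_above_stiff_when_longer(self):
        soft = BrushPopulationTheory(L=10.0, s=1.0)
        stiff = BrushPopulationTheory(L=6.0, s=1.0)
        h = np.linspace(0.5, 11.9, 100)  # both compressed: h < 2 L_stiff
        assert np.all(adg_sphere_force(h, soft) > adg_sphere_force(h, stiff))


class TestMultiBrush:
    def test_single_equals_sphere_force(self):
        pop = BrushPopulationTheory(L=10.0, s=1.0)
        h = np.linspace(1.0, 25.0, 50)
        np.testing.assert_array_equal(multi_brush_force(h, [pop]),
                                      adg_sphere_force(h, pop))

    def test_duplicated_population_doubles(self):
        pop = BrushPopulationTheory(L=10.0, s=1.0)
        h = np.linspace(1.0, 25.0, 50)
        np.testing.assert_allclose(multi_brush_force(h, [pop, pop]),
                                   2 * adg_sphere_force(h, pop))

    def test_onsets_at_contact_separations(self):
        pops = [BrushPopulationTheory(L=3.0, s=1.0),
                BrushPopulationTheory(L=18.0, s=2.0),
                BrushPopulationTheory(L=25.0, s=3.0)]
        h = np.linspace(0.5, 60.0, 1200)
        f = multi_brush_force(h, pops)
        for L in (3.0, 18.0, 25.0):
            below = f[np.searchsorted(h, 2 * L - 0.3)]
            above = f[np.searchsorted(h, 2 * L + 0.3)]
            assert below > above

    def test_empty_list_rejected(self):
        with pytest.raises(ValueError):
            multi_brush_force(np.array([1.0]), [])


class TestFitting:
    def test_single_brush_recovery(self):
        spec = SyntheticCurveSpec(populations=[(20.0, 1.13 ** -2)],
                                  h_grid=np.linspace(2.5, 45.0, 120))
        df = synth_force_curve(spec)
        res = fit_force_profile(df, n_populations=1,
                                Gamma_fixed=[1.13 ** -2])
        assert res.L[0] == pytest.approx(20.0, rel=0.01)

    def test_free_amplitude_recovery(self):
        spec = SyntheticCurveSpec(populations=[(15.0, 0.5)],
                                  h_grid=np.linspace(2.0, 35.0, 100))
        df = synth_force_curve(spec)
        res = fit_force_profile(df, n_populations=1)
        assert res.free_amplitude
        assert res.L[0] == pytest.approx(15.0, rel=0.02)

    def test_three_brush_beats_single_on_three_population_truth(self):
        gammas = [0.73, 0.2, 0.083]
        spec = SyntheticCurveSpec(
            populations=[(3.0, gammas[0]), (12.0, gammas[1]),
                         (20.0, gammas[2])],
            h_grid=np.linspace(0.8, 45.0, 150))
        df = synth_force_curve(spec)
        fit1 = fit_force_profile(df, n_populations=1, Gamma_fixed=[0.3])
        fit3 = fit_force_profile(df, n_populations=3, Gamma_fixed=gammas)
        cmp_ = compare_fits(df, fit1, fit3)
        assert cmp_["rss_b"] < cmp_["rss_a"]
        assert cmp_["preferred"] == "b"

    def test_label_switching_broken(self):
        spec = SyntheticCurveSpec(populations=[(8.0, 0.5), (16.0, 0.2)],
                                  h_grid=np.linspace(1.0, 40.0, 120))
        res = fit_force_profile(synth_force_curve(spec), n_populations=2,
                                Gamma_fixed=[0.5, 0.2])
        assert res.L[0] >= res.L[1]

    def test_noisy_recovery_median_error(self):
        # 20 seeded noisy curves at 5% noise: median |L̂ - L| / L < 5%
        errors = []
        for seed in range(20):
            spec = SyntheticCurveSpec(populations=[(20.0, 0.78)],
                                      h_grid=np.linspace(2.5, 45.0, 80),
                                      noise_sd=0.05, seed=seed)
            df = synth_force_curve(spec)
            res = fit_force_profile(df, n_populations=1, Gamma_fixed=[0.78],
                                    seed=seed)
            errors.append(abs(res.L[0] - 20.0) / 20.0)
        assert np.median(errors) < 0.05

    def test_axis_rescaling_invariance(self):
        # fitting h in different units recovers the rescaled L
        spec = SyntheticCurveSpec(populations=[(20.0, 0.5)],
                                  h_grid=np.linspace(2.5, 45.0, 100))
        df = synth_force_curve(spec)
        res_rc = fit_force_profile(df, n_populations=1)
        df_nm = df.copy()
        df_nm["h"] = df["h"] * 0.646
        res_nm = fit_force_profile(df_nm, n_populations=1)
        assert res_nm.L[0] / 0.646 == pytest.approx(res_rc.L[0], rel=1e-3)

    def test_zero_curve_rejected(self):
        df = synth_force_curve(SyntheticCurveSpec(
            populations=[(2.0, 1.0)], h_grid=np.linspace(30.0, 40.0, 20)))
        with pytest.raises(ValueError, match="identically zero"):
            fit_force_profile(df, n_populations=1)

    def test_validity_mask_respected(self):
        spec = SyntheticCurveSpec(populations=[(20.0, 0.5)],
                                  h_grid=np.linspace(1.0, 45.0, 150))
        res = fit_force_profile(synth_force_curve(spec), n_populations=1,
                                Gamma_fixed=[0.5])
        h = spec.h_grid
        x = h / res.L[0]
        np.testing.assert_array_equal(res.mask, (x > 0.1) & (x < 0.9))


class TestNormalize:
    def test_maxima_become_one(self):
        df = normalize_curve((np.array([1.0, 5.0]), np.array([4.0, 2.0])))
        assert df["h"].max() == 1.0
        assert df["F_over_R"].max() == 1.0

    def test_idempotent(self):
        df = normalize_curve((np.array([1.0, 5.0]), np.array([4.0, 2.0])))
        df2 = normalize_curve(df)
        np.testing.assert_allclose(df2.values, df.values)

    def test_zero_max_rejected(self):
        with pytest.raises(ValueError):
            normalize_curve((np.array([1.0, 2.0]), np.array([0.0, 0.0])))
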