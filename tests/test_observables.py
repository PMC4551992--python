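import math

import numpy as np
import pandas as pd
import pytest

from brushsim.builder import build_system
from brushsim.energetics import ParticleSystem
from brushsim.gcmc import RunSchedule, run_chain
from brushsim.model import (InteractionTable, SimulationParameters,
                            cancer_architecture)
from brushsim.observables import (BrushHeight, DensityProfile, MeanderTrace,
                                  block_average, brush_height,
                                  density_profile, derjaguin_transform,
                                  force_profile, graft_trace,
                                  normalize_profile, solvent_penetration,
                                  tip_force)
from brushsim.theory import BrushPopulationTheory, adg_pressure, adg_sphere_force


class TestTipForce:
    def test_no_particle_in_range(self):
        s = ParticleSystem.solvent_only([[3.0, 3.0, 2.0]], (7.0, 7.0), 10.0)
        assert tip_force(s) == 0.0

    def test_contact_value(self):
        s = ParticleSystem.solvent_only([[3.0, 3.0, 10.0]], (7.0, 7.0), 10.0)
        assert tip_force(s, 25.0) == pytest.approx(25.0)

    def test_half_gap(self):
        s = ParticleSystem.solvent_only([[3.0, 3.0, 9.5]], (7.0, 7.0), 10.0)
        assert tip_force(s, 25.0) == pytest.approx(12.5)


def fake_run(h, forces, area=49.0, seed=0):
    """Minimal RunResult stand-in for profile aggregation tests."""
    from brushsim.gcmc import MoveStatistics, RunResult

    n = len(forces)
    return RunResult(
        samples=pd.DataFrame({"sweep": np.arange(n), "n_solvent": 100,
                              "energy": 0.0, "tip_force": forces}),
        hist=np.zeros((2, 10)), bin_width=1.0,
        graft_trace=np.zeros((n, 0, 2)),
        graft_index=np.zeros(0, dtype=int),
        graft_chain=np.zeros(0, dtype=int),
        final_system=ParticleSystem.empty((7.0, 7.0), h),
        stats=MoveStatistics(attempted={}, accepted={}),
        schedule=RunSchedule(seed=seed), h=h,
        box_xy=(math.sqrt(area), math.sqrt(area)), seed=seed,
        max_displacement_final=np.array([0.2]), widom_mean=float("nan"))


class TestForceProfile:
    def test_constant_streams_zero_se(self):
        runs = [fake_run(5.0, np.full(40, 7.0)), fake_run(10.0, np.full(40, 7.0))]
        prof = force_profile(runs)
        assert np.all(prof.force_se == 0.0)
        assert np.all(prof.force == 7.0)

    def test_single_point_rejected(self):
        with pytest.raises(ValueError):
            force_profile([fake_run(5.0, np.full(10, 1.0))])

    def test_single_sample_rejected(self):
        with pytest.raises(ValueError):
            force_profile([fake_run(5.0, np.array([1.0])),
                           fake_run(8.0, np.array([1.0]))])

    def test_tail_baseline_subtraction(self):
        runs = [fake_run(5.0, np.full(20, 10.0)), fake_run(15.0, np.full(20, 4.0))]
        prof = force_profile(runs)
        assert prof.net_pressure[-1] == pytest.approx(0.0)
        assert prof.net_pressure[0] == pytest.approx((10.0 - 4.0) / 49.0)

    def test_normalization_contract(self):
        h, f = normalize_profile(np.array([2.0, 4.0]), np.array([3.0, 1.0]))
        assert h.max() == 1.0 and f.max() == 1.0

    def test_normalize_rejects_zero_max(self):
        with pytest.raises(ValueError):
            normalize_profile(np.array([1.0, 2.0]), np.zeros(2))


class TestDerjaguin:
    def test_zero_pressure(self):
        h = np.linspace(1, 10, 20)
        np.testing.assert_allclose(derjaguin_transform((h, np.zeros(20))), 0.0)

    def test_rectangle_integral(self):
        # constant pressure c on [h, hmax]: F/R = 2 pi c (hmax - h)
        h = np.linspace(2.0, 12.0, 101)
        c = 3.0
        fr = derjaguin_transform((h, np.full(101, c)))
        np.testing.assert_allclose(fr, 2 * math.pi * c * (12.0 - h), rtol=1e-12)

    def test_matches_adg_sphere_force(self):
        # cross-module oracle: integrating the AdG pressure numerically
        # must match the closed-form sphere force to < 1%
        pop = BrushPopulationTheory(L=10.0, s=1.0)
        h = np.linspace(2.0, 20.0, 200)
        pressure = adg_pressure(h, pop)
        fr = derjaguin_transform((h, pressure))
        expected = adg_sphere_force(h, pop)
        scale = expected.max()
        np.testing.assert_allclose(fr, expected, atol=0.01 * scale)

    def test_truncation_warning(self):
        runs = [fake_run(5.0, np.full(20, 10.0)),
                fake_run(8.0, np.full(20, 8.0))]
        prof = force_profile(runs, baseline="none")
        with pytest.warns(UserWarning, match="zero-force tail"):
            derjaguin_transform(prof)
        assert "truncation_bound" in prof.meta


@pytest.fixture(scope="module")
def small_cancer_run():
    p = SimulationParameters(architecture=cancer_architecture("soft"),
                             h=10.0, seed=2)
    system = build_system(p)
    return run_chain(system, RunSchedule(50, 200, 4, seed=2), p), p, system


class TestDensityProfile:
    def test_uniform_ideal_gas_flat(self):
        p = SimulationParameters(box_xy=(5.0, 5.0), h=6.0, activity=2.0,
                                 target_density=2.0, bin_width=1.0)
        p.interactions = InteractionTable(a=np.zeros((2, 2)),
                                          a_wall_surface=0.0, a_wall_tip=0.0)
        rng = np.random.default_rng(0)
        sys0 = ParticleSystem.solvent_only(rng.random((300, 3))
                                           * np.array([5, 5, 6.0]),
                                           (5.0, 5.0), 6.0)
        res = run_chain(sys0, RunSchedule(100, 800, 2, seed=1), p)
        dp = density_profile(res)
        np.testing.assert_allclose(dp.rho_solvent, 2.0, rtol=0.08)

    def test_brush_integral_matches_bead_count(self, small_cancer_run):
        res, p, system = small_cancer_run
        dp = density_profile(res)
        total = dp.rho_brush.sum() * dp.bin_width * dp.area
        assert total == pytest.approx(system.n_brush, rel=1e-3)

    def test_solvent_integral_matches_mean_count(self, small_cancer_run):
        res, _p, _system = small_cancer_run
        dp = density_profile(res)
        total = dp.rho_solvent.sum() * dp.bin_width * dp.area
        assert total == pytest.approx(res.samples.n_solvent.mean(), rel=1e-6)

    def test_too_few_samples_rejected(self, small_cancer_run):
        res, _p, _system = small_cancer_run
        trimmed = res
        import dataclasses
        trimmed = dataclasses.replace(res, samples=res.samples.iloc[:5])
        with pytest.raises(ValueError, match=">= 10 samples"):
            density_profile(trimmed)


class TestBrushHeight:
    def profile(self, rho_brush, bw=0.5):
        n = len(rho_brush)
        return DensityProfile(
            z=(np.arange(n) + 0.5) * bw, rho_solvent=np.zeros(n),
            rho_brush=np.asarray(rho_brush, dtype=float),
            rho_per_population=np.asarray([rho_brush], dtype=float),
            bin_width=bw, h=n * bw, area=49.0, n_samples=10)

    def test_delta_distribution(self):
        rho = np.zeros(20)
        rho[10] = 5.0  # all beads in bin centred at z = 5.25 (bw 0.5)
        L = brush_height(self.profile(rho))
        assert L.L_cumulative == pytest.approx(5.25, abs=0.5)
        assert L.L_moment == pytest.approx(2 * 5.25, abs=1e-9)

    def test_step_profile(self):
        # uniform on [0, 5]: 98% estimator = 4.9, first moment 2<z> = 5
        rho = np.concatenate([np.ones(10), np.zeros(10)])
        L = brush_height(self.profile(rho))
        assert L.L_cumulative == pytest.approx(4.9, abs=1e-9)
        assert L.L_moment == pytest.approx(5.0, abs=1e-9)

    def test_empty_profile_rejected(self):
        with pytest.raises(ValueError, match="empty brush"):
            brush_height(self.profile(np.zeros(10)))


class TestMeander:
    def test_trace_length_and_unwrapped(self, small_cancer_run):
        res, _p, _system = small_cancer_run
        cid = int(res.graft_chain[0])
        tr = graft_trace(res, cid)
        assert tr.n_samples == res.schedule.n_samples
        assert np.isfinite(tr.xy).all()

    def test_msd_zero_for_constant_trace(self):
        tr = MeanderTrace(xy=np.ones((50, 2)), sample_interval=100,
                          chain_id=0)
        assert np.all(tr.msd() == 0.0)

    def test_unknown_chain(self, small_cancer_run):
        res, _p, _system = small_cancer_run
        with pytest.raises(KeyError):
            graft_trace(res, 10_000)


class TestSolventPenetration:
    def flat_profile(self, rho=3.0, h=10.0, bw=0.5, area=49.0):
        n = int(h / bw)
        return DensityProfile(
            z=(np.arange(n) + 0.5) * bw, rho_solvent=np.full(n, rho),
            rho_brush=np.zeros(n), rho_per_population=np.zeros((1, n)),
            bin_width=bw, h=h, area=area, n_samples=10)

    def test_uniform_window_arithmetic(self):
        dp = self.flat_profile(rho=3.0, area=49.0)
        # 3 * 3 rc * 49 rc^2 = 441
        assert solvent_penetration(dp, (2.0, 5.0)) == pytest.approx(441.0)

    def test_zero_solvent(self):
        dp = self.flat_profile(rho=0.0)
        assert solvent_penetration(dp, (2.0, 5.0)) == 0.0

    def test_partial_bins(self):
        dp = self.flat_profile(rho=2.0, bw=1.0)
        assert solvent_penetration(dp, (0.25, 0.75)) == pytest.approx(
            2.0 * 0.5 * 49.0)

    def test_invalid_windows(self):
        dp = self.flat_profile()
        with pytest.raises(ValueError):
            solvent_penetration(dp, (5.0, 5.0))
        with pytest.raises(ValueError):
            solvent_penetration(dp, (8.0, 12.0))


class TestBlockAverage:
    def test_mean_exact(self):
        x = np.arange(100, dtype=float)
        m, se = block_average(x)
        assert m == pytest.approx(49.5)
        assert se > 0

    def test_requires_two_samples(self):
        with pytest.raises(ValueError):
            block_average(np.array([1.0]))
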