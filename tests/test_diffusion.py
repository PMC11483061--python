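"""MSD/rotational estimators, finite-size corrections, Stokes-Einstein."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from crowdtransport import units
from crowdtransport.curves import CorrelationCurve
from crowdtransport.diffusion import (MSDCurve, RotationalDiffusion,
                                      TranslationalDiffusion, compute_msd,
                                      fit_diffusion, fit_rotational,
                                      hydrodynamic_radii,
                                      pbc_correct_rotational,
                                      pbc_correct_translational,
                                      rescale_by_viscosity_ratio, rot_acf,
                                      stokes_einstein_ratio, tau_from_tensor,
                                      xi_factor)
from crowdtransport.trajectory import Trajectory
from crowdtransport import synthetic


def _traj_from_paths(paths, L=1e4, dt=0.1):
    coords = np.stack(paths, axis=1)
    n, m = coords.shape[:2]
    return Trajectory(np.arange(n) * dt, coords, np.full(n, L),
                      np.arange(m), np.arange(m), ["heavy"] * m,
                      np.ones(m), wrapped=False)


class TestMSD:
    def test_stationary_molecule_msd_zero(self):
        traj = _traj_from_paths([np.tile([3.0, 4.0, 5.0], (50, 1))])
        msd = compute_msd(traj)
        # FFT evaluation leaves cancellation noise ~1e-13 of |r|^2
        np.testing.assert_allclose(msd.msd, 0.0, atol=1e-9)

    def test_ballistic_path_quadratic(self):
        t = np.arange(64) * 0.1
        v = 7.0
        path = np.column_stack([v * t, np.zeros_like(t), np.zeros_like(t)])
        msd = compute_msd(_traj_from_paths([path]))
        np.testing.assert_allclose(msd.msd, (v * msd.lags) ** 2, atol=1e-8)

    def test_wrapped_input_rejected(self, brownian_sample):
        with pytest.raises(ValueError, match="unwrap"):
            compute_msd(brownian_sample.wrapped)

    def test_empty_selection_rejected(self, brownian_sample):
        with pytest.raises(ValueError, match="no molecules"):
            compute_msd(brownian_sample.unwrapped, selection=[])

    def test_brownian_recovery_within_3se(self, brownian_sample):
        res = TranslationalDiffusion(brownian_sample.unwrapped).fit()
        assert abs(res.D_pbc - 100.0) < 3 * res.se


class TestFitDiffusion:
    def _curve(self, msd):
        lags = np.linspace(0, 12, 121)
        return MSDCurve(lags, msd(lags), np.ones_like(lags))

    def test_exact_linear_slope(self):
        d = fit_diffusion(self._curve(lambda t: 6 * 50.0 * t))
        assert d == pytest.approx(50.0)

    def test_intercept_does_not_bias_slope(self):
        d = fit_diffusion(self._curve(lambda t: 6 * 50.0 * t + 30.0))
        assert d == pytest.approx(50.0)

    def test_window_outside_grid_rejected(self):
        with pytest.raises(ValueError):
            fit_diffusion(self._curve(lambda t: t), window=(50.0, 60.0))


class TestFiniteSizeCorrections:
    def test_xi_point_particle_constant(self):
        assert xi_factor(0.0, 100.0) == pytest.approx(2.837297)

    def test_xi_worked_value(self):
        assert xi_factor(20.0, 80.0) == pytest.approx(2.575498, abs=1e-6)

    def test_xi_root(self):
        rp = 80.0 * math.sqrt(3 * 2.837297 / (4 * math.pi))
        assert xi_factor(rp, 80.0) == pytest.approx(0.0, abs=1e-12)

    def test_translational_correction_value(self):
        # independent SI arithmetic: kB T xi/(6 pi eta L) in m^2/s -> A^2/ns
        expected = 10.0 + (1.380649e-23 * 298 * 2.837297
                           / (6 * math.pi * 0.347e-3 * 100e-10)) * 1e11
        got = pbc_correct_translational(10.0, 0.347, 100.0, 0.0, 298.0)
        assert got == pytest.approx(expected, rel=1e-12)
        assert got == pytest.approx(27.85, abs=0.01)

    def test_zero_xi_is_identity(self):
        L = 80.0
        rp = L * math.sqrt(3 * 2.837297 / (4 * math.pi))
        got = pbc_correct_translational(12.0, 0.347, L, rp, 298.0)
        assert got == pytest.approx(12.0, abs=1e-9)

    def test_rotational_correction_value(self):
        expected = (1.380649e-23 * 298 / (6 * 0.334e-3 * (50e-10) ** 3)) * 1e-9
        got = pbc_correct_rotational(0.0, 0.334, 50.0, 298.0)
        assert got == pytest.approx(expected, rel=1e-12)
        assert got == pytest.approx(0.0164, abs=2e-4)

    def test_corrections_vanish_for_huge_box(self):
        # translational correction decays as 1/L, rotational as 1/L^3:
        # 1e-6 relative needs a correspondingly larger box for translation
        assert pbc_correct_translational(10.0, 0.347, 1e10, 0.0) \
            == pytest.approx(10.0, rel=1e-6)
        assert pbc_correct_rotational(0.05, 0.347, 1e6) \
            == pytest.approx(0.05, rel=1e-6)

    def test_rotational_correction_decreases_with_eta(self):
        lo = pbc_correct_rotational(0.0, 0.3, 60.0)
        hi = pbc_correct_rotational(0.0, 0.6, 60.0)
        assert hi < lo


class TestViscosityRescaling:
    def test_water_diffusion_worked_example(self):
        assert rescale_by_viscosity_ratio(622.5, 0.334, 0.890) \
            == pytest.approx(233.6, abs=0.05)

    def test_equal_viscosities_identity(self):
        assert rescale_by_viscosity_ratio(42.0, 0.5, 0.5) == 42.0

    def test_zero_maps_to_zero(self):
        assert rescale_by_viscosity_ratio(0.0, 0.334, 0.890) == 0.0

    @settings(deadline=None, max_examples=20, derandomize=True)
    @given(st.floats(1e-3, 1e3), st.floats(1e-3, 10), st.floats(1e-3, 10))
    def test_rescaling_roundtrip_is_identity(self, d, em, ee):
        once = rescale_by_viscosity_ratio(d, em, ee)
        back = rescale_by_viscosity_ratio(once, ee, em)
        assert back == pytest.approx(d, rel=1e-12)


class TestRotACF:
    def test_non_rotating_body_has_unit_acf(self):
        rng = np.random.default_rng(0)
        sites = rng.normal(size=(5, 3)) * 8.0
        coords = np.tile(sites, (40, 1, 1))
        traj = Trajectory(np.arange(40) * 0.1, coords, np.full(40, 100.0),
                          np.zeros(5, int), np.arange(5), ["calpha"] * 5,
                          np.ones(5), wrapped=False)
        acf = rot_acf(traj, n_vectors=20, window=2.0, seed=1)
        np.testing.assert_allclose(acf.values, 1.0, atol=1e-9)

    def test_collinear_sites_rejected(self):
        sites = np.outer(np.arange(4.0), [1.0, 0, 0])
        coords = np.tile(sites, (10, 1, 1))
        traj = Trajectory(np.arange(10) * 0.1, coords, np.full(10, 100.0),
                          np.zeros(4, int), np.arange(4), ["calpha"] * 4,
                          np.ones(4), wrapped=False)
        with pytest.raises(ValueError, match="collinear"):
            rot_acf(traj, n_vectors=8, window=0.5, seed=0)

    def test_vector_count_changes_variance_not_mean(self, rotational_replicas):
        traj = rotational_replicas[0].trajectory
        few = rot_acf(traj, n_vectors=4, window=5.0, seed=5)
        many = rot_acf(traj, n_vectors=256, window=5.0, seed=5)
        # same underlying expectation: curves agree within the small-n noise
        assert np.abs(few.values - many.values).max() < 0.2
        late = slice(int(2.0 / 0.02), None)
        assert few.values[late].std() >= many.values[late].std() * 0.5


class TestFitRotational:
    def _acf(self, fn, tmax=30.0, dt=0.05):
        t = np.arange(0, tmax, dt)
        return CorrelationCurve(t, fn(t))

    def test_single_exponential_reduction(self):
        fit = fit_rotational(self._acf(lambda t: np.exp(-t / 5.0)),
                             window=(0, 20))
        assert fit.tau == pytest.approx(5.0, rel=1e-6)
        assert fit.Dr == pytest.approx(1.0 / 30.0, rel=1e-6)

    def test_double_exponential_overall_time(self):
        fit = fit_rotational(
            self._acf(lambda t: 0.4 * np.exp(-t) + 0.6 * np.exp(-t / 10.0)),
            window=(0, 20))
        # tau = (0.4/1 + 0.6/10)^-1
        assert fit.tau == pytest.approx(1.0 / 0.46, rel=1e-4)
        assert fit.tau1 < fit.tau2 and 0 <= fit.w <= 1

    def test_replica_recovery_within_3se(self, rotational_replicas):
        drs = []
        for rep in rotational_replicas:
            res = RotationalDiffusion(rep.trajectory, n_vectors=200,
                                      seed=11).fit((0.0, 20.0))
            drs.append(res.Dr_pbc)
        drs = np.array(drs)
        se = drs.std(ddof=1) / np.sqrt(drs.size)
        assert abs(drs.mean() - 0.05) < 3 * se


class TestTensorRelaxation:
    def test_isotropic_limit_matches_inverse_rate(self):
        assert tau_from_tensor(0.05, 0.05, 0.05) \
            == pytest.approx(1.0 / (6 * 0.05))

    @pytest.mark.parametrize("d", [0.01, 0.3, 7.0])
    def test_isotropic_symmetry_any_rate(self, d):
        assert tau_from_tensor(d, d, d) == pytest.approx(1.0 / (6 * d))

    def test_anisotropic_value_against_independent_sum(self):
        d1, d2, d3 = 0.02, 0.05, 0.08
        # independent evaluation built from elementary operations
        dbar = np.mean([d1, d2, d3])
        terms = [1.0 / (dbar + di) for di in (d1, d2, d3)]
        terms.append((d1 + d2 + d3)
                     / (d1 * d2 + d2 * d3 + d3 * d1))
        expected = sum(terms) / 15.0
        assert tau_from_tensor(d1, d2, d3) == pytest.approx(expected,
                                                            rel=1e-14)

    def test_nonpositive_eigenvalue_rejected(self):
        with pytest.raises(ValueError):
            tau_from_tensor(0.0, 0.1, 0.1)


class TestStokesEinstein:
    def test_radius_roundtrip(self):
        d_t = units.d_t_from_radius(20.0, 0.334, 298.0)
        d_r = units.d_r_from_radius(20.0, 0.334, 298.0)
        rh = hydrodynamic_radii(d_t, d_r, 0.334, 298.0)
        assert rh.Rh_translational == pytest.approx(20.0, rel=1e-12)
        assert rh.Rh_rotational == pytest.approx(20.0, rel=1e-12)

    def test_sphere_obeys_both_laws_consistently(self):
        d_t = units.d_t_from_radius(15.0, 0.89, 298.0)
        d_r = units.d_r_from_radius(15.0, 0.89, 298.0)
        rh = hydrodynamic_radii(d_t, d_r, 0.89, 298.0)
        assert rh.Rh_translational == pytest.approx(rh.Rh_rotational,
                                                    rel=1e-12)

    def test_fixture_pair_from_one_radius_agrees(self):
        # Brownian and tumbling fixtures built from the same sphere
        eta, rh_true = 0.334, 20.0
        d_t = units.d_t_from_radius(rh_true, eta, 298.0)
        d_r = units.d_r_from_radius(rh_true, eta, 298.0)
        b = synthetic.gen_brownian(n_particles=100, D_true=d_t, L=200.0,
                                   dt=0.01, n_steps=8000, seed=21)
        r = synthetic.gen_rotational(Dr_true=d_r, dt=0.02, n_steps=10_000,
                                     seed=22)
        d_t_est = TranslationalDiffusion(b.unwrapped).fit().D_pbc
        d_r_est = RotationalDiffusion(r.trajectory, n_vectors=200,
                                      seed=23).fit((0, 15.0)).Dr_pbc
        rh = hydrodynamic_radii(d_t_est, d_r_est, eta, 298.0)
        assert rh.Rh_translational == pytest.approx(rh_true, rel=0.05)
        assert rh.Rh_rotational == pytest.approx(rh_true, rel=0.05)

    def test_deviation_unity_when_se_holds(self):
        rel_d, rel_f, dev = stokes_einstein_ratio(5.0, 10.0, 2.0, 1.0)
        assert dev == pytest.approx(1.0)

    def test_dilute_limit_all_unity(self):
        assert stokes_einstein_ratio(3.0, 3.0, 0.9, 0.9) \
            == pytest.approx((1.0, 1.0, 1.0))

    def test_cluster_slowdown_matches_construction(self):
        # generator construction: deviation = (1+ς φ)^(-1/3) for translation
        table, gt = synthetic.gen_concentration_series(noise_sd=0.0, seed=0)
        row = table.iloc[30]
        _, _, dev = stokes_einstein_ratio(row.D_t, 1.0, row.eta_r, 1.0)
        expected = (1.0 + gt.params["cluster_factor"] * row.phi) ** (-1 / 3)
        assert dev == pytest.approx(expected, rel=1e-9)


class TestTransportEstimateFlow:
    def test_corrected_value_exceeds_raw(self, brownian_sample):
        res = TranslationalDiffusion(brownian_sample.unwrapped).fit()
        est = res.correct(eta=0.347, Rp=0.0)
        assert est.pbc_corrected > est.raw
        assert est.rescaled == pytest.approx(
            est.pbc_corrected * 0.334 / 0.890)
        assert est.inputs["L"] == pytest.approx(200.0)
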