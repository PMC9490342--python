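"""Fractional-particle grand-canonical sampling and chemical-potential
bookkeeping."""

import warnings

import numpy as np
import pytest

import sorbmech as sm
from sorbmech import constants
from sorbmech.gce import GCEState, ideal_gas_log_term, step_lambda

from conftest import make_gas


class TestFractionalPotential:
    def test_full_coupling_recovers_plain_lj(self):
        r = np.array([1.0, 1.3, 2.0])
        e, _ = sm.fractional_potential(1.0, r)
        plain = np.sum(4.0 * ((1 / r) ** 12 - (1 / r) ** 6))
        assert e == pytest.approx(plain, rel=1e-12)

    def test_decoupled_is_zero_and_finite(self):
        e, dudl = sm.fractional_potential(0.0, np.array([0.0, 0.5, 1.0]))
        assert e == 0.0
        assert np.isfinite(dudl)

    @pytest.mark.parametrize("lam", [0.15, 0.5, 0.85])
    def test_dudl_matches_finite_difference(self, lam):
        r = np.array([0.4, 0.9, 1.2, 2.0])
        d = 1e-6
        _, dudl = sm.fractional_potential(lam, r)
        ep, _ = sm.fractional_potential(lam + d, r)
        em, _ = sm.fractional_potential(lam - d, r)
        assert dudl == pytest.approx((ep - em) / (2 * d), rel=1e-6, abs=1e-8)

    def test_out_of_range_lambda_rejected(self):
        with pytest.raises(ValueError):
            sm.fractional_potential(1.2, np.array([1.0]))


class TestStepLambda:
    def test_constant_force_kinematics(self):
        """With dU/dl = 0 and mu = 5, W = 5 from rest:
        lambda(t) = (mu/2W) t^2 = 0.5 at t = 1."""
        state = GCEState(lam=0.0, w_mass=5.0, mu_ex_target=5.0)
        dt = 1e-3
        for _ in range(1000):
            state, event = step_lambda(state, 0.0, dt)
            assert event is None
        assert state.lam == pytest.approx(0.5, rel=2e-3)

    def test_zero_force_lambda_constant(self):
        state = GCEState(lam=0.3, w_mass=1.0, mu_ex_target=0.0)
        for _ in range(100):
            state, _ = step_lambda(state, 0.0, 0.01)
        assert state.lam == pytest.approx(0.3)

    def test_event_counters(self):
        state = GCEState(lam=0.95, lam_velocity=10.0, w_mass=1.0)
        state, event = step_lambda(state, 0.0, 0.01)
        assert event == "insertion"
        assert state.insertions == 1
        state = GCEState(lam=0.05, lam_velocity=-10.0, w_mass=1.0)
        state, event = step_lambda(state, 0.0, 0.01)
        assert event == "deletion"
        assert state.deletions == 1

    def test_invalid_mass_rejected(self):
        with pytest.raises(ValueError):
            GCEState(w_mass=0.0)


class TestWidom:
    def test_ideal_gas_exactly_zero(self, lj_gas):
        cfg = lj_gas(40, 8.0, seed=1)
        ff = sm.ForceField(epsilon={"backbone": 0, "cys": 0, "solvent": 0.0})
        mu, se = sm.widom_mu_ex(cfg, ff, 1.0, 500, seed=2)
        assert mu == 0.0

    def test_dilute_lj_matches_virial_expansion(self, lj_gas):
        """mu_ex of a dilute LJ gas equals 2 B2 rho kT, with B2 from
        numerical quadrature of the truncated potential."""
        from scipy.integrate import quad

        ff = sm.ForceField()
        T, L, n = 1.5, 12.0, 40
        cfg = lj_gas(n, L, seed=2)
        sm.push_off(cfg, ff, 60)
        st = sm.IntegratorSettings(dt=0.004, t_target=T, thermostat=True,
                                   seed=2)
        frames = sm.md.sample_frames(cfg, ff, st, 10, 100, n_equil=1000)
        mu, se = sm.widom_mu_ex(frames, ff, T, 20000, seed=6)

        def u(r):
            if r >= ff.r_cut:
                return 0.0
            x = (1.0 / r) ** 6
            return 4.0 * (x * x - x)

        b2 = -0.5 * quad(
            lambda r: (np.exp(-u(r) / T) - 1) * 4 * np.pi * r**2,
            1e-2, 6.0, limit=200,
        )[0]
        expect = 2 * b2 * (n / L**3) * T
        assert mu == pytest.approx(expect, abs=max(3 * se, 0.02))

    def test_error_shrinks_with_sample_size(self, lj_gas):
        cfg = lj_gas(60, 6.0, seed=3)
        ff = sm.ForceField()
        _, se1 = sm.widom_mu_ex(cfg, ff, 1.5, 4000, seed=4)
        _, se2 = sm.widom_mu_ex(cfg, ff, 1.5, 16000, seed=4)
        assert se2 == pytest.approx(se1 / 2, rel=0.35)

    def test_all_overlaps_warns_infinite(self, lattice):
        cfg = lattice(3, 0.02)  # minuscule box, everything overlaps
        ff = sm.ForceField(r_cut=0.02, r_list=0.029)
        with pytest.warns(UserWarning, match="overlap"):
            mu, se = sm.widom_mu_ex(cfg, ff, 0.05, 64, seed=5)
        assert mu == np.inf


class TestRunGCE:
    def test_same_seed_identical_trace(self, lj_gas):
        ff = sm.ForceField(epsilon={"backbone": 0, "cys": 0, "solvent": 0.0})
        st = sm.IntegratorSettings(dt=0.01, t_target=1.0, thermostat=True,
                                   seed=1)
        kw = dict(rho_ref=40 / 8.0**3, w_mass=0.2, lam_gamma=0.5)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            r1 = sm.run_gce(lj_gas(35, 8.0, seed=2), ff, st, 0.0, 2000,
                            seed=9, **kw)
            r2 = sm.run_gce(lj_gas(35, 8.0, seed=2), ff, st, 0.0, 2000,
                            seed=9, **kw)
        assert np.array_equal(r1.n_eff_trace, r2.n_eff_trace)
        assert r1.events == r2.events

    def test_particle_count_changes_one_per_event(self, lj_gas):
        ff = sm.ForceField(epsilon={"backbone": 0, "cys": 0, "solvent": 0.0})
        st = sm.IntegratorSettings(dt=0.01, t_target=1.0, thermostat=True,
                                   seed=3)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = sm.run_gce(lj_gas(30, 8.0, seed=3), ff, st, 0.0, 4000,
                             seed=4, rho_ref=40 / 8.0**3, w_mass=0.2,
                             lam_gamma=0.5)
        dn = np.diff(res.n_trace)
        assert set(np.unique(dn)).issubset({-1, 0, 1})
        assert res.state.insertions - res.state.deletions == \
            res.n_trace[-1] - res.n_trace[0]

    def test_lambda_stays_in_unit_interval(self, lj_gas):
        ff = sm.ForceField()
        st = sm.IntegratorSettings(dt=0.004, t_target=1.5, thermostat=True,
                                   seed=5)
        cfg = lj_gas(50, 8.0, seed=5)
        sm.push_off(cfg, ff, 60)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = sm.run_gce(cfg, ff, st, -0.5, 3000, seed=6, w_mass=1.0)
        assert np.all(res.lam_trace >= 0.0)
        assert np.all(res.lam_trace <= 1.0)

    def test_prescan_density_tracks_reference(self, lj_gas):
        """The exploratory pre-scan of a non-interacting solvent at
        mu_ex = 0 suggests a density near the bookkeeping reference."""
        from sorbmech.gce import prescan_density

        ff = sm.ForceField(epsilon={"backbone": 0, "cys": 0, "solvent": 0.0})
        st = sm.IntegratorSettings(dt=0.01, t_target=1.0, thermostat=True,
                                   seed=2)
        rho = prescan_density(
            lj_gas(60, 8.0, seed=2), ff, st, 0.0, n_steps=20_000, seed=2,
            rho_ref=80 / 8.0**3, w_mass=0.2, lam_gamma=0.5,
        )
        assert rho == pytest.approx(80 / 8.0**3, rel=0.15)

    def test_clamped_lambda_reduces_to_nvt(self, lj_gas):
        """With lambda clamped at 1 the fractional particle is an
        ordinary particle: particle count never changes."""
        ff = sm.ForceField()
        st = sm.IntegratorSettings(dt=0.004, t_target=1.5, thermostat=True,
                                   seed=7)
        cfg = lj_gas(40, 8.0, seed=7)
        sm.push_off(cfg, ff, 60)
        res = sm.run_gce(cfg, ff, st, 0.0, 1000, seed=8, clamp_lambda=1.0)
        assert res.state.insertions == 0
        assert res.state.deletions == 0
        assert np.all(res.n_trace == res.n_trace[0])
        assert np.all(res.lam_trace == 1.0)


class TestChemicalPotentialBookkeeping:
    def test_pressure_expansion_identity_at_equal_pressure(self):
        assert sm.mu_pressure_expand(-3.0, 0.02, 5000.0, 5000.0, 300.0) \
            == pytest.approx(-3.0)

    def test_pressure_expansion_log_term_is_rt(self):
        """v = 0 and P = P'/e: the shift is exactly +RT."""
        mu = sm.mu_pressure_expand(0.0, 0.0, 1000.0, 1000.0 / np.e, 300.0)
        assert mu == pytest.approx(constants.R_GAS_KJ * 300.0, rel=1e-9)
        assert mu == pytest.approx(2.494, abs=2e-3)

    def test_pressure_expansion_atmospheric_to_saturation(self):
        """Expansion from 101.3 kPa down to the 3.55 kPa saturation
        pressure: +8.358 (log) - 0.0012 (volume) kJ/mol."""
        mu = sm.mu_pressure_expand(0.0, 0.0203, 101300.0, 3550.0, 300.0)
        assert mu == pytest.approx(8.357, abs=5e-3)

    def test_bad_pressures_rejected(self):
        with pytest.raises(ValueError):
            sm.mu_pressure_expand(0.0, 0.0, -1.0, 2.0, 300.0)

    def test_vapour_density_at_saturation(self):
        gas = sm.rh_to_gas_state(100.0, 300.0)
        assert gas.number_density == pytest.approx(
            3550.0 / (constants.KB * 300.0), rel=1e-12
        )
        assert gas.number_density == pytest.approx(8.571e23, rel=1e-3)

    def test_partial_pressure_proportional_to_rh(self):
        assert sm.rh_to_gas_state(50.0).p_vapour == pytest.approx(1775.0)
        with pytest.raises(ValueError):
            sm.rh_to_gas_state(0.0)
        with pytest.raises(ValueError):
            sm.rh_to_gas_state(120.0)

    def test_phase_equilibrium_log_term(self):
        """Saturated keratin (C = 17.19 g/100 g at density 1.0853 g/cm3)
        against saturated vapour at 300 K: 22.18 kJ/mol."""
        gas = sm.rh_to_gas_state(100.0, 300.0)
        term = ideal_gas_log_term(17.19, 1.0853, gas)
        assert term == pytest.approx(22.18, abs=0.01)
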