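"""Mechanical observables: modulus, yield, Poisson, voids, failure."""

import numpy as np
import pytest

import sorbmech as sm
from sorbmech.mechanics import StressStrainCurve, VoidTrace
from sorbmech.synthetic import SynthCurveSpec, plant_cavity, synth_stress_strain

from conftest import make_gas, make_lattice


GRID = np.round(np.linspace(0.0, 0.15, 301), 12)
FIXTURE = SynthCurveSpec(elastic_modulus=4.65, hardening_modulus=0.5,
                         hardening_intercept=0.100, noise_sd=0.0)


class TestYoungsModulus:
    def test_noiseless_line_exact(self):
        eps = np.linspace(0, 0.05, 50)
        curve = StressStrainCurve(strain=eps, stress=2.10 * eps)
        slope, err, _ = sm.youngs_modulus(curve)
        assert slope == pytest.approx(2.10, rel=1e-12)
        assert err == pytest.approx(0.0, abs=1e-9)

    def test_recovery_under_noise(self):
        spec = SynthCurveSpec(4.65, 0.5, 0.100, noise_sd=0.002, seed=3)
        curve = synth_stress_strain(spec, GRID)
        slope, err, _ = sm.youngs_modulus(curve)
        assert abs(slope - 4.65) < 2 * err + 0.05

    def test_points_above_cap_provably_unused(self):
        curve = synth_stress_strain(FIXTURE, GRID)
        full, _, _ = sm.youngs_modulus(curve)
        below = curve.strain < 0.02
        trimmed = StressStrainCurve(strain=curve.strain[below],
                                    stress=curve.stress[below])
        trim, _, _ = sm.youngs_modulus(trimmed)
        assert trim == full

    def test_too_few_samples_rejected(self):
        curve = StressStrainCurve(strain=np.linspace(0, 0.5, 6),
                                  stress=np.zeros(6))
        with pytest.raises(ValueError, match="at least 5"):
            sm.youngs_modulus(curve, strain_cap=0.05)


class TestYieldPoint:
    def test_piecewise_fixture_analytic_intersection(self):
        curve = synth_stress_strain(FIXTURE, GRID)
        eps_y, sig_y, info = sm.yield_point(
            curve, hardening_window=(0.05, 0.15)
        )
        assert eps_y == pytest.approx(0.100 / 4.15, rel=1e-9)
        assert sig_y == pytest.approx(4.65 * 0.100 / 4.15, rel=1e-9)
        assert info["hardening_slope"] == pytest.approx(0.5, rel=1e-9)

    def test_parallel_tangents_rejected(self):
        eps = np.linspace(0, 0.15, 100)
        curve = StressStrainCurve(strain=eps, stress=2.0 * eps)
        with pytest.raises(ValueError, match="parallel|intersection"):
            sm.yield_point(curve)

    def test_noise_limit_converges_to_analytic(self):
        """Yield estimates on noisy fixtures approach the analytic
        intersection as the noise amplitude goes to zero."""
        truth = FIXTURE.analytic_yield[0]
        errs = []
        for sd in (0.01, 0.001, 0.0001):
            est = []
            for seed in range(5):
                spec = SynthCurveSpec(4.65, 0.5, 0.100, noise_sd=sd,
                                      seed=seed)
                curve = synth_stress_strain(spec, GRID)
                eps_y, _, _ = sm.yield_point(
                    curve, hardening_window=(0.05, 0.15)
                )
                est.append(eps_y)
            errs.append(abs(np.mean(est) - truth))
        assert errs[2] < errs[0]
        assert errs[2] < 1e-4


class TestPoissonRatio:
    def test_planted_ratio_recovered(self):
        spec = SynthCurveSpec(4.65, 0.5, 0.100, poisson_ratio=0.405)
        curve = synth_stress_strain(spec, GRID)
        assert sm.poisson_ratio(curve) == pytest.approx(0.405, rel=0.01)

    def test_constant_transverse_gives_zero(self):
        eps = np.linspace(0, 0.1, 100)
        curve = StressStrainCurve(strain=eps, stress=eps,
                                  l_perp=np.ones_like(eps))
        assert sm.poisson_ratio(curve) == 0.0

    def test_volume_preserving_limit_is_half(self):
        eps = np.linspace(0, 0.02, 200)
        curve = StressStrainCurve(strain=eps, stress=eps,
                                  l_perp=(1 + eps) ** -0.5)
        assert sm.poisson_ratio(curve) == pytest.approx(0.5, abs=0.01)

    def test_missing_transverse_rejected(self):
        curve = StressStrainCurve(strain=np.linspace(0, 0.1, 10),
                                  stress=np.zeros(10))
        with pytest.raises(ValueError):
            sm.poisson_ratio(curve)


class TestLargestVoid:
    def test_empty_box_is_box_volume(self):
        from sorbmech.system import SystemConfiguration

        cfg = SystemConfiguration(
            positions=np.empty((0, 3)),
            species=np.empty(0, dtype=object),
            bonds=np.empty((0, 2), dtype=np.intp),
            crosslinks=np.empty((0, 2), dtype=np.intp),
            box=np.full(3, 5.0),
        )
        v, _ = sm.largest_void(cfg, 0.2, 0.4)
        assert v == pytest.approx(125.0)

    def test_planted_sphere_volume_recovered(self):
        """A 0.65-radius cavity carved from a dense medium reports the
        sphere volume (4/3) pi 0.65^3 ~ 1.150 within a voxel shell."""
        cfg = make_lattice(20, 0.15, jitter=0.02, seed=3)
        cav = plant_cavity(cfg, np.full(3, 1.5), 0.65)
        v, centre = sm.largest_void(
            cav, grid_spacing=0.05, probe_radius=0.16,
            particle_radii={"solvent": 0.075},
        )
        expect = 4 / 3 * np.pi * 0.65**3
        shell = 4 / 3 * np.pi * ((0.65 + 0.05) ** 3 - (0.65 - 0.05) ** 3)
        assert abs(v - expect) < shell
        assert np.allclose(centre, 1.5, atol=0.1)

    def test_interstitial_cluster_matches_brute_force(self):
        """Coarse lattice with a probe smaller than the interstice: the
        empty-voxel count equals a direct O(N_vox * N) recount."""
        from sorbmech.system import minimum_image

        cfg = make_lattice(4, 1.0)
        spacing = 0.125
        v, _ = sm.largest_void(cfg, spacing, 0.3,
                               particle_radii={"solvent": 0.2},
                               reexpand=False)
        g = (np.arange(32) + 0.5) * spacing
        mesh = np.stack(np.meshgrid(g, g, g, indexing="ij"), -1).reshape(-1, 3)
        n_empty = 0
        for p in mesh:
            dr = minimum_image(cfg.positions - p, cfg.box)
            if (np.linalg.norm(dr, axis=1) >= 0.5).all():
                n_empty += 1
        # one periodic interstitial network -> every empty voxel in one cluster
        assert v == pytest.approx(n_empty * spacing**3)

    def test_monotone_in_probe_radius(self):
        cfg = make_lattice(20, 0.15, jitter=0.02, seed=5)
        cav = plant_cavity(cfg, np.full(3, 1.5), 0.7)
        vols = [
            sm.largest_void(cav, 0.05, p, particle_radii={"solvent": 0.075})[0]
            for p in (0.16, 0.25, 0.35)
        ]
        assert vols[0] >= vols[1] >= vols[2]

    def test_too_coarse_grid_rejected(self):
        cfg = make_lattice(4, 1.0)
        with pytest.raises(ValueError, match="coarse"):
            sm.largest_void(cfg, 1.0, 0.3)


class TestFailurePoint:
    def test_first_crossing_without_interpolation(self):
        trace = VoidTrace(strain=[0.0, 0.4, 0.8, 1.2],
                          volume=np.array([1, 5, 9, 11.0]), v0=1.0)
        eps_f, _ = sm.failure_point(trace)
        assert eps_f == 1.2

    def test_constant_trace_no_failure(self):
        trace = VoidTrace(strain=np.linspace(0, 1, 10),
                          volume=np.full(10, 2.0), v0=1.0)
        assert sm.failure_point(trace) is None

    def test_linear_fixture_ground_truth(self):
        from sorbmech.synthetic import synth_void_trace

        grid = np.round(np.linspace(0, 1.1, 111), 10)
        trace = synth_void_trace(2.0, lambda e: 2.0 * (1 + 11 * e / 1.1),
                                 grid)
        eps_f, _ = sm.failure_point(trace)
        assert eps_f == pytest.approx(0.9, abs=1e-9)

    def test_invariant_to_frames_after_crossing(self):
        strain = np.linspace(0, 2, 21)
        vol = np.linspace(1, 21, 21)
        t1 = VoidTrace(strain=strain[:12], volume=vol[:12], v0=1.0)
        t2 = VoidTrace(strain=strain, volume=vol, v0=1.0)
        assert sm.failure_point(t1)[0] == sm.failure_point(t2)[0]

    def test_stress_interpolated_from_curve(self):
        curve = StressStrainCurve(strain=np.array([0.0, 1.0]),
                                  stress=np.array([0.0, 10.0]))
        trace = VoidTrace(strain=np.array([0.0, 0.5]),
                          volume=np.array([1.0, 20.0]), v0=1.0)
        _, sig_f = sm.failure_point(trace, curve)
        assert sig_f == pytest.approx(5.0)


class TestCavityDensityProfile:
    def _cavity_gas(self, seed=0):
        cfg = make_gas(4000, 10.0, seed=seed)
        return plant_cavity(cfg, np.full(3, 5.0), 1.5)

    def test_empty_inside_bulk_outside(self):
        cav = self._cavity_gas()
        prof = sm.cavity_density_profile(cav, np.full(3, 5.0), 0.25)
        inside = prof.bin_centers < 1.3
        outside = (prof.bin_centers > 2.0) & (prof.bin_centers < 4.5)
        assert np.all(prof.profiles["all"][inside] < 0.05)
        assert np.mean(prof.profiles["all"][outside]) == pytest.approx(
            1.0, abs=0.1
        )

    def test_translation_invariance(self):
        cav = self._cavity_gas(seed=1)
        p1 = sm.cavity_density_profile(cav, np.full(3, 5.0), 0.25)
        shifted = cav.copy()
        shifted.positions = (shifted.positions + shifted.box) % shifted.box
        p2 = sm.cavity_density_profile(shifted, np.full(3, 5.0), 0.25)
        assert np.allclose(p1.profiles["all"], p2.profiles["all"])

    def test_bin_count_conservation(self):
        """Counts summed over all shells recover the selection size."""
        cav = self._cavity_gas(seed=2)
        r_max = np.sqrt(3) / 2 * cav.box[0] * 1.001
        prof = sm.cavity_density_profile(
            cav, np.full(3, 5.0), 0.25, r_max=r_max
        )
        assert np.sum(prof.raw_counts["all"]) == pytest.approx(
            cav.n_particles, rel=1e-9
        )

    def test_empty_selection_rejected(self):
        cav = self._cavity_gas(seed=3)
        with pytest.raises(ValueError, match="ghost"):
            sm.cavity_density_profile(
                cav, np.full(3, 5.0), 0.25,
                selections={"ghost": np.array([], dtype=int)},
            )


class TestSummaries:
    def test_out_of_range_poisson_flagged(self):
        with pytest.warns(UserWarning, match="Poisson"):
            sm.MechanicalSummary(youngs_modulus=1.0, poisson_ratio=0.7)

    def test_summary_on_fixture(self):
        spec = SynthCurveSpec(4.65, 0.5, 0.100, poisson_ratio=0.405)
        curve = synth_stress_strain(spec, GRID)
        summary = sm.summarize_curve(curve, hardening_window=(0.05, 0.15))
        assert summary.youngs_modulus == pytest.approx(4.65, rel=1e-9)
        assert summary.yield_strain == pytest.approx(0.02410, abs=1e-5)
        assert summary.poisson_ratio == pytest.approx(0.405, rel=0.01)
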