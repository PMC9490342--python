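"""GAB isotherm fitting, concentration conversions, swelling, dielectric."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import sorbmech as sm
from sorbmech import io as sio
from sorbmech.sorption import ConcentrationRecord, GABParams, SorptionIsotherm


REF = GABParams(cm=3.20, k=13.51, b=0.81)


class TestGabEvaluate:
    def test_zero_activity_zero_content(self):
        assert sm.gab_evaluate(0.0, REF) == 0.0

    def test_half_saturation_value(self):
        """C(0.5) with the reference coefficients: 4.851 g/100 g,
        within 1% of the half-saturation solubility 4.82."""
        c = sm.gab_evaluate(0.5, REF)
        assert c == pytest.approx(4.851, abs=1e-3)
        assert c == pytest.approx(4.82, rel=0.01)

    def test_saturation_value(self):
        assert sm.gab_evaluate(1.0, REF) == pytest.approx(16.55, abs=0.01)

    def test_strictly_increasing_on_domain(self):
        a = np.linspace(0, 1, 200)
        c = sm.gab_evaluate(a, REF)
        assert np.all(np.diff(c) > 0)

    def test_pole_rejected(self):
        # valid params keep b < 1 so the pole is outside [0, 1]; a
        # corrupted record must still fail loudly at evaluation
        bad = GABParams(cm=1.0, k=2.0, b=0.9)
        bad.b = 1.2
        with pytest.raises(ValueError, match="pole"):
            sm.gab_evaluate(1.0, bad)
        with pytest.raises(ValueError):
            GABParams(cm=1.0, k=2.0, b=1.2)


class TestGabFit:
    def test_exact_recovery_from_noiseless_data(self):
        a = np.linspace(0.05, 0.95, 12)
        iso = SorptionIsotherm(activity=a, content=sm.gab_evaluate(a, REF))
        fit = sm.gab_fit(iso)
        assert fit.diagnostics["sse"] < 1e-10
        assert fit.cm == pytest.approx(REF.cm, rel=1e-4)
        assert fit.k == pytest.approx(REF.k, rel=1e-3)
        assert fit.b == pytest.approx(REF.b, rel=1e-4)

    def test_low_parameter_bias_under_noise(self):
        """Across replicates of mildly noisy synthetic isotherms the
        mean fitted parameters stay within 2% of the truth."""
        a = np.linspace(0.05, 0.95, 15)
        truth = sm.gab_evaluate(a, REF)
        rng = np.random.default_rng(42)
        fits = []
        for _ in range(60):
            noisy = truth * (1 + rng.normal(0, 0.005, a.shape))
            iso = SorptionIsotherm(activity=a, content=noisy)
            f = sm.gab_fit(iso)
            fits.append([f.cm, f.k, f.b])
        mean = np.mean(fits, axis=0)
        assert mean[0] == pytest.approx(REF.cm, rel=0.02)
        assert mean[1] == pytest.approx(REF.k, rel=0.02)
        assert mean[2] == pytest.approx(REF.b, rel=0.02)

    def test_too_few_points_rejected(self):
        iso = SorptionIsotherm(activity=[0.1, 0.5, 0.9],
                               content=[1.0, 2.0, 3.0])
        with pytest.raises(ValueError, match="4"):
            sm.gab_fit(iso)

    def test_weight_modes(self):
        iso = sio.table1_isotherm()
        rel = sm.gab_fit(iso, weights="relative")
        unw = sm.gab_fit(iso, weights="none")
        assert rel.k != unw.k  # different objectives, different optimum
        with pytest.raises(ValueError):
            sm.gab_fit(iso, weights="bogus")


class TestGabEnthalpy:
    def test_unit_k_zero_enthalpy(self):
        assert sm.gab_enthalpy(1.0, 300.0) == 0.0

    def test_reference_value(self):
        # R T ln K at 300 K for K = 13.51
        assert sm.gab_enthalpy(13.51, 300.0) == pytest.approx(6.493, abs=2e-3)

    def test_round_trip(self):
        from sorbmech.constants import R_GAS_KJ

        dh = sm.gab_enthalpy(13.51, 300.0)
        assert np.exp(dh / (R_GAS_KJ * 300.0)) == pytest.approx(13.51,
                                                                rel=1e-12)


class TestIsothermPointFromTrace:
    def test_constant_trace_zero_error(self):
        c, err = sm.isotherm_point_from_trace(np.full(50, 100.0), 1000.0)
        assert err == 0.0

    def test_alternating_trace_rms(self):
        trace = np.tile([90.0, 110.0], 25)
        conv = 100.0 * 18.015 / 1000.0
        c, err = sm.isotherm_point_from_trace(trace, 1000.0)
        assert c == pytest.approx(100.0 * conv)
        assert err == pytest.approx(10.0 * conv)

    def test_doubling_sorbent_mass_halves_content(self):
        trace = np.full(20, 50.0)
        c1, _ = sm.isotherm_point_from_trace(trace, 1000.0)
        c2, _ = sm.isotherm_point_from_trace(trace, 2000.0)
        assert c2 == pytest.approx(c1 / 2)

    def test_empty_segment_rejected(self):
        with pytest.raises(ValueError):
            sm.isotherm_point_from_trace(np.array([]), 1000.0)


class TestConvertConcentration:
    def test_saturation_row_per_residue(self):
        """C = 17.19 g/100 g with 96.23 g/mol residues: 0.918 sorbate
        molecules per residue."""
        rec = sm.convert_concentration(
            ConcentrationRecord(c=17.19, m_res=96.23)
        )
        assert rec.per_residue == pytest.approx(0.918, abs=5e-4)

    def test_invert_density_conversion(self):
        rec = sm.convert_concentration(
            ConcentrationRecord(c=17.19, number_density=6.237)
        )
        assert rec.rho_k == pytest.approx(1.085, abs=1e-3)

    def test_zero_content_all_zero(self):
        rec = sm.convert_concentration(
            ConcentrationRecord(c=0.0, rho_k=1.3, m_res=96.0, v_w=0.02)
        )
        assert rec.number_density == 0.0
        assert rec.per_residue == 0.0
        assert rec.vol_percent == 0.0

    def test_inconsistent_overdetermined_input_rejected(self):
        with pytest.raises(ValueError, match="per_residue"):
            sm.convert_concentration(
                ConcentrationRecord(c=17.19, m_res=96.23, per_residue=0.5)
            )

    @given(
        c=st.floats(0.5, 30.0),
        rho_k=st.floats(0.8, 1.4),
        m_res=st.floats(80.0, 120.0),
        v_w=st.floats(0.01, 0.05),
    )
    @settings(max_examples=40, deadline=None)
    def test_conversions_round_trip(self, c, rho_k, m_res, v_w):
        """Completing from (C, rho_k, m_res, v_w) and then re-deriving C
        from the derived fields is the identity to 1e-9 relative."""
        rec = sm.convert_concentration(
            ConcentrationRecord(c=c, rho_k=rho_k, m_res=m_res, v_w=v_w)
        )
        back = sm.convert_concentration(
            ConcentrationRecord(per_residue=rec.per_residue, m_res=m_res,
                                number_density=rec.number_density,
                                v_w=v_w)
        )
        assert back.c == pytest.approx(c, rel=1e-9)
        assert back.rho_k == pytest.approx(rho_k, rel=1e-9)


class TestReferenceTableConsistency:
    def test_solubility_per_residue_ratio_constant(self):
        """Solubility / molecules-per-residue across the packaged table:
        relative standard deviation below 0.3% (one implied mean residue
        mass ~96.2 g/mol)."""
        df = sio.load_table1()
        ratio = (df["solubility_g_per_100g_keratin"]
                 / df["water_per_residue"]).to_numpy()
        rsd = ratio.std() / ratio.mean()
        assert rsd < 0.003
        m_res = 100.0 * 18.015 / ratio.mean()
        assert m_res == pytest.approx(96.2, abs=0.3)

    def test_predict_saturation_per_residue_from_other_rows(self):
        df = sio.load_table1()
        ratio = (df["solubility_g_per_100g_keratin"]
                 / df["water_per_residue"]).to_numpy()
        pred = 17.19 / ratio[:-1].mean()
        assert round(pred, 3) == 0.918

    def test_sigmoidal_shape(self):
        """The packaged isotherm is type II: its curvature changes sign
        exactly once over the activity range."""
        iso = sio.table1_isotherm()
        fit = sm.gab_fit(iso)
        a = np.linspace(0.02, 0.98, 97)
        c = sm.gab_evaluate(a, fit)
        curv_sign = np.sign(np.round(np.diff(c, 2), 12))
        changes = np.count_nonzero(np.diff(curv_sign[curv_sign != 0]) != 0)
        assert changes == 1


class TestSwellingAndDielectric:
    def test_toy_swelling_linear_in_content(self):
        """Equilibrium NPT volumes of the toy network at increasing
        solvent content: the swelling ratio is linear in content
        (R^2 > 0.98), the same linearity seen for water-swollen
        protein matrices."""
        import warnings

        from sorbmech.pipeline import toy_swelling_series

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = toy_swelling_series(seed=5)
        x = np.array([r["n_solvent"] for r in res], dtype=float)
        y = np.array([r["swelling_percent"] for r in res])
        A = np.vstack([x, np.ones_like(x)]).T
        _, resid, *_ = np.linalg.lstsq(A, y, rcond=None)
        ss_tot = np.sum((y - y.mean()) ** 2)
        r2 = 1 - (resid[0] if resid.size else 0.0) / ss_tot
        assert r2 > 0.98
        assert np.all(np.diff(y) > 0)

    def test_swelling_ratio_values(self):
        assert sm.swelling_ratio(100.0, 100.0) == 0.0
        assert sm.swelling_ratio(110.0, 100.0) == pytest.approx(10.0)
        with pytest.raises(ValueError):
            sm.swelling_ratio(100.0, 0.0)

    def test_dielectric_endpoints(self):
        assert sm.effective_dielectric(0.0) == 4.0
        assert sm.effective_dielectric(1.0) == 72.0

    def test_dielectric_at_saturation_water_fraction(self):
        """12.65 vol% water: effective dielectric 12.6, consistent with
        the reported 12.7 within rounding."""
        assert sm.effective_dielectric(0.1265) == pytest.approx(12.60,
                                                                abs=0.01)
        assert sm.effective_dielectric(0.1265) == pytest.approx(12.7,
                                                                abs=0.15)

    def test_dielectric_bad_fraction_rejected(self):
        with pytest.raises(ValueError):
            sm.effective_dielectric(1.2)
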