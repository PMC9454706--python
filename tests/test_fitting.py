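"""Curve-fitting estimators: exactness on their model class, failure
flagging, and inversion of the forward exchange model."""

import dataclasses

import numpy as np
import pytest

import ffcrelax as fr
from ffcrelax.exchange import ExchangeParams, apparent_from_physio
from ffcrelax.fitting import IdentifiabilityError


def curve_from(t, y, nu=0.01, seq="PP/S", sigma=None):
    return fr.DecayCurve("m1", "synthetic", nu, seq, np.asarray(t),
                         np.asarray(y), noise_sigma=sigma)


class TestMonoFit:
    def test_exact_on_noiseless_exponential(self):
        t = np.geomspace(1e-3, 2.0, 16)
        fit = fr.fit_monoexponential(curve_from(t, 2.0 * np.exp(-3.0 * t)))
        assert fit.success
        # residuals hit machine precision; parameter precision is then set
        # by the optimizer's step tolerance
        assert fit.r1 == pytest.approx(3.0, abs=1e-8)
        assert fit.amplitude == pytest.approx(2.0, abs=1e-8)
        assert fit.offset == pytest.approx(0.0, abs=1e-8)

    def test_recovers_offset_and_negative_amplitude(self):
        # non-polarized recovery toward equilibrium 0.7
        t = np.geomspace(1e-3, 4.0, 32)
        y = 0.7 * (1 - np.exp(-1.5 * t))
        fit = fr.fit_monoexponential(curve_from(t, y, nu=10.0, seq="NP/S"))
        assert fit.r1 == pytest.approx(1.5, rel=1e-8)
        assert fit.amplitude == pytest.approx(-0.7, rel=1e-8)

    def test_constant_signal_flagged_not_fitted(self):
        t = np.geomspace(1e-3, 2.0, 16)
        fit = fr.fit_monoexponential(curve_from(t, np.full(16, 0.5)))
        assert not fit.success
        assert np.isnan(fit.r1)
        assert "unidentifiable" in fit.message

    def test_glio6_replicates_recover_calibrated_rate(self, presets):
        """Ten 1%-noise replicates at 0.01 MHz average to the preset's
        calibrated low-field rate within 2%."""
        preset = dataclasses.replace(presets["Glio6"], between_animal_cv=0.0)
        spec = fr.CohortSpec(presets=[preset], n_specimens=10,
                             noise_fraction=0.01, seed=42)
        curves, _ = fr.simulate_cohort(spec)
        rates = [fr.fit_monoexponential(c).r1 for c in curves
                 if np.isclose(c.evolution_frequency, 0.01)]
        assert np.mean(rates) == pytest.approx(preset.reference_r1, rel=0.02)


class TestBiexpFit:
    def test_inverts_forward_model_exactly(self):
        p = ExchangeParams(r1_in=3.0, r1_ex=1.0, tau_in=0.5, v_ex=0.2)
        truth = apparent_from_physio(p)
        t = np.geomspace(1e-3, 4.0, 32)
        y = 1.7 * ((1 - truth.a_short) * np.exp(-t * truth.r1_long)
                   + truth.a_short * np.exp(-t * truth.r1_short))
        fit = fr.fit_biexponential(curve_from(t, y))
        assert fit.success
        assert fit.r1_long == pytest.approx(truth.r1_long, rel=1e-6)
        assert fit.r1_short == pytest.approx(truth.r1_short, rel=1e-6)
        assert fit.a_short == pytest.approx(truth.a_short, rel=1e-5)
        assert fit.r1_short >= fit.r1_long

    def test_too_few_points_rejected(self):
        t = np.geomspace(1e-3, 1.0, 6)
        with pytest.raises(ValueError, match="at least 8"):
            fr.fit_biexponential(curve_from(t, np.exp(-t)))

    def test_explicit_init_is_honored(self):
        p = ExchangeParams(r1_in=3.0, r1_ex=1.0, tau_in=0.5, v_ex=0.2)
        truth = apparent_from_physio(p)
        t = np.geomspace(1e-3, 4.0, 32)
        y = (1 - truth.a_short) * np.exp(-t * truth.r1_long) \
            + truth.a_short * np.exp(-t * truth.r1_short)
        fit = fr.fit_biexponential(curve_from(t, y), init=truth)
        assert fit.r1_long == pytest.approx(truth.r1_long, rel=1e-6)


class TestSelectModel:
    def test_prefers_bi_on_strongly_biexponential_curve(self):
        t = np.geomspace(1e-3, 4.0, 32)
        y = 0.5 * np.exp(-12 * t) + 0.5 * np.exp(-1.2 * t)
        rng = np.random.default_rng(0)
        choice = fr.select_model(
            curve_from(t, y + rng.normal(0, 0.002, t.size), sigma=0.002))
        assert choice.decision == "bi"
        assert choice.delta_aicc > 2

    def test_prefers_mono_under_the_null(self):
        t = np.geomspace(1e-3, 4.0, 32)
        rng = np.random.default_rng(1)
        y = np.exp(-3 * t) + rng.normal(0, 0.01, t.size)
        choice = fr.select_model(curve_from(t, y, sigma=0.01))
        assert choice.decision == "mono"

    def test_tie_resolves_to_mono(self):
        # noiseless mono-exponential: both models fit perfectly, the
        # parsimony rule must pick mono
        t = np.geomspace(1e-3, 4.0, 32)
        choice = fr.select_model(curve_from(t, np.exp(-3 * t)))
        assert choice.decision == "mono"

    def test_strong_fast_component_detected_at_low_field(self, presets):
        """The proliferative model's low-field decay is visibly
        bi-exponential at instrument noise."""
        preset = dataclasses.replace(presets["U87"], between_animal_cv=0.0)
        spec = fr.CohortSpec(presets=[preset], n_specimens=1,
                             noise_fraction=0.01, seed=3)
        curves, _ = fr.simulate_cohort(spec)
        c = next(c for c in curves if np.isclose(c.evolution_frequency, 0.01))
        choice = fr.select_model(c)
        assert choice.decision == "bi"
        # and the bi-exponential residual is strictly smaller
        n = c.n_points
        assert choice.bi.redchi * (n - 5) < choice.mono.redchi * (n - 3)


class TestMultifield2SX:
    def test_noiseless_inversion_is_exact(self, presets, matrigel_map):
        preset = dataclasses.replace(presets["U87"], between_animal_cv=0.0)
        spec = fr.CohortSpec(presets=[preset], n_specimens=1,
                             noise_fraction=0.0, seed=1)
        curves, _ = fr.simulate_cohort(spec)
        res = fr.fit_2sx_multifield(curves, matrigel_map,
                                    fr.V_EX_BOUNDS["tumor"])
        assert res.success
        assert res.tau_in == pytest.approx(preset.tau_in, rel=1e-4)
        assert res.v_ex == pytest.approx(preset.v_ex, rel=1e-4)
        for nu, r1in in res.r1_in_per_field.items():
            assert r1in == pytest.approx(preset.r1_in(nu), rel=1e-3)

    def test_too_few_fields_raises_identifiability_error(self, presets,
                                                         matrigel_map):
        preset = presets["U87"]
        spec = fr.CohortSpec(presets=[preset], n_specimens=1,
                             noise_fraction=0.0, seed=1)
        curves, _ = fr.simulate_cohort(spec)
        with pytest.raises(IdentifiabilityError):
            fr.fit_2sx_multifield(curves[:3], matrigel_map,
                                  fr.V_EX_BOUNDS["tumor"])

    def test_missing_extracellular_rate_raises(self, presets):
        spec = fr.CohortSpec(presets=[presets["U87"]], n_specimens=1,
                             noise_fraction=0.0, seed=1)
        curves, _ = fr.simulate_cohort(spec)
        with pytest.raises(ValueError, match="extracellular rate"):
            fr.fit_2sx_multifield(curves, {0.01: 1.0},
                                  fr.V_EX_BOUNDS["tumor"])

    def test_label_exchange_symmetry_of_forward_model(self, scheme):
        """With equal pool sizes the compartment labels are arbitrary:
        swapping the intrinsic rates leaves the signal unchanged."""
        t = np.geomspace(1e-3, 4.0, 32)
        p = ExchangeParams(r1_in=4.0, r1_ex=1.5, tau_in=0.5, v_ex=0.5)
        q = ExchangeParams(r1_in=1.5, r1_ex=4.0, tau_in=p.tau_ex, v_ex=0.5)
        m_p = fr.magnetization_model(p, scheme, 0.01, t)
        m_q = fr.magnetization_model(q, scheme, 0.01, t)
        np.testing.assert_allclose(m_p, m_q, rtol=1e-12)

    def test_fix_vex_mode_freezes_v_ex(self, presets, matrigel_map):
        preset = dataclasses.replace(presets["Glio96"], between_animal_cv=0.0)
        spec = fr.CohortSpec(presets=[preset], n_specimens=1,
                             noise_fraction=0.0, seed=2)
        curves, _ = fr.simulate_cohort(spec)
        res = fr.fit_2sx_multifield(curves, matrigel_map,
                                    fr.V_EX_BOUNDS["tumor"],
                                    fix_v_ex=preset.v_ex)
        assert res.v_ex == preset.v_ex
        assert res.v_ex_stderr is None
        assert res.tau_in == pytest.approx(preset.tau_in, rel=1e-4)

    def test_reports_per_field_rates_and_diagnostics(self, fixed_vex_fits):
        for fits in fixed_vex_fits.values():
            for res in fits:
                assert res.success
                assert len(res.r1_in_per_field) == 8
                assert res.tau_in_stderr is None or res.tau_in_stderr > 0
                assert np.isfinite(res.redchi)
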