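"""Synthetic cohort generator: presets, determinism, noise and mixtures."""

import dataclasses

import numpy as np
import pytest

import ffcrelax as fr
from ffcrelax.cohort import (
    WHOLE_LEG_R1,
    _apparent_mono_r1,
    builtin_presets,
    implied_tumor_fraction,
)
from ffcrelax.exchange import magnetization_model


class TestPresets:
    def test_generating_lifetimes(self, presets):
        assert presets["U87"].tau_in == pytest.approx(0.826)
        assert presets["Glio6"].tau_in == pytest.approx(0.516)
        assert presets["Glio96"].tau_in == pytest.approx(0.596)
        assert presets["muscle"].tau_in == pytest.approx(1.190)

    def test_v_ex_inside_class_bounds(self, presets):
        for preset in presets.values():
            lo, hi = fr.V_EX_BOUNDS[preset.tissue_class]
            assert lo <= preset.v_ex <= hi

    def test_invasive_models_have_larger_v_ex(self, presets):
        assert presets["Glio6"].v_ex > presets["U87"].v_ex
        assert presets["Glio96"].v_ex > presets["U87"].v_ex

    def test_out_of_bounds_v_ex_rejected(self):
        with pytest.raises(ValueError, match="bounds"):
            fr.TissuePreset(name="bad", tissue_class="tumor", tau_in=0.5,
                            v_ex=0.6, r1_in_profile=(1.0, 0.4))

    def test_calibration_closure(self, presets, scheme):
        """Mono-fitting the noiseless forward curve at 0.01 MHz reproduces
        each preset's reference rate to 0.1%."""
        for preset in presets.values():
            r1 = _apparent_mono_r1(preset, scheme, 0.01,
                                   preset.r1_in_profile[0])
            assert r1 == pytest.approx(preset.reference_r1, rel=1e-3)

    def test_matrigel_rates_weakly_dispersive(self, presets, scheme):
        p = presets["U87"]
        rates = [p.r1_ex(nu) for nu in scheme.evolution_frequencies]
        assert all(r > 0 for r in rates)
        assert rates == sorted(rates, reverse=True)
        assert rates[0] / rates[-1] < 3  # much flatter than the tissues

    def test_implied_tumor_fraction_closes_eq1(self, presets):
        # calibration anchor: the U87 composite at f=0.6 gives the printed
        # whole-volume rate exactly
        assert implied_tumor_fraction("U87") == pytest.approx(0.6, abs=1e-12)
        for name in ("U87", "Glio6", "Glio96"):
            f = implied_tumor_fraction(name)
            mix = (f * presets[name].reference_r1
                   + (1 - f) * presets["muscle"].reference_r1)
            assert mix == pytest.approx(WHOLE_LEG_R1[name], abs=1e-9)


class TestSimulateCohort:
    def test_noiseless_curves_equal_forward_model(self, scheme):
        preset = dataclasses.replace(builtin_presets()["U87"],
                                     between_animal_cv=0.0)
        spec = fr.CohortSpec(presets=[preset], n_specimens=1,
                             noise_fraction=0.0, seed=1)
        curves, truth = fr.simulate_cohort(spec)
        assert truth.tau_in[0] == preset.tau_in
        for c in curves:
            expected = magnetization_model(
                preset.exchange_params(c.evolution_frequency), scheme,
                c.evolution_frequency, c.times)
            np.testing.assert_allclose(c.magnetization, expected, rtol=1e-12)

    def test_shape_contract(self, presets):
        spec = fr.CohortSpec(presets=[presets["Glio6"]], n_specimens=1,
                             noise_fraction=0.01, seed=0)
        curves, truth = fr.simulate_cohort(spec)
        assert len(curves) == 8
        assert sum(c.n_points for c in curves) == 256
        assert len(truth) == 1

    def test_seed_contract(self, presets):
        spec = fr.CohortSpec(presets=[presets["U87"]], n_specimens=2,
                             noise_fraction=0.01, seed=9)
        c1, t1 = fr.simulate_cohort(spec)
        c2, t2 = fr.simulate_cohort(spec)
        for a, b in zip(c1, c2):
            np.testing.assert_allclose(a.magnetization, b.magnetization,
                                       atol=1e-12, rtol=0)
        spec3 = dataclasses.replace(spec, seed=10)
        c3, _ = fr.simulate_cohort(spec3)
        assert not np.allclose(c1[0].magnetization, c3[0].magnetization)

    def test_noise_realism_matches_instrument_precision(self, presets,
                                                        matrigel_map):
        """Fitted R1 scatter across replicates at 1% point noise stays
        within the instrument's stated few-percent rate reproducibility."""
        preset = dataclasses.replace(presets["U87"], between_animal_cv=0.0)
        spec = fr.CohortSpec(presets=[preset], n_specimens=10,
                             noise_fraction=0.01, seed=4)
        curves, _ = fr.simulate_cohort(spec)
        rates = [fr.fit_monoexponential(c).r1 for c in curves
                 if np.isclose(c.evolution_frequency, 0.01)]
        assert np.std(rates) / np.mean(rates) < 0.02


class TestSimulateWholeLeg:
    def test_boundary_fractions_reduce_to_single_tissue(self, presets, scheme):
        tumor = dataclasses.replace(presets["U87"], between_animal_cv=0.0)
        muscle = dataclasses.replace(presets["muscle"], between_animal_cv=0.0)
        spec = fr.CohortSpec(presets=[tumor], n_specimens=1,
                             noise_fraction=0.0, seed=0)
        pure_tumor, _ = fr.simulate_cohort(spec)
        leg_all_tumor, _ = fr.simulate_whole_leg(tumor, muscle, 1.0, spec)
        for a, b in zip(sorted(pure_tumor, key=lambda c: c.evolution_frequency),
                        sorted(leg_all_tumor, key=lambda c: c.evolution_frequency)):
            np.testing.assert_allclose(a.magnetization, b.magnetization,
                                       rtol=1e-12)
        spec_m = fr.CohortSpec(presets=[muscle], n_specimens=1,
                               noise_fraction=0.0, seed=0)
        pure_muscle, _ = fr.simulate_cohort(spec_m)
        leg_no_tumor, _ = fr.simulate_whole_leg(tumor, muscle, 0.0, spec)
        for a, b in zip(sorted(pure_muscle, key=lambda c: c.evolution_frequency),
                        sorted(leg_no_tumor, key=lambda c: c.evolution_frequency)):
            np.testing.assert_allclose(a.magnetization, b.magnetization,
                                       rtol=1e-12)

    def test_signal_mixing_is_weighted_sum(self, presets, scheme):
        tumor = dataclasses.replace(presets["U87"], between_animal_cv=0.0)
        muscle = dataclasses.replace(presets["muscle"], between_animal_cv=0.0)
        spec = fr.CohortSpec(presets=[tumor], n_specimens=1,
                             noise_fraction=0.0, seed=0)
        leg, truth = fr.simulate_whole_leg(tumor, muscle, 0.6, spec)
        assert truth.f_tum[0] == 0.6
        for c in leg:
            nu = c.evolution_frequency
            m_t = magnetization_model(tumor.exchange_params(nu), scheme, nu,
                                      c.times)
            m_m = magnetization_model(muscle.exchange_params(nu), scheme, nu,
                                      c.times)
            np.testing.assert_allclose(c.magnetization,
                                       0.6 * m_t + 0.4 * m_m, rtol=1e-12)

    def test_initial_slope_of_signal_mixture_is_rate_weighted(self):
        """The short-time decay rate of a signal mixture is the volume-
        weighted mean of the component rates (here 0.6*10 + 0.4*4 = 7.6)."""
        t = np.array([0.0, 1e-7])
        mix = 0.6 * np.exp(-10 * t) + 0.4 * np.exp(-4 * t)
        slope = -(np.log(mix[1]) - np.log(mix[0])) / (t[1] - t[0])
        assert slope == pytest.approx(7.6, rel=1e-5)

    def test_rate_mixing_truth_records_component_rates(self, presets):
        spec = fr.CohortSpec(presets=[presets["U87"]], n_specimens=2,
                             noise_fraction=0.0, seed=3)
        curves, truth = fr.simulate_whole_leg(
            presets["U87"], presets["muscle"], 0.6, spec, mixing="rate")
        expected = 0.6 * truth.r1_tum_apparent + 0.4 * truth.r1_mus_apparent
        np.testing.assert_allclose(truth.r1_mix, expected, rtol=1e-12)

    def test_invalid_fraction_rejected(self, presets):
        spec = fr.CohortSpec(presets=[presets["U87"]], n_specimens=1,
                             noise_fraction=0.0, seed=0)
        with pytest.raises(ValueError):
            fr.simulate_whole_leg(presets["U87"], presets["muscle"], 1.5, spec)
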