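"""Shared fixtures: presets, schemes, and the (expensive) fitted cohorts.

Cohort simulations and multi-field fits are session-scoped so the
parameter-recovery results are computed once and reused by the pipeline
and acceptance tests.
"""

from __future__ import annotations

import numpy as np
import pytest

import ffcrelax as fr
from ffcrelax.cohort import apparent_profile, builtin_presets

#: protocol constants shared across recovery tests
COHORT_N = 10
NOISE = 0.01
COHORT_SEED = 42
MIXTURE_SEED = 11
COMPOSITE_SEED = 5
F_TUM = 0.6


@pytest.fixture(scope="session")
def scheme():
    return fr.default_scheme()


@pytest.fixture(scope="session")
def presets():
    return builtin_presets()


@pytest.fixture(scope="session")
def matrigel_map(scheme, presets):
    p = presets["U87"]  # r1_ex_profile shared by all presets
    return {nu: p.r1_ex(nu) for nu in scheme.evolution_frequencies}


@pytest.fixture(scope="session")
def tumor_cohorts(presets):
    """Simulated tissue-only cohorts (curves + ground truth) per preset."""
    out = {}
    for name, preset in presets.items():
        spec = fr.CohortSpec(presets=[preset], n_specimens=COHORT_N,
                             noise_fraction=NOISE, seed=COHORT_SEED)
        out[name] = fr.simulate_cohort(spec)
    return out


@pytest.fixture(scope="session")
def fixed_vex_fits(tumor_cohorts, presets, matrigel_map):
    """Multi-field 2SX fits with v_ex fixed to the generating value."""
    out = {}
    for name, (curves, truth) in tumor_cohorts.items():
        preset = presets[name]
        bounds = fr.V_EX_BOUNDS[preset.tissue_class]
        fits = []
        for sid in truth.specimen_id:
            cc = [c for c in curves if c.specimen_id == sid]
            fits.append(fr.fit_2sx_multifield(cc, matrigel_map, bounds,
                                              fix_v_ex=preset.v_ex))
        out[name] = fits
    return out


@pytest.fixture(scope="session")
def free_vex_fits(tumor_cohorts, presets, matrigel_map):
    """Bounds-constrained fits (v_ex free) for the tumor models."""
    out = {}
    for name in ("U87", "Glio6", "Glio96"):
        curves, truth = tumor_cohorts[name]
        fits = []
        for sid in truth.specimen_id:
            cc = [c for c in curves if c.specimen_id == sid]
            with np.errstate(all="ignore"):
                fits.append(fr.fit_2sx_multifield(
                    cc, matrigel_map, fr.V_EX_BOUNDS["tumor"]))
        out[name] = fits
    return out


def _recover_tumor_rates(tumor_name, presets, scheme, seed):
    """The whole-leg recovery protocol: rate-level mixtures, per-field mono
    fits, muscle subtraction with the specimen's known muscle profile."""
    preset = presets[tumor_name]
    muscle = presets["muscle"]
    spec = fr.CohortSpec(presets=[preset], n_specimens=COHORT_N,
                         noise_fraction=NOISE, seed=seed)
    curves, truth = fr.simulate_whole_leg(preset, muscle, F_TUM, spec,
                                          mixing="rate")
    recovered = []
    for _, row in truth.iterrows():
        known_muscle = apparent_profile(muscle, scheme,
                                        tau_in=row.muscle_tau_in,
                                        amp_a=row.muscle_r1_in_amplitude)
        records = [(row.specimen_id, c.evolution_frequency,
                    fr.fit_monoexponential(c))
                   for c in curves if c.specimen_id == row.specimen_id]
        profile = fr.build_profile(records, "whole-leg")
        tumor = fr.subtract_muscle(profile, fr.MixtureSpec(F_TUM, known_muscle))
        recovered.append(
            float(tumor.rates[np.isclose(tumor.frequencies, 0.01)][0]))
    return np.asarray(recovered)


@pytest.fixture(scope="session")
def whole_leg_recovery(presets, scheme):
    """Recovered tumor rates at 0.01 MHz for the U87 and Glio6 mixtures."""
    return {name: _recover_tumor_rates(name, presets, scheme, MIXTURE_SEED)
            for name in ("U87", "Glio6")}


@pytest.fixture(scope="session")
def composite_rates(presets):
    """Whole-volume mono-fit rates at 0.01 MHz of the U87 composite cohort."""
    spec = fr.CohortSpec(presets=[presets["U87"]], n_specimens=COHORT_N,
                         noise_fraction=NOISE, seed=COMPOSITE_SEED)
    curves, _ = fr.simulate_whole_leg(presets["U87"], presets["muscle"],
                                      F_TUM, spec, mixing="rate")
    return np.asarray([fr.fit_monoexponential(c).r1 for c in curves
                       if np.isclose(c.evolution_frequency, 0.01)])


@pytest.fixture(scope="session")
def cohort_powerlaws(tumor_cohorts):
    """Group NMRD profiles and power-law fits for the three tumor models."""
    out = {}
    for name in ("U87", "Glio6", "Glio96"):
        curves, truth = tumor_cohorts[name]
        records = [(c.specimen_id, c.evolution_frequency,
                    fr.fit_monoexponential(c)) for c in curves]
        profile = fr.build_profile(records, name)
        out[name] = (profile, fr.fit_power_law(profile))
    return out
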