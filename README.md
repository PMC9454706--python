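# ffcrelax

Fast-field-cycling (FFC) NMR relaxometry analysis of transmembrane water
exchange in tissue, with synthetic glioma cohorts for end-to-end
parameter-recovery studies.

FFC relaxometry measures the longitudinal relaxation rate R₁ at proton
Larmor frequencies far below clinical field strengths (here 0.01–10 MHz)
by cycling the magnet between a polarization field, a variable evolution
field, and a detection field. At very low fields R₁ becomes sensitive to
the kinetics of water exchange across the cell membrane, which makes the
intracellular water lifetime τ_in — shorter in aggressively invasive
tumors — measurable in vivo without contrast agents. This package is for
researchers who want to simulate, fit and benchmark that analysis chain.

## The model

Longitudinal magnetization of the intra-/extracellular two-pool system
relaxes by coupled Bloch–McConnell kinetics (the two-site exchange, 2SX,
model). The deviation from equilibrium decays as

    M_z(t) = M_eq + (M_0 − M_eq) [(1 − a_s) e^(−R₁ᴸ t) + a_s e^(−R₁ˢ t)]

where the apparent rates R₁ˢ ≥ R₁ᴸ are the eigenvalues of

    A = [ R₁ᵢₙ + k_in     −k_ex        ]
        [ −k_in           R₁ₑₓ + k_ex  ]

with k_in = 1/τ_in, k_ex = 1/τ_ex, constrained by volume closure
V_in + V_ex = 1 and mass balance V_in τ_ex = V_ex τ_in. Fitting the
decay simultaneously over all evolution fields — with one intrinsic
intracellular rate per field, the extracellular rate fixed to a Matrigel
reference, and τ_in shared — yields τ_in and the extracellular volume
fraction V_ex.

The per-field mono-exponential rates assemble into an NMRD dispersion
profile R₁(ν); the whole-leg signal is a tumor/muscle mixture corrected
through the volume-weighted rate decomposition
R₁ = f_tum R₁ᵗᵘᵐ + (1 − f_tum) R₁ᵐᵘˢ, and the dispersive part of the
tumor profile is summarized by the power law R₁(ν) = A_P ν^(−β).

## Worked example

```python
import numpy as np
import ffcrelax as fr

presets = fr.builtin_presets()          # U87, Glio6, Glio96, muscle
scheme = fr.default_scheme()            # 8 fields, 32 t_E per field
matrigel = {nu: presets["U87"].r1_ex(nu)
            for nu in scheme.evolution_frequencies}

spec = fr.CohortSpec(presets=[presets["Glio6"]], n_specimens=10,
                     noise_fraction=0.01, seed=7)
curves, truth = fr.simulate_cohort(spec)

taus = []
for sid in truth.specimen_id:
    cc = [c for c in curves if c.specimen_id == sid]
    res = fr.fit_2sx_multifield(cc, matrigel, fr.V_EX_BOUNDS["tumor"],
                                fix_v_ex=presets["Glio6"].v_ex)
    taus.append(res.tau_in)
print(f"tau_in = {np.mean(taus):.3f} +/- "
      f"{np.std(taus, ddof=1)/np.sqrt(len(taus)):.3f} s "
      f"(generating value {presets['Glio6'].tau_in} s)")
```

prints

```
tau_in = 0.480 +/- 0.010 s (generating value 0.516 s)
```

i.e. a ten-animal cohort at 1% instrument noise recovers the invasive
model's generating intracellular lifetime to within about 7%. (The
quoted error is the scatter of the fitted values; the cohort mean itself
moves by a few percent from seed to seed — see `docs/methods.md` for the
precision analysis.)
The same cohort's per-field mono-exponential fits give the NMRD profile
(`fr.build_profile`), and `fr.fit_power_law` returns its dispersion
parameters (A_P, β).

A command-line interface covers the same flow:

```sh
ffcrelax simulate --preset Glio6 --n 10 --noise 0.01 --seed 7 \
    --out curves.csv --truth truth.csv
ffcrelax matrigel --out matrigel.csv
ffcrelax fit-exchange --curves curves.csv --matrigel matrigel.csv \
    --tissue-class tumor --fix-vex 0.45 --out exchange.csv
ffcrelax fit-mono --curves curves.csv --out fits.csv
ffcrelax nmrd --fits fits.csv --out-profile profile.csv --out-powerlaw pl.csv
ffcrelax report --exchange exchange.csv --powerlaw pl.csv --out report/
```

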