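# Methods

## Acquisition model

A field-cycling measurement polarizes the sample at a high field
(proton Larmor frequency 14.5 MHz), lets the magnetization evolve at one
of eight evolution fields for a time t_E, and detects at 13 MHz. Seven
evolution fields between 0.01 and 1 MHz are acquired pre-polarized
(PP/S: the curve decays from the polarized amplitude toward the small
evolution-field equilibrium); one at 10 MHz is acquired non-polarized
(NP/S: the curve grows from zero). Magnetization is expressed in units
of the polarization-field equilibrium, so every PP/S curve starts at 1
and the equilibrium at evolution frequency ν is ν/14.5. Polarization is
taken as complete (the polarization interval is long against T₁ at
14.5 MHz), and a single amplitude is shared by all fields of a specimen
— in hardware the pre-polarized starting magnetization cannot depend on
the evolution field, and this cross-field constraint carries a large
share of the information that separates the exchange time from the
per-field rates.

Each field records 32 evolution times, log-spaced from 1 ms to a
per-field maximum interpolated (linearly in log ν) from 2.8 s at
0.01 MHz to 4 s at 10 MHz. The protocol states only the count and the
range; log spacing was chosen because the fast bi-exponential component
lives in the first tens of milliseconds.

## Two-site exchange forward model

Intra- and extracellular water pools with volume fractions
V_in + V_ex = 1 exchange with unidirectional rate constants
k_in = 1/τ_in (efflux, also written k_io) and k_ex = 1/τ_ex, tied by
mass balance V_in τ_ex = V_ex τ_in. Both constraints are enforced by
parameterization — `ExchangeParams` stores (R₁ᵢₙ, R₁ₑₓ, τ_in, V_ex)
and derives the rest — so no fitted point can violate them. The coupled
longitudinal relaxation has closed-form eigenvalues (the apparent rates
R₁ˢ ≥ R₁ᴸ) and, for the field-cycling initial condition in which both
pools start equally polarized in proportion to their populations, a
closed-form amplitude fraction a_s. The decay model follows the
standard bi-exponential form with both eigenmodes relaxing toward
equilibrium with the same sign; the eigen-decomposition is verified in
the tests against numpy eigendecomposition and matrix-exponential
oracles to 1e-10 relative.

Identities used as property tests: trace, R₁ᴸ + R₁ˢ = R₁ᵢₙ + R₁ₑₓ +
k_in + k_ex; bracketing, min(R₁ᵢₙ, R₁ₑₓ) ≤ R₁ᴸ ≤ V_in R₁ᵢₙ + V_ex R₁ₑₓ
and R₁ˢ ≥ max(R₁ᵢₙ, R₁ₑₓ); amplitude normalization; and the slow- and
fast-exchange limits.

## Synthetic cohorts

The generator replaces the animal experiment. Four tissue presets carry
the generating physiology:

| preset | class | τ_in (s) | V_ex | R₁ᵢₙ(ν) = a ν^(−b) + c | apparent R₁ at 0.01 MHz (s⁻¹) |
|--------|-------|---------|------|------------------------|-------------------------------|
| U87    | tumor (proliferative) | 0.826 | 0.22 | a = 1.5416, b = 0.50, c = 2.2 | 12.26 |
| Glio6  | tumor (invasive)      | 0.516 | 0.45 | a = 0.9560, b = 0.32, c = 2.2 | 3.76 |
| Glio96 | tumor (invasive)      | 0.596 | 0.40 | a = 1.6463, b = 0.42, c = 2.2 | 6.90 |
| muscle | healthy               | 1.190 | 0.14 | a = 3.6075, b = 0.45, c = 2.6 | 24.36 |

τ_in values and the tumor low-field rates are the published group
values; the rest is package design. The intracellular dispersion is a
power law over a high-field floor — the generic tissue NMRD shape —
with the floor keeping 10 MHz rates at a realistic 2–3 s⁻¹ and making
the three tumor models nearly indistinguishable there, as observed.
Exponents are steeper for the proliferative model so that the fitted
dispersion parameters (A_P, β) order U87 > Glio96 > Glio6. The
extracellular fractions sit inside the class bounds (healthy 0.09–0.19,
tumor 0.15–0.5) with larger values for the invasive models. The
extracellular (Matrigel surrogate) rate is fixed at
R₁ₑₓ(ν) = 0.9 ν^(−0.10) s⁻¹, a weakly dispersive dilute-gel profile;
no published Matrigel values exist, so the preset is its own ground
truth throughout.

Each power-law amplitude `a` is calibrated through the forward model so
that a mono-exponential fit of the noiseless single-tissue curve at
0.01 MHz returns the reference rate (`calibrate_presets` re-derives all
four; the tests assert closure to 0.1%). The muscle reference, 24.36
s⁻¹, is the healthy hind-limb rate implied by the volume-weighted
decomposition of the published U87 pair at tumor fraction 0.6:
(17.10 − 0.6·12.26)/0.4. This closes the preset family under the
mixture equation: the U87 whole-leg composite at f_tum = 0.6 generates
exactly the published whole-volume rate.

Animal-to-animal variability is lognormal and mean-preserving with 5%
CV on τ_in and on the rate amplitude; noise is additive Gaussian on
M_z with σ equal to 1–2% of the polarized amplitude, consistent with
the instrument's stated few-percent rate reproducibility (Gaussian, not
Rician: the detected signals are high-SNR averages). Identical seeds
reproduce datasets exactly.

### Whole-leg mixtures: signal-level vs rate-level

`simulate_whole_leg` offers two mixing models. Signal-level mixing
(default) sums the tumor and muscle magnetization curves — physically
what the coil detects. But the full-curve least-squares mono-fit is
*sub-additive* in the component rates: fitting a signal mixture of a
3.76 s⁻¹ tumor and a 24 s⁻¹ muscle returns far less than the
volume-weighted rate, so the rate-decomposition correction applied to
such curves is biased by tens of percent (a test pins down the bias
direction and magnitude). Rate-level mixing instead generates the
composite as a mono-exponential decay at the volume-weighted apparent
rate — the generator exactly matched to the rate-decomposition analysis
model, and therefore the one used in recovery studies of that analysis.
The discrepancy between the two is a real property of mixture
relaxometry, not an implementation artifact; published whole-volume and
tumor rates are mutually consistent because the tumor rate is *defined*
through the decomposition.

## Fitting

All fits are Levenberg–Marquardt (lmfit's `leastsq`, box constraints by
internal parameter transformation) from deterministic multi-start
grids; no random restarts. Convergence: step tolerance 1e-12, residual
tolerance 1e-14, at most 20000 function evaluations; on noiseless data
parameters converge to ~1e-8 relative. Residuals are weighted by the
per-curve noise σ (taken from the data when recorded, otherwise
estimated from late-time mono-fit residuals). Flat or degenerate curves
return flagged failures, never silent numbers.

* Mono-exponential: amplitude·exp(−R₁ t) + offset; the offset absorbs
  the evolution-field equilibrium, so the same model fits PP/S decays
  and NP/S recoveries. Three-point multi-start on the initial rate.
* Bi-exponential: R₁ˢ = R₁ᴸ + δ with δ ≥ 0 enforces the ordering
  structurally; starts span rate ratios {2, 5, 10, 20} and fast-
  fraction {0.1, 0.2, 0.3, 0.5}.
* Model choice: corrected AIC, with ties (ΔAICc < 2) and
  machine-precision mono fits resolved to the simpler model.
* Multi-field 2SX inversion: one global least-squares problem per
  specimen — shared τ_in and V_ex, one free R₁ᵢₙ per field, R₁ₑₓ fixed
  per field to the Matrigel reference, one shared amplitude; τ_in
  multi-start over {0.2, 0.5, 1.0, 2.0} s. V_ex moves inside the
  tissue-class box bounds or is frozen via `fix_v_ex`.

### Identifiability of τ_in, and the fixed-V_ex convention

With V_ex free inside the wide tumor bounds, τ_in is practically
unidentifiable at 1% point noise: the likelihood is nearly flat along
the ridge that preserves the exchange flux V_in/τ_in, because per-field
R₁ᵢₙ and V_ex can compensate a change in τ_in almost exactly. (The
narrow healthy-tissue bounds act as a strong prior, which is why muscle
is least affected.) The estimation convention is therefore two-pass:
τ_in is reported from fits with V_ex fixed at the class value — the
reading of the original fitting procedure that its reported precision
requires — while V_ex group comparisons use the bounds-constrained free
fit, which localizes V_ex well even where τ_in is noisy.

Precision at the study conditions (8 fields × 32 points, 1% noise,
fixed V_ex): the per-specimen τ_in standard error is ≈ 9% for Glio6
(the least bi-exponential preset, its intrinsic rate separation being
smallest relative to its exchange rate), 4–7% for the others, and these
are likelihood-curvature limits, not optimizer artifacts. A ten-animal
cohort mean therefore carries a seed-to-seed sampling spread of ≈ 3–5%,
so recovery checks at the few-percent level are exact in expectation
but can exceed a 5% band for individual seeds.

## NMRD pipeline

Profiles are the across-specimen mean ± SE of per-field mono-fit rates
(specimens must share the field set). Muscle subtraction inverts the
volume-weighted rate decomposition per field with errors propagated in
quadrature and f_tum treated as exact; non-positive subtracted points
are excluded with a warning, never clipped. Regime segmentation
computes local log–log slopes (central differences; one-sided at the
ends), takes the maximal slope magnitude as the gradient response, and
places the transition where the slope magnitude first crosses half that
maximum (linear interpolation in log ν); a profile whose maximal slope
stays below 0.05 carries no usable dispersion. Central differences
smear a sharp plateau/power-law kink across one neighboring point, so
the located transition can sit one grid position below the kink. The
power law is fitted as a weighted linear regression of log R₁ on log ν
over the dispersive points (weights from the profile SEs propagated to
log space), which is exact on noiseless power-law input for any
exponent; nondispersive points are averaged into a plateau level.

## Statistics and converters

Group comparisons are two-sided Welch t-tests of each group against the
reference, starred at p < 0.05/0.01/0.001, uncorrected by default (an
optional Holm step-down is provided). Cross-method lifetime converters
implement the printed formulas τ_in = 1/(fe·AXR) (filter-exchange
imaging) and τ_in = τ_mix/Ve (time-dependent kurtosis imaging) with
domain checks; the published FEXI worked examples are reproduced as
printed, without reconciling their internal arithmetic. IHC area
fraction is 100 × positive∩total / total pixels on binary masks.

## What the synthetic tests do and do not show

Passing recovery tests show that the full chain — generator, forward
model, constrained inversion, mixture correction, dispersion fit —
inverts itself correctly at realistic noise, cohort size and protocol,
and that group differences of the published magnitude are detectable
with the published significance pattern. They do not validate the 2SX
model against real tissue (the generator *is* the 2SX model: no
vascular compartment, no bound-pool exchange, no field-switching
transients, no B₁ inhomogeneity, single global f_tum per composite),
nor the specific preset dispersion shapes, which are calibrated
constructs. Eq-(1)-style mixture correction applied to genuinely
signal-mixed curves carries the documented sub-additivity bias; on real
data that bias is part of the measurement.
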