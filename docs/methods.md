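# Methods

## Scope and model assumptions

The package analyzes ²³Na (and, by changing the nucleus label, ¹H/other)
PFG diffusion NMR data for counterions around charged macromolecules. The
analysis chain rests on four assumptions:

1. **Monoexponential attenuation in g².** The BPP-LED decay follows the
   bipolar-pair Stejskal–Tanner law with b-factor
   γ²g²δ²(Δ − δ/3 − τ/2). Convection, eddy-current and pulse-imperfection
   artifacts are assumed removed by hardware and sequence design (coaxial
   geometry, LED block) and are not modeled.
2. **Two-state fast exchange.** Free and territorially bound ions exchange
   much faster than the measurement timescale, so diffusion and R₂ are
   single population-weighted averages. No intermediate states, no exchange
   broadening term (R_ex) in the R₂ model — the titration data are fit
   without it, and systematic residual structure would be the diagnostic
   that this simplification fails.
3. **Counterion condensation.** The atmosphere holds a fixed number of
   monovalent cations per macromolecule (a, equivalently n_c), independent
   of free-ion concentration. This makes [Na⁺]_total linear in C_M and
   fixes the total atmosphere occupancy T = n_c[DNA] during a KCl
   titration — a modeling assumption, flagged in the pipeline log, not a
   measurement.
4. **Release bookkeeping.** The protein–DNA comparison assumes equal total
   Na⁺ in both samples (same equilibrated stocks) and no Na⁺ atmosphere
   around the positively charged protein (its titration data are flat).

## Parameters, units, defaults

Internal units are SI throughout (m² s⁻¹, T m⁻¹, s, mol L⁻¹); conversion to
the reporting conventions (10⁻⁵ cm² s⁻¹, G cm⁻¹, mM) happens only in I/O.
Key parameters:

| parameter | meaning | default | why |
|---|---|---|---|
| δ | total bipolar-pair gradient length | 2 ms | two 1 ms lobes, the acquisition used for the attenuation bounds; "1 ms gradients" with a pair means δ = 2 ms — the only reading consistent with ≥85% attenuation at 265 G/cm and ≤10% at 55 G/cm |
| Δ | diffusion delay | 20 ms | the reference acquisition |
| τ | intra-echo gradient gap | 0.2 ms | rarely reported; contributes <1% to the effective diffusion time |
| γ(²³Na) | gyromagnetic ratio | 0.2645 × γ(¹H) | derived from the ratio rather than tabulated, keeping the pipeline's convention self-consistent |
| [Na⁺]_buffer | buffer cation concentration | 20 mM | the sodium-succinate buffer of the reference system |
| noise σ | generator relative noise | 1% | consistent with replicate SEMs of ~1–2% on apparent D |
| replicates | per condition | 3 | the standard protocol; SEM over replicates is the reported uncertainty |
| D bounds | fit envelope | (10⁻¹³, 10⁻⁷) m²/s | generous physical range preventing sign flips |

The ion-excess fit defaults to a free intercept with a warning if it
deviates from the buffer concentration by >2 SE (exposing quantification
bias); a fixed-intercept mode reproduces the strict linear model. Whether
the published slope fixed its intercept is not stated, so both are provided.

## Numerical choices

- **Raw-intensity residuals.** Diffusion fits minimize residuals on the
  intensity scale (matching "fitting to signal integral data"); the
  log-linear regression of ln I on b is used only for initialization.
- **Dimensionless optimization.** The one-parameter D_b and Q fits scale
  the observable (and D_b itself) by D_f before optimization: apparent
  diffusion coefficients are ~10⁻⁹ in SI, small enough that
  gradient-based convergence tests would otherwise fire at the starting
  point.
- **Competition root.** The bound-Na⁺ quadratic is solved in the citardauq
  form N_b = 2·Na_total·T/(B + √(B² + 4C·Na_total)), which avoids
  cancellation when B² ≫ 4C·Na_total and is continuous through Q = 1
  (where C = 0 and the expression degenerates smoothly to the
  no-preference linear solution) — no branch switch needed. The root is
  validated against the physical interval [0, min(T, Na_total)] and, in
  tests, against an independent bisection solver of the primitive
  equilibrium over a 1000-point (Q, KCl, T) grid.
- **Line shapes.** Absorption-mode Lorentzians parameterized so that
  R₂ = π·FWHM is read directly off the fit (lmfit's Lorentzian plus a
  constant baseline). Phase errors are not modeled; overlapping
  unresolvable components are flagged when parameter correlations exceed
  0.99. Baseline fitting is on by default, phase is not a parameter.
- **Uncertainties.** Covariance-based SEs by default; optional seeded
  residual bootstrap (1000 resamples by default) for the one-parameter
  fits; first-order propagation for the released-ion count; SEM across
  replicates whenever replicate-level data are supplied.
- **Degenerate inputs.** Fewer than 3 distinct gradients, identical
  titration concentrations, zero reference integrals, D_f = D_D in the
  release equation, and non-positive storage intensities are all explicit
  errors, not NaNs. Non-convergence is flagged on the result, never
  silent.

## What the generators emulate — and what they do not

The synthetic-data module reproduces the statistical structure the analysis
assumes: exact forward models (attenuation in g², population-averaged D and
R₂, competition mass balance, linear total-Na⁺) with relative Gaussian
noise, three replicates per condition, the 25-point 2–265 G/cm gradient
ramp and the eight-point 0.21–1.74 mM titration grid. Generators are pure
functions of (parameters, seed).

They do **not** emulate: time-domain acquisition (spectra are built in the
frequency domain), baseline roll or phase errors, convection or
eddy-current artifacts, radiation damping, concentration-dependent
viscosity, or any failure of the fast-exchange/condensation assumptions.
Passing recovery tests therefore demonstrates that the estimators are
unbiased and correctly implemented *under the model*, not that the model
describes any particular real sample; on real data the soft consistency
checks (forward-model prediction vs direct measurement, Stokes–Einstein
viscosity scaling of the reference line) are the first diagnostics.

## Problem sizes

Monte-Carlo characterization uses 200 seeded replicates per recovery
(8–10-point titrations, one-parameter fits), enough to pin the recovery
mean to a standard error several-fold smaller than the published
uncertainty envelopes it is compared against. The brute-force oracles in
the test suite (grid search over D_b at 10⁻⁴×10⁻⁵ cm² s⁻¹ resolution, R_b
at 0.01 s⁻¹, bisection at rtol 10⁻¹⁴) are deliberately slow, independent
re-solvers of the same problems.

## Known limitations

- Only two exchange states; multi-state or slow-exchange systems are out
  of scope.
- The relaxation-rate analogue of the competition fit is not provided: the
  R₂ titration under added KCl shows systematic deviations from the
  fixed-R_f/R_b model (rates may depend on KCl through local electric
  fields), so the package exposes the diffusion-based Q fit only.
- R_f/R_b are apparent quadrupolar rates; the package makes no attempt to
  interpret them mechanistically (QCC and correlation-time contributions
  are not separable from these data).
- Vendor raw-data directories are not parsed; the readers consume sampled
  decay tables and spectra in delimited text.
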