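# iondiff

Quantitative analysis of ²³Na pulsed-field-gradient (PFG) diffusion NMR data
for counterion–macromolecule interactions: from gradient-series signal decays
to diffusion coefficients, counterion counts, ion-atmosphere mobility,
Na⁺/K⁺ competition quotients, protein-induced counterion release, the entropy
of release, and line-shape-derived relaxation rates.

It is written for NMR spectroscopists and biophysicists who measure the
diffusion of NMR-detectable counterions (²³Na⁺, ¹⁵NH₄⁺, ...) around nucleic
acids and proteins and want a tested, scriptable replacement for ad-hoc
fitting spreadsheets. A seeded synthetic-data generator emulates every input
the pipeline reads, so the entire analysis is testable without a
spectrometer.

## The models

**Signal attenuation.** In a BPP-LED (bipolar pulsed-gradient pair,
longitudinal eddy-current delay) experiment the signal decays with gradient
strength *g* as

    I(g) = I₀ exp(−D γ² g² δ² (Δ − δ/3 − τ/2))

where δ is the total length of a pair of bipolar gradients, Δ the diffusion
delay, τ the gap between the two gradients of each spin echo, and γ the
gyromagnetic ratio (γ(²³Na) = 0.2645 γ(¹H)). Nonlinear least squares on
(g, I) yields the diffusion coefficient *D*.

**Two-state fast exchange.** Free ions (D_f) and ions territorially bound in
the ion atmosphere (D_b) exchange rapidly, so one population-averaged
coefficient is observed:

    D_app = p_f D_f + p_b D_b,   p_b = a·C_M / ([Na⁺]_buffer + a·C_M)

with *a* ions per macromolecule (measured from signal-integral ratios via
[Na⁺]_total = [Na⁺]_buffer + a·C_M). D_b is the single fitted parameter.
The same population average applied to transverse relaxation, R₂,app =
p_f R_f + p_b R_b, gives the bound-state relaxation rate from Lorentzian
line widths (FWHM = R₂/π).

**Ionic competition.** With an added competitor cation (K⁺) the atmosphere's
fixed capacity T = n_c[DNA] is shared according to a preference quotient
Q = [Na⁺_b][K⁺_f]/([Na⁺_f][K⁺_b]); the bound Na⁺ concentration is the
physical root of (C/T)N_b² + B N_b − [Na⁺]_total·T = 0 with
C = T(Q⁻¹ − 1), B = [Na⁺]_total + Q⁻¹[KCl] − C.

**Counterion release and entropy.** Comparing protein–DNA and DNA-only
samples, the ions released per complex are
n_R = n_c(D_PD − D_D)/((D_f − D_D)·p_complex), and the per-ion entropy of
release follows the Seki–Bagchi relation ΔS = −k_B ln(D_b/D_f).

## Worked example

```python
import numpy as np
from iondiff import (ExchangeParameters, NoiseModel, ReleaseInputs,
                     entropy_of_release, fit_Db, released_ions)
from iondiff.simulate import gen_dna_titration

# simulate an 8-point DNA titration under the reference conditions
truth = ExchangeParameters(D_f=1.251e-9, D_b=0.71e-9, a=25.5, Na_buffer=0.020)
ts = gen_dna_titration(truth, NoiseModel(sigma=0.01, seed=4))

fit = fit_Db(ts.x, ts.y, D_f=1.251e-9, a=25.5, Na_buffer=0.020)
print(f"D_b = {fit.estimate/1e-9:.3f} +/- {fit.se/1e-9:.3f} x1e-5 cm2/s")

ent = entropy_of_release(fit.estimate, 1.251e-9)
print(f"D_b/D_f = {ent.ratio:.2f}; dS_release = {ent.dS_per_ion_eu:.2f} eu/ion")

n_R, se = released_ions(ReleaseInputs(D_PD=1.036, D_D=0.883, D_f=1.251,
                                      n_c=25.5, p_complex=1.10/1.52,
                                      se_D_PD=0.012, se_D_D=0.014))
print(f"n_R = {n_R:.1f} +/- {se:.1f} ions released per complex")
```

prints

```
D_b = 0.710 +/- 0.005 x1e-5 cm2/s
D_b/D_f = 0.57; dS_release = 1.13 eu/ion
n_R = 14.6 +/- 1.4 ions released per complex
```

D_b ≈ 0.71×10⁻⁵ cm² s⁻¹ says bound Na⁺ keeps ~57% of its free mobility —
ions in the atmosphere remain highly mobile. The release entropy (~1.1
cal mol⁻¹ K⁻¹ per ion) is correspondingly modest, and ~15 Na⁺ ions leave the
DNA when one protein binds.

The same analyses are available from the shell:

```sh
iondiff simulate --kind titration --out titration.csv --sigma 0.01 --seed 4
iondiff fit-exchange titration.csv --d-f 1.251 --a 25.5
iondiff release --d-pd 1.036 --d-d 0.883 --d-f 1.251 --nc 25.5 \
        --p-total 1.10 --dna-total 1.52
iondiff run --config pipeline.yaml     # multi-stage analysis from a config
```

Every fitter is also exposed as a scikit-learn estimator
(`DiffusionDecayFit`, `IonExcessFit`, `BoundDiffusionFit`, `CompetitionFit`,
`BoundRelaxationFit`) with `fit`/`predict`, `get_params`/`set_params`, and
trailing-underscore fitted attributes, so they compose with sklearn
pipelines and model selection.

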