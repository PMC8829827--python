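"""Seeded synthetic-data generators emulating every input the pipeline reads.

Each generator applies the corresponding forward model exactly and then
multiplicative (relative) or additive Gaussian noise, replicated per
condition.  Defaults reflect the measurement protocol the analysis assumes:
25 gradient strengths spanning 2-265 G/cm, eight DNA-duplex concentrations
between 0.21 and 1.74 mM, 20 mM buffer Na+, three replicates per condition,
and 1% relative noise (comparable to the ~1.6% SEs typical of replicated
diffusion measurements).

Every generator is a pure function of its parameters and the seed: the same
inputs give bit-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .competition import CompetitionSystem, apparent_D_competition
from .constants import gradient_G_per_cm_to_T_per_m
from .decay import GradientDecaySeries, PulseParams, attenuation
from .exchange import ExchangeParameters, apparent_D
from .lineshape import LorentzianComponent, R2ExchangeParameters, Spectrum1D, r2_apparent_model
from .results import TitrationSeries

#: the eight DNA-duplex concentrations of the reference titration, mol/L
DEFAULT_DNA_CONCENTRATIONS = np.array(
    [0.21, 0.47, 0.66, 0.88, 1.09, 1.44, 1.52, 1.74]) * 1e-3

#: default gradient ramp: 25 strengths from 2 to 265 G/cm, in T/m
DEFAULT_GRADIENTS = gradient_G_per_cm_to_T_per_m(np.linspace(2.0, 265.0, 25))


@dataclass(frozen=True)
class NoiseModel:
    """Gaussian noise specification for the generators.

    kind : "relative-gaussian" multiplies each value by (1 + eps);
           "absolute-gaussian" adds eps in the observable's own units.
    """

    kind: str = "relative-gaussian"
    sigma: float = 0.01
    seed: int = 0
    n_replicates: int = 3

    def __post_init__(self) -> None:
        if self.kind not in ("relative-gaussian", "absolute-gaussian"):
            raise ValueError("kind must be 'relative-gaussian' or 'absolute-gaussian'")
        if self.sigma < 0:
            raise ValueError("sigma must be non-negative")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)

    def apply(self, values: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        values = np.asarray(values, dtype=float)
        if self.sigma == 0:
            return values.copy()
        eps = rng.normal(0.0, self.sigma, size=values.shape)
        if self.kind == "relative-gaussian":
            return values * (1.0 + eps)
        return values + eps


def gen_decay_series(D: float, params: PulseParams, noise: NoiseModel,
                     gradients=None, I0: float = 1.0) -> list[GradientDecaySeries]:
    """Gradient-ramp decays I = I0 exp(-D b(g)) x noise, one series per replicate."""
    g = np.asarray(DEFAULT_GRADIENTS if gradients is None else gradients,
                   dtype=float)
    clean = I0 * np.asarray(attenuation(D, params, g), dtype=float)
    rng = noise.rng()
    return [GradientDecaySeries(g, noise.apply(clean, rng), params, replicate=i)
            for i in range(noise.n_replicates)]


def _titration(x, clean, noise: NoiseModel, x_name, y_name) -> TitrationSeries:
    """Replicate, perturb, and reduce to mean +/- SEM per condition."""
    rng = noise.rng()
    reps = np.stack([noise.apply(clean, rng) for _ in range(noise.n_replicates)])
    mean = reps.mean(axis=0)
    if noise.n_replicates > 1:
        se = reps.std(axis=0, ddof=1) / np.sqrt(noise.n_replicates)
    else:
        se = np.zeros_like(mean)
    return TitrationSeries(x=x, y=mean, se=se, x_name=x_name, y_name=y_name)


def gen_dna_titration(params: ExchangeParameters, noise: NoiseModel,
                      concentrations=None) -> TitrationSeries:
    """Apparent-D vs macromolecule concentration from the two-state model."""
    C = np.asarray(DEFAULT_DNA_CONCENTRATIONS if concentrations is None
                   else concentrations, dtype=float)
    clean = np.asarray(apparent_D(params, C), dtype=float)
    return _titration(C, clean, noise, "C_M", "D_app")


def gen_competition_series(template: CompetitionSystem, noise: NoiseModel,
                           KCl_grid=None) -> TitrationSeries:
    """Apparent-D vs added KCl from the competition mass balance."""
    K = (np.linspace(0.0, 0.150, 10) if KCl_grid is None
         else np.asarray(KCl_grid, dtype=float))
    clean = np.array([
        apparent_D_competition(CompetitionSystem(
            template.Na_total, k, template.T_capacity, template.Q,
            template.D_f, template.D_b))
        for k in K])
    return _titration(K, clean, noise, "KCl", "D_app")


def gen_quant_series(a: float, intercept: float, noise: NoiseModel,
                     C_M_grid=None) -> TitrationSeries:
    """Total-Na+ vs macromolecule concentration: intercept + a * C_M."""
    C = np.asarray(DEFAULT_DNA_CONCENTRATIONS if C_M_grid is None
                   else C_M_grid, dtype=float)
    clean = intercept + a * C
    return _titration(C, clean, noise, "C_M", "Na_total")


def gen_r2_titration(params: R2ExchangeParameters, noise: NoiseModel,
                     C_M_grid=None) -> TitrationSeries:
    """Apparent-R2 vs macromolecule concentration from the two-state model."""
    C = np.asarray(DEFAULT_DNA_CONCENTRATIONS if C_M_grid is None
                   else C_M_grid, dtype=float)
    clean = np.asarray(r2_apparent_model(params, C), dtype=float)
    return _titration(C, clean, noise, "C_M", "R2_app")


def gen_spectrum(components: list[LorentzianComponent], noise: NoiseModel,
                 freq_grid=None) -> Spectrum1D:
    """Frequency-domain spectrum: sum of absorption Lorentzians plus noise.

    Noise is additive relative to the tallest peak when the model is
    relative-gaussian (a spectrum baseline has no per-point "true value" to
    scale by), matching how spectral noise floors behave.
    """
    if freq_grid is None:
        centers = [c.center for c in components]
        widths = [c.fwhm for c in components]
        lo = min(centers) - 20 * max(widths)
        hi = max(centers) + 20 * max(widths)
        freq_grid = np.linspace(lo, hi, 1024)
    f = np.asarray(freq_grid, dtype=float)
    clean = sum(c.evaluate(f) for c in components) + components[0].baseline
    rng = noise.rng()
    if noise.sigma == 0:
        y = clean.copy()
    else:
        scale = noise.sigma * (np.max(clean) if noise.kind == "relative-gaussian" else 1.0)
        y = clean + rng.normal(0.0, scale, size=f.shape)
    return Spectrum1D(freq=f, intensity=y)
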