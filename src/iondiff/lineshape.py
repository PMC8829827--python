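"""Lorentzian line-shape fitting for apparent R2, and the two-state R_b fit.

In the fast-exchange regime the observed 23Na resonance is a single
absorption-mode Lorentzian whose full width at half maximum encodes the
apparent transverse relaxation rate, FWHM = R2 / pi.  Fitting spectra at a
series of macromolecule concentrations and applying the same two-state
population average used for diffusion,

    R_2,app = p_f R_f + p_b R_b

(with no exchange-contribution term R_ex), yields the bound-state rate R_b
as the single fitted parameter.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from lmfit.models import ConstantModel, LorentzianModel
from scipy.optimize import curve_fit
from sklearn.base import BaseEstimator, RegressorMixin

from .decay import _as_1d
from .exchange import ExchangeParameters, p_bound
from .results import FitResult, residual_bootstrap


@dataclass
class Spectrum1D:
    """Sampled 1D spectrum: frequency axis (Hz) and real intensities."""

    freq: np.ndarray
    intensity: np.ndarray

    def __post_init__(self) -> None:
        self.freq = np.asarray(self.freq, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.freq.shape != self.intensity.shape or self.freq.ndim != 1:
            raise ValueError("freq and intensity must be 1-D and equal length")
        if self.freq.size < 16:
            raise ValueError("need at least 16 spectral points")
        d = np.diff(self.freq)
        if not (np.all(d > 0) or np.all(d < 0)):
            raise ValueError("freq must be strictly monotone")


@dataclass(frozen=True)
class LorentzianComponent:
    """One absorption Lorentzian: FWHM = R2/pi, peak height 2A/(pi FWHM)."""

    center: float     # Hz
    R2: float         # s^-1
    amplitude: float  # integrated area
    baseline: float = 0.0

    def __post_init__(self) -> None:
        if not self.R2 > 0:
            raise ValueError("R2 must be positive")

    @property
    def fwhm(self) -> float:
        return self.R2 / np.pi

    def evaluate(self, freq) -> np.ndarray:
        f = np.asarray(freq, dtype=float)
        hwhm = 0.5 * self.fwhm
        return (self.amplitude / np.pi) * hwhm / ((f - self.center) ** 2 + hwhm ** 2)


def fit_lorentzians(spec: Spectrum1D, n_components: int = 1,
                    init_centers=None,
                    fit_baseline: bool = True) -> list[LorentzianComponent]:
    """Least-squares fit of a sum of absorption Lorentzians plus a baseline.

    ``init_centers`` must lie inside the spectral window; when omitted for a
    single component the peak position is used.  Components whose fitted
    parameters are correlated above 0.99 (unresolvable overlap) trigger a
    warning.
    """
    if n_components < 1:
        raise ValueError("n_components must be >= 1")
    f, y = spec.freq, spec.intensity
    lo, hi = float(np.min(f)), float(np.max(f))
    if init_centers is None:
        if n_components == 1:
            init_centers = [float(f[np.argmax(y)])]
        else:
            raise ValueError("init_centers required for multiple components")
    init_centers = [float(c) for c in init_centers]
    if len(init_centers) != n_components:
        raise ValueError("need one initial center per component")
    for c in init_centers:
        if not lo <= c <= hi:
            raise ValueError(f"initial center {c} outside spectral window")

    model = ConstantModel(prefix="bl_") if fit_baseline else None
    params = None
    span = hi - lo
    for i, c in enumerate(init_centers):
        comp = LorentzianModel(prefix=f"p{i}_")
        model = comp if model is None else model + comp
    params = model.make_params()
    if fit_baseline:
        params["bl_c"].set(value=float(np.median(y)))
    for i, c in enumerate(init_centers):
        idx = int(np.argmin(np.abs(f - c)))
        height = max(float(y[idx] - (np.median(y) if fit_baseline else 0.0)), 1e-12)
        sigma0 = max(span / 50.0, 1e-6)  # HWHM guess
        params[f"p{i}_center"].set(value=c, min=lo, max=hi)
        params[f"p{i}_sigma"].set(value=sigma0, min=1e-9)
        params[f"p{i}_amplitude"].set(value=height * np.pi * sigma0, min=0)
    out = model.fit(y, params, x=f)

    # flag unresolvable overlap through parameter correlations
    for name, par in out.params.items():
        if par.correl:
            for other, rho in par.correl.items():
                if name < other and abs(rho) > 0.99:
                    warnings.warn(
                        f"parameters {name} and {other} are correlated "
                        f"above 0.99: components may be unresolvable",
                        RuntimeWarning)

    baseline = float(out.params["bl_c"].value) if fit_baseline else 0.0
    comps = []
    for i in range(n_components):
        sigma = float(out.params[f"p{i}_sigma"].value)   # HWHM
        comps.append(LorentzianComponent(
            center=float(out.params[f"p{i}_center"].value),
            R2=np.pi * 2.0 * sigma,                      # pi * FWHM
            amplitude=float(out.params[f"p{i}_amplitude"].value),
            baseline=baseline))
    comps.sort(key=lambda c: c.center)
    return comps


@dataclass(frozen=True)
class R2ExchangeParameters:
    """Two-state R2 model state (s^-1, ions, mol/L)."""

    R_f: float
    R_b: float
    a: float
    Na_buffer: float

    def __post_init__(self) -> None:
        if not self.R_f > 0:
            raise ValueError("R_f must be positive")
        if self.R_b < self.R_f:
            warnings.warn(
                "R_b < R_f is unexpected for macromolecule-bound quadrupolar "
                "nuclei", UserWarning)


def r2_apparent_model(params: R2ExchangeParameters, C_M) -> np.ndarray | float:
    """Population-weighted apparent R2: p_f R_f + p_b R_b (no R_ex term)."""
    # reuse the diffusion-model population with dummy diffusion coefficients
    ex = ExchangeParameters(1.0, 1.0, params.a, params.Na_buffer)
    pb = np.asarray(p_bound(ex, C_M), dtype=float)
    out = (1.0 - pb) * params.R_f + pb * params.R_b
    return out if out.ndim else float(out)


class BoundRelaxationFit(RegressorMixin, BaseEstimator):
    """One-parameter fit of the ion-atmosphere relaxation rate R_b.

    R_f (measured on buffer alone), the ion count ``a`` and the buffer
    concentration are fixed; R_b is optimized against (C_M, R_2,app) data.
    """

    def __init__(self, R_f: float = None, a: float = None,
                 Na_buffer: float = None, weighted: bool = False,
                 n_boot: int = 0, seed: int = 0):
        self.R_f = R_f
        self.a = a
        self.Na_buffer = Na_buffer
        self.weighted = weighted
        self.n_boot = n_boot
        self.seed = seed

    def _model(self, C, R_b):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", UserWarning)
            p = R2ExchangeParameters(self.R_f, R_b, self.a, self.Na_buffer)
        return np.asarray(r2_apparent_model(p, C), dtype=float)

    def fit(self, X, y, sigma=None):
        for name in ("R_f", "a", "Na_buffer"):
            if getattr(self, name) is None:
                raise ValueError(f"{name} must be provided (measured upstream)")
        C = _as_1d(X)
        R = np.asarray(y, dtype=float)
        if C.size < 2:
            raise ValueError("need at least 2 points")
        use_sigma = sigma if self.weighted else None
        converged = True
        try:
            popt, pcov = curve_fit(
                self._model, C, R, p0=[2.0 * self.R_f],
                sigma=use_sigma, absolute_sigma=use_sigma is not None,
                bounds=([0.0], [np.inf]), maxfev=10000)
        except RuntimeError:
            converged = False
            popt, pcov = np.array([2.0 * self.R_f]), np.array([[np.nan]])
            warnings.warn("R_b fit did not converge", RuntimeWarning)
        self.R_b_ = float(popt[0])
        self.se_R_b_ = float(np.sqrt(pcov[0, 0]))
        self.residuals_ = R - self._model(C, self.R_b_)
        self.converged_ = converged
        self.n_points_ = C.size
        if self.n_boot:
            rng = np.random.default_rng(self.seed)
            self.se_R_b_bootstrap_ = residual_bootstrap(
                lambda x: self._model(x, self.R_b_),
                lambda x, yy: curve_fit(self._model, x, yy, p0=[self.R_b_],
                                        bounds=([0.0], [np.inf]),
                                        maxfev=10000)[0][0],
                C, R, self.n_boot, rng)
        return self

    def predict(self, X):
        return self._model(_as_1d(X), self.R_b_)

    def result_(self) -> FitResult:
        return FitResult(
            estimate=self.R_b_, se=self.se_R_b_, residuals=self.residuals_,
            converged=self.converged_, n_points=self.n_points_,
            method="one-parameter nonlinear least-squares (R_b)",
            se_bootstrap=getattr(self, "se_R_b_bootstrap_", None),
        )


def fit_Rb(C_M, R2_app, R_f: float, a: float, Na_buffer: float,
           sigma=None, weighted: bool = False,
           n_boot: int = 0, seed: int = 0) -> FitResult:
    """Fit R_b to an R_2,app titration; see :class:`BoundRelaxationFit`."""
    est = BoundRelaxationFit(R_f=R_f, a=a, Na_buffer=Na_buffer,
                             weighted=weighted, n_boot=n_boot, seed=seed)
    est.fit(C_M, R2_app, sigma=sigma)
    return est.result_()
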