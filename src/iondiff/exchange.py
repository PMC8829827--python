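"""Two-state fast-exchange diffusion model and counterion-release entropy.

Na+ ions exchange between the free state (diffusion coefficient D_f) and the
territorially bound state inside the ion atmosphere (D_b) much faster than
the measurement timescale, so a single population-weighted apparent
coefficient is observed::

    D_app = p_f D_f + p_b D_b,    p_b = a C_M / ([Na+]_buffer + a C_M)

with ``a`` ions per macromolecule.  D_f is measured directly on buffer and
``a`` is measured by quantification; D_b is the single fitted parameter.

The per-ion entropy gained on release from the atmosphere follows the
Seki-Bagchi relation between entropy and diffusion,
dS = -k_B ln(D_b / D_f), reported on the molar scale via the gas constant
in cal mol^-1 K^-1 ("eu").
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit
from sklearn.base import BaseEstimator, RegressorMixin

from .constants import R_CAL
from .decay import _as_1d
from .results import FitResult, residual_bootstrap


@dataclass(frozen=True)
class ExchangeParameters:
    """State of the two-state model (SI units: m^2/s, mol/L)."""

    D_f: float
    D_b: float
    a: float
    Na_buffer: float

    def __post_init__(self) -> None:
        if not (0 < self.D_b <= self.D_f):
            raise ValueError("require 0 < D_b <= D_f (bound ions are never faster)")
        if self.a < 0:
            raise ValueError("a must be non-negative")


def p_bound(params: ExchangeParameters, C_M) -> np.ndarray | float:
    """Bound-state population a C_M / (Na_buffer + a C_M), in [0, 1)."""
    C = np.asarray(C_M, dtype=float)
    if np.any(C < 0):
        raise ValueError("C_M must be non-negative")
    denom = params.Na_buffer + params.a * C
    if np.any(denom == 0):
        raise ValueError("Na_buffer + a*C_M must be nonzero")
    out = params.a * C / denom
    return out if out.ndim else float(out)


def apparent_D(params: ExchangeParameters, C_M) -> np.ndarray | float:
    """Population-weighted apparent diffusion coefficient, in [D_b, D_f]."""
    pb = np.asarray(p_bound(params, C_M), dtype=float)
    out = (1.0 - pb) * params.D_f + pb * params.D_b
    return out if out.ndim else float(out)


class BoundDiffusionFit(RegressorMixin, BaseEstimator):
    """One-parameter fit of the ion-atmosphere diffusion coefficient D_b.

    D_f, the ion count ``a`` and the buffer concentration are measured
    upstream and held fixed; D_b is the only optimized parameter, fit by
    nonlinear least squares to (C_M, D_app) titration data.

    Parameters
    ----------
    D_f, a, Na_buffer : float
        Fixed model inputs (m^2/s, ions, mol/L).
    weighted : bool
        Inverse-variance weighting by per-point SEs passed to :meth:`fit`.
    n_boot : int
        Residual-bootstrap resamples for an alternative SE (0 disables).
    seed : int
        Bootstrap seed.

    Attributes
    ----------
    D_b_, se_D_b_ : float
    """

    def __init__(self, D_f: float = None, a: float = None,
                 Na_buffer: float = None, weighted: bool = False,
                 n_boot: int = 0, seed: int = 0):
        self.D_f = D_f
        self.a = a
        self.Na_buffer = Na_buffer
        self.weighted = weighted
        self.n_boot = n_boot
        self.seed = seed

    def _model(self, C, D_b):
        p = ExchangeParameters(self.D_f, min(D_b, self.D_f), self.a, self.Na_buffer)
        return np.asarray(apparent_D(p, C), dtype=float)

    def fit(self, X, y, sigma=None):
        for name in ("D_f", "a", "Na_buffer"):
            if getattr(self, name) is None:
                raise ValueError(f"{name} must be provided (measured upstream)")
        C = _as_1d(X)
        D_app = np.asarray(y, dtype=float)
        if np.unique(C).size < 2:
            raise ValueError("need at least 2 distinct concentrations")
        use_sigma = sigma if self.weighted else None
        lo, hi = 1e-13, self.D_f
        converged = True
        # fit in dimensionless form (observable and parameter scaled by D_f)
        # so the optimizer's relative tolerances see O(1) magnitudes
        scaled = lambda CC, r: self._model(CC, r * self.D_f) / self.D_f
        try:
            popt, pcov = curve_fit(
                scaled, C, D_app / self.D_f, p0=[0.5],
                sigma=None if use_sigma is None else np.asarray(use_sigma) / self.D_f,
                absolute_sigma=use_sigma is not None,
                bounds=([lo / self.D_f], [1.0]), maxfev=10000,
            )
        except RuntimeError:
            converged = False
            popt, pcov = np.array([0.5]), np.array([[np.nan]])
            warnings.warn("D_b fit did not converge", RuntimeWarning)
        self.D_b_ = float(popt[0]) * self.D_f
        self.se_D_b_ = float(np.sqrt(pcov[0, 0])) * self.D_f
        if converged and (self.D_b_ <= lo * 1.01 or self.D_b_ >= hi * 0.9999):
            warnings.warn("fitted D_b is at a bound", RuntimeWarning)
        self.residuals_ = D_app - self._model(C, self.D_b_)
        self.converged_ = converged
        self.n_points_ = C.size
        if self.n_boot:
            rng = np.random.default_rng(self.seed)
            self.se_D_b_bootstrap_ = self.D_f * residual_bootstrap(
                lambda x: scaled(x, self.D_b_ / self.D_f),
                lambda x, yy: curve_fit(scaled, x, yy,
                                        p0=[self.D_b_ / self.D_f],
                                        bounds=([lo / self.D_f], [1.0]),
                                        maxfev=10000)[0][0],
                C, D_app / self.D_f, self.n_boot, rng)
        return self

    def predict(self, X):
        return self._model(_as_1d(X), self.D_b_)

    def result_(self) -> FitResult:
        return FitResult(
            estimate=self.D_b_, se=self.se_D_b_, residuals=self.residuals_,
            converged=self.converged_, n_points=self.n_points_,
            method="one-parameter nonlinear least-squares (D_b)",
            se_bootstrap=getattr(self, "se_D_b_bootstrap_", None),
        )


def fit_Db(C_M, D_app, D_f: float, a: float, Na_buffer: float,
           sigma=None, weighted: bool = False,
           n_boot: int = 0, seed: int = 0) -> FitResult:
    """Fit D_b to a macromolecule titration; see :class:`BoundDiffusionFit`."""
    est = BoundDiffusionFit(D_f=D_f, a=a, Na_buffer=Na_buffer,
                            weighted=weighted, n_boot=n_boot, seed=seed)
    est.fit(C_M, D_app, sigma=sigma)
    return est.result_()


@dataclass(frozen=True)
class EntropyResult:
    """Per-ion entropy of release from the ion atmosphere."""

    ratio: float            # D_b / D_f
    dS_per_ion_kB: float    # multiples of k_B
    dS_per_ion_eu: float    # cal mol^-1 K^-1


def entropy_of_release(D_b: float, D_f: float) -> EntropyResult:
    """Seki-Bagchi entropy estimate -k_B ln(D_b/D_f), also on the molar scale."""
    if not (D_b > 0 and D_f > 0):
        raise ValueError("diffusion coefficients must be positive")
    ratio = D_b / D_f
    dS_kB = -float(np.log(ratio))
    return EntropyResult(ratio=float(ratio), dS_per_ion_kB=dS_kB,
                         dS_per_ion_eu=R_CAL * dS_kB)
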