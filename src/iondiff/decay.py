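"""Pulsed-field-gradient signal attenuation and diffusion-coefficient fitting.

The attenuation model is the bipolar-pair Stejskal-Tanner law for a BPP-LED
experiment::

    I(g) = I0 * exp(-D * gamma^2 g^2 delta^2 (Delta - delta/3 - tau/2))

where ``delta`` is the total length of a pair of bipolar gradients, ``Delta``
the time between the beginning points of the two spin-echo periods, and
``tau`` the time between the two gradients within each spin echo.  The
coefficient multiplying D is the b-factor.  Fitting I vs g yields the
translational diffusion coefficient D; because b scales with gamma^2, a
low-gamma nucleus such as 23Na needs roughly (1/0.2645)^2 ~ 14x stronger
gradients than 1H for the same attenuation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit
from sklearn.base import BaseEstimator, RegressorMixin

from .constants import gamma_for
from .results import FitResult

#: default tau (s) when an acquisition record does not state it; its
#: contribution to the effective diffusion time is below 1% at typical Delta
DEFAULT_TAU = 0.2e-3

# generous physical bounds preventing sign flips during optimisation
_D_BOUNDS = (1e-13, 1e-7)


@dataclass(frozen=True)
class PulseParams:
    """BPP-LED acquisition timing.

    delta : total length of a pair of bipolar gradients, s (two lobes; a
        "1 ms" single gradient lobe means delta = 2 ms)
    Delta : time between the beginning points of the two spin echoes, s
    tau   : time between the two gradients within each spin echo, s
    T_L   : longitudinal storage (eddy-current settling) delay, s
    """

    delta: float
    Delta: float
    tau: float = DEFAULT_TAU
    T_L: float = 0.0
    nucleus: str = "23Na"

    def __post_init__(self) -> None:
        if not self.delta > 0:
            raise ValueError("delta must be positive")
        if self.tau < 0 or self.T_L < 0:
            raise ValueError("tau and T_L must be non-negative")
        if self.effective_diffusion_time <= 0:
            raise ValueError(
                "Delta - delta/3 - tau/2 must be positive "
                "(non-positive effective diffusion time)"
            )
        gamma_for(self.nucleus)  # validate the label early

    @property
    def effective_diffusion_time(self) -> float:
        return self.Delta - self.delta / 3.0 - self.tau / 2.0


@dataclass
class GradientDecaySeries:
    """One diffusion measurement: signal integrals over a gradient ramp."""

    g: np.ndarray  # T m^-1
    I: np.ndarray  # signal integrals, arbitrary units
    params: PulseParams
    replicate: int = 0
    sigma_I: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.g = np.asarray(self.g, dtype=float)
        self.I = np.asarray(self.I, dtype=float)
        if self.g.shape != self.I.shape or self.g.ndim != 1:
            raise ValueError("g and I must be 1-D arrays of equal length")
        if np.any(self.g < 0):
            raise ValueError("gradient strengths must be non-negative")
        if not np.all(np.isfinite(self.I)):
            raise ValueError("signal integrals must be finite")
        if np.unique(self.g).size < 3:
            raise ValueError(
                "need at least 3 distinct gradient strengths for a "
                "2-parameter fit"
            )
        if self.sigma_I is not None:
            self.sigma_I = np.asarray(self.sigma_I, dtype=float)
            if self.sigma_I.shape != self.g.shape:
                raise ValueError("sigma_I must match g in length")


def b_factor(params: PulseParams, g) -> np.ndarray | float:
    """Stejskal-Tanner b-factor gamma^2 g^2 delta^2 (Delta - delta/3 - tau/2), s m^-2."""
    gamma = gamma_for(params.nucleus)
    g = np.asarray(g, dtype=float)
    out = (gamma * g * params.delta) ** 2 * params.effective_diffusion_time
    return out if out.ndim else float(out)


def attenuation(D: float, params: PulseParams, g) -> np.ndarray | float:
    """Fractional remaining signal I/I0 = exp(-D b(g)); 1 at g = 0."""
    if D < 0:
        raise ValueError("D must be non-negative")
    out = np.exp(-D * np.asarray(b_factor(params, g), dtype=float))
    return out if out.ndim else float(out)


class DiffusionDecayFit(RegressorMixin, BaseEstimator):
    """Nonlinear least-squares fit of I = I0 exp(-D b(g)) to a gradient series.

    Parameters
    ----------
    params : PulseParams
        Acquisition timing and nucleus; fixes the b-factor.
    weighting : {"none", "inverse-variance"}
        Residual weighting; inverse-variance requires per-point sigmas
        passed to :meth:`fit`.

    Attributes
    ----------
    D_ : float
        Fitted diffusion coefficient, m^2 s^-1.
    I0_ : float
        Fitted zero-gradient intensity.
    se_D_, se_I0_ : float
        Standard errors from the fit covariance.
    residuals_ : ndarray
        I - I_fit on the raw intensity scale.
    converged_ : bool
    """

    def __init__(self, params: PulseParams | None = None,
                 weighting: str = "none"):
        self.params = params
        self.weighting = weighting

    def fit(self, X, y, sigma=None):
        if self.params is None:
            raise ValueError("params (PulseParams) must be provided")
        if self.weighting not in ("none", "inverse-variance"):
            raise ValueError("weighting must be 'none' or 'inverse-variance'")
        g = _as_1d(X)
        I = np.asarray(y, dtype=float)
        series = GradientDecaySeries(g, I, self.params, sigma_I=sigma)
        b = np.asarray(b_factor(self.params, g), dtype=float)

        # initialize from the log-linear regression ln I = ln I0 - D b
        pos = I > 0
        if pos.sum() >= 2:
            slope, intercept = np.polyfit(b[pos], np.log(I[pos]), 1)
            D0 = float(np.clip(-slope, *_D_BOUNDS))
            I0_0 = float(np.exp(intercept))
        else:  # pathological data; fall back to crude guesses
            D0, I0_0 = 1e-9, float(np.max(np.abs(I)) or 1.0)

        abs_sigma = sigma is not None
        use_sigma = sigma if self.weighting == "inverse-variance" else None
        converged = True
        try:
            popt, pcov = curve_fit(
                lambda bb, I0, D: I0 * np.exp(-D * bb),
                b, I, p0=[I0_0, D0],
                sigma=use_sigma, absolute_sigma=abs_sigma and use_sigma is not None,
                bounds=([0.0, _D_BOUNDS[0]], [10.0 * np.max(np.abs(I)), _D_BOUNDS[1]]),
                maxfev=10000,
            )
        except RuntimeError:
            converged = False
            popt = np.array([I0_0, D0])
            pcov = np.full((2, 2), np.nan)
            warnings.warn("diffusion fit did not converge", RuntimeWarning)

        self.I0_, self.D_ = float(popt[0]), float(popt[1])
        perr = np.sqrt(np.diag(pcov))
        self.se_I0_, self.se_D_ = float(perr[0]), float(perr[1])
        self.residuals_ = I - self.I0_ * np.exp(-self.D_ * b)
        self.converged_ = converged
        self.n_points_ = int(g.size)
        return self

    def predict(self, X):
        g = _as_1d(X)
        return self.I0_ * np.exp(-self.D_ * np.asarray(b_factor(self.params, g)))

    def result_(self) -> DiffusionFitResult:
        return DiffusionFitResult(
            D=self.D_, I0=self.I0_, se_D=self.se_D_,
            residuals=self.residuals_, converged=self.converged_,
            n_points=self.n_points_,
        )


@dataclass
class DiffusionFitResult:
    D: float
    I0: float
    se_D: float
    residuals: np.ndarray
    converged: bool
    n_points: int

    def __post_init__(self) -> None:
        if self.converged and not self.D > 0:
            raise ValueError("fitted D must be positive")


def fit_diffusion(series: GradientDecaySeries,
                  weighting: str = "none") -> DiffusionFitResult:
    """Fit (I0, D) to one gradient decay series; see :class:`DiffusionDecayFit`."""
    est = DiffusionDecayFit(series.params, weighting=weighting)
    est.fit(series.g, series.I, sigma=series.sigma_I)
    return est.result_()


def fit_replicates(series_list: list[GradientDecaySeries],
                   weighting: str = "none") -> tuple[float, float, list[DiffusionFitResult]]:
    """Fit each replicate independently; return (mean D, SEM, per-fit results).

    Mirrors the convention of measuring each decay three times and reporting
    the standard error of the mean across replicates.
    """
    fits = [fit_diffusion(s, weighting) for s in series_list]
    ds = np.array([f.D for f in fits])
    sem = float(np.std(ds, ddof=1) / np.sqrt(ds.size)) if ds.size > 1 else float("nan")
    return float(np.mean(ds)), sem, fits


def calibrate_gradient(series: GradientDecaySeries,
                       D_reference: float) -> float:
    """Gradient-scale factor from a measurement on a diffusion standard.

    Fitting the standard's decay with *nominal* gradient values yields an
    apparent D; since b scales with g^2, the true gradient is
    ``s * g_nominal`` with ``s = sqrt(D_apparent / D_reference)``.
    """
    if not D_reference > 0:
        raise ValueError("D_reference must be positive")
    fit = fit_diffusion(series)
    return float(np.sqrt(fit.D / D_reference))


def fit_storage_decay(T_L_values, I) -> FitResult:
    """Monoexponential fit I = I0 exp(-rate * T_L) of a storage-delay series.

    Returns the longitudinal decay rate (s^-1) governing how quickly the
    stored signal relaxes away during the LED delay.
    """
    t = np.asarray(T_L_values, dtype=float)
    I = np.asarray(I, dtype=float)
    if t.size < 3:
        raise ValueError("need at least 3 points")
    if np.any(I <= 0):
        raise ValueError("intensities must be positive")
    slope, intercept = np.polyfit(t, np.log(I), 1)
    rate0, I0_0 = max(-slope, 0.0), float(np.exp(intercept))
    popt, pcov = curve_fit(
        lambda tt, I0, k: I0 * np.exp(-k * tt),
        t, I, p0=[I0_0, rate0], bounds=([0, 0], [np.inf, np.inf]),
        maxfev=10000,
    )
    resid = I - popt[0] * np.exp(-popt[1] * t)
    perr = np.sqrt(np.diag(pcov))
    return FitResult(
        estimate={"I0": float(popt[0]), "rate": float(popt[1])},
        se={"I0": float(perr[0]), "rate": float(perr[1])},
        residuals=resid, converged=True, n_points=t.size,
        method="monoexponential least-squares",
    )


def _as_1d(X) -> np.ndarray:
    """Accept either a 1-D array or an sklearn-style (n, 1) column."""
    X = np.asarray(X, dtype=float)
    if X.ndim == 2 and X.shape[1] == 1:
        X = X[:, 0]
    if X.ndim != 1:
        raise ValueError("expected a 1-D array or a single-column 2-D array")
    return X
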