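"""Na+/K+ competition for the ion atmosphere: mass balance and the Q fit.

The atmosphere is assumed to hold a fixed total of monovalent cations,
T = n_c [DNA] (counterion condensation), partitioned between Na+ and the
competitor K+ according to an equilibrium quotient::

    Q = [Na+_b][K+_f] / ([Na+_f][K+_b])

Q < 1 means the atmosphere prefers the competitor.  Combining Q with the
three mass balances (Na_b + Na_f = Na_total; K_b + K_f = K_total;
Na_b + K_b = T) gives a quadratic in the bound sodium N_b::

    (C/T) N_b^2 + B N_b - Na_total T = 0,
    C = T (1/Q - 1),   B = Na_total + K_total/Q - C

whose physical root feeds the fast-exchange prediction
D_app = D_f - (D_f - D_b) N_b / Na_total.  Q is the only fitted parameter;
Na_total, T, D_f and D_b come from the cation-only measurements.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit
from sklearn.base import BaseEstimator, RegressorMixin

from .decay import _as_1d
from .results import FitResult, residual_bootstrap


@dataclass(frozen=True)
class CompetitionSystem:
    """Fixed composition plus the preference quotient (mol/L, m^2/s)."""

    Na_total: float
    K_total: float
    T_capacity: float  # n_c * [DNA]: total monovalent cations in the atmosphere
    Q: float
    D_f: float
    D_b: float

    def __post_init__(self) -> None:
        if not self.Q > 0:
            raise ValueError("Q must be positive")
        if self.T_capacity < 0:
            raise ValueError("T_capacity must be non-negative")
        if not self.T_capacity < self.Na_total + self.K_total:
            raise ValueError(
                "the ion atmosphere cannot hold more cations than exist "
                "(T_capacity must be < Na_total + K_total)")
        if not (0 < self.D_b <= self.D_f):
            raise ValueError("require 0 < D_b <= D_f")


def bound_sodium(system: CompetitionSystem) -> float:
    """Bound Na+ concentration N_b, mol/L: physical root of the mass balance.

    Uses the citardauq form N_b = 2 Na_total T / (B + sqrt(B^2 + 4 C Na_total)),
    which is numerically stable against cancellation and continuous through
    Q = 1 (where the quadratic degenerates to the linear no-preference case).
    """
    Na, K, T, Q = (system.Na_total, system.K_total,
                   system.T_capacity, system.Q)
    if T == 0:
        return 0.0
    C = T * (1.0 / Q - 1.0)
    B = Na + K / Q - C
    disc = B * B + 4.0 * C * Na
    if disc < 0:
        raise ValueError("no real root: inconsistent competition inputs")
    denom = B + np.sqrt(disc)
    if denom <= 0:
        raise ValueError("no physical root: inconsistent competition inputs")
    N_b = 2.0 * Na * T / denom
    hi = min(T, Na)
    if not (-1e-9 * max(hi, 1.0) <= N_b <= hi * (1.0 + 1e-9)):
        raise ValueError("root outside the physical interval [0, min(T, Na_total)]")
    return float(min(max(N_b, 0.0), hi))


def apparent_D_competition(system: CompetitionSystem) -> float:
    """Apparent Na+ diffusion coefficient in the presence of the competitor."""
    N_b = bound_sodium(system)
    return system.D_f - (system.D_f - system.D_b) * N_b / system.Na_total


class CompetitionFit(RegressorMixin, BaseEstimator):
    """One-parameter fit of the preference quotient Q to a KCl titration.

    Na_total, the atmosphere capacity T = n_c [DNA], D_f and D_b are fixed
    at their values from the single-cation experiments; Q alone is optimized
    against (K_total, D_app) data.

    Attributes
    ----------
    Q_, se_Q_ : float
    """

    _Q_BOUNDS = (1e-4, 1e4)

    def __init__(self, Na_total: float = None, T_capacity: float = None,
                 D_f: float = None, D_b: float = None,
                 weighted: bool = False, n_boot: int = 0, seed: int = 0):
        self.Na_total = Na_total
        self.T_capacity = T_capacity
        self.D_f = D_f
        self.D_b = D_b
        self.weighted = weighted
        self.n_boot = n_boot
        self.seed = seed

    def _model(self, K, Q):
        K = np.atleast_1d(np.asarray(K, dtype=float))
        return np.array([
            apparent_D_competition(CompetitionSystem(
                self.Na_total, k, self.T_capacity, Q, self.D_f, self.D_b))
            for k in K])

    def fit(self, X, y, sigma=None):
        for name in ("Na_total", "T_capacity", "D_f", "D_b"):
            if getattr(self, name) is None:
                raise ValueError(f"{name} must be provided (measured upstream)")
        K = _as_1d(X)
        D_app = np.asarray(y, dtype=float)
        if K.size < 2:
            raise ValueError("need at least 2 KCl points")
        use_sigma = sigma if self.weighted else None
        lo, hi = self._Q_BOUNDS
        converged = True
        # scale the observable by D_f so the optimizer's relative
        # tolerances see O(1) magnitudes (D_app is ~1e-9 in SI)
        scaled = lambda KK, Q: self._model(KK, Q) / self.D_f
        try:
            popt, pcov = curve_fit(
                scaled, K, D_app / self.D_f, p0=[1.0],
                sigma=None if use_sigma is None else np.asarray(use_sigma) / self.D_f,
                absolute_sigma=use_sigma is not None,
                bounds=([lo], [hi]), maxfev=10000)
        except RuntimeError:
            converged = False
            popt, pcov = np.array([1.0]), np.array([[np.nan]])
            warnings.warn("Q fit did not converge", RuntimeWarning)
        self.Q_ = float(popt[0])
        self.se_Q_ = float(np.sqrt(pcov[0, 0]))
        if converged and (self.Q_ <= lo * 1.01 or self.Q_ >= hi * 0.99):
            warnings.warn("fitted Q is at a bound", RuntimeWarning)
        self.residuals_ = D_app - self._model(K, self.Q_)
        self.converged_ = converged
        self.n_points_ = K.size
        if self.n_boot:
            rng = np.random.default_rng(self.seed)
            self.se_Q_bootstrap_ = residual_bootstrap(
                lambda x: scaled(x, self.Q_),
                lambda x, yy: curve_fit(scaled, x, yy, p0=[self.Q_],
                                        bounds=([lo], [hi]), maxfev=10000)[0][0],
                K, D_app / self.D_f, self.n_boot, rng)
        return self

    def predict(self, X):
        return self._model(_as_1d(X), self.Q_)

    def result_(self) -> FitResult:
        return FitResult(
            estimate=self.Q_, se=self.se_Q_, residuals=self.residuals_,
            converged=self.converged_, n_points=self.n_points_,
            method="one-parameter nonlinear least-squares (Q)",
            se_bootstrap=getattr(self, "se_Q_bootstrap_", None),
        )


def fit_Q(K_total, D_app, Na_total: float, T_capacity: float,
          D_f: float, D_b: float, sigma=None, weighted: bool = False,
          n_boot: int = 0, seed: int = 0) -> FitResult:
    """Fit the competition quotient Q; see :class:`CompetitionFit`."""
    est = CompetitionFit(Na_total=Na_total, T_capacity=T_capacity,
                         D_f=D_f, D_b=D_b, weighted=weighted,
                         n_boot=n_boot, seed=seed)
    est.fit(K_total, D_app, sigma=sigma)
    return est.result_()
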