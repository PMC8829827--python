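"""Shared fit-result container and resampling helpers."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class FitResult:
    """Outcome of a least-squares fit.

    ``estimate``/``se`` hold the primary parameter(s); scalar for
    one-parameter fits, dict for multi-parameter ones.  ``se_bootstrap`` is
    populated only when a residual bootstrap was requested.
    """

    estimate: float | dict[str, float]
    se: float | dict[str, float]
    residuals: np.ndarray
    converged: bool
    n_points: int
    method: str = "least-squares"
    se_bootstrap: float | None = None
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.residuals = np.asarray(self.residuals, dtype=float)
        if self.residuals.size != self.n_points:
            raise ValueError("residuals length must equal n_points")


@dataclass
class TitrationSeries:
    """(control variable, observable, SE) triples from a titration.

    ``x`` is a macromolecule or competitor-salt concentration (mol/L);
    ``y`` an apparent diffusion coefficient (m^2/s) or relaxation rate
    (s^-1); ``se`` the per-point standard error (may be zero).
    """

    x: np.ndarray
    y: np.ndarray
    se: np.ndarray | None = None
    x_name: str = "C_M"
    y_name: str = "D_app"

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if self.x.shape != self.y.shape or self.x.ndim != 1:
            raise ValueError("x and y must be 1-D arrays of equal length")
        if self.se is not None:
            self.se = np.asarray(self.se, dtype=float)
            if self.se.shape != self.x.shape:
                raise ValueError("se must match x in length")


def residual_bootstrap(
    predict,
    refit,
    x: np.ndarray,
    y: np.ndarray,
    n_boot: int,
    rng: np.random.Generator,
) -> float:
    """Residual-bootstrap standard error of a scalar fitted parameter.

    ``predict(x)`` evaluates the fitted model; ``refit(x, y*)`` returns the
    scalar parameter fitted to a resampled data set.  Residuals are resampled
    with replacement and added back onto the fitted curve.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    yhat = predict(x)
    resid = y - yhat
    estimates = np.empty(n_boot)
    for i in range(n_boot):
        y_star = yhat + rng.choice(resid, size=resid.size, replace=True)
        estimates[i] = refit(x, y_star)
    return float(np.std(estimates, ddof=1))
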