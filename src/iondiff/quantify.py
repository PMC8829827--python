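"""Counterion quantification from signal-integral ratios.

A coaxial reference solution provides a constant-concentration 23Na signal;
the ratio r = I_sample / I_ref, normalized by the same ratio for buffer
alone, converts integrals to total Na+ concentrations.  Counterion
condensation predicts the ion atmosphere holds a fixed number ``a`` of
cations per macromolecule independent of the free-ion concentration, so the
total is linear in macromolecule concentration::

    [Na+]_total = [Na+]_buffer + a * C_M

The slope ``a`` is the ion excess (Delta N_cation) when Na+ is the only
cation present.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, RegressorMixin

from .decay import _as_1d

#: buffer Na+ concentration, mol/L (20 mM sodium succinate buffer)
DEFAULT_NA_BUFFER = 0.020


@dataclass(frozen=True)
class IntegralRatioRecord:
    """One quantification measurement (all ratios dimensionless, C in mol/L)."""

    r_sample: float
    r_buffer: float
    C_M: float = 0.0
    Na_buffer: float = DEFAULT_NA_BUFFER

    def __post_init__(self) -> None:
        if not (self.r_sample > 0 and self.r_buffer > 0):
            raise ValueError("integral ratios must be positive")
        if self.C_M < 0:
            raise ValueError("C_M must be non-negative")


def na_total(record: IntegralRatioRecord) -> float:
    """Total Na+ concentration, mol/L: Na_buffer * r_sample / r_buffer."""
    return record.Na_buffer * record.r_sample / record.r_buffer


class IonExcessFit(RegressorMixin, BaseEstimator):
    """Linear fit of [Na+]_total vs macromolecule concentration.

    Parameters
    ----------
    fix_intercept : float or None
        If given (mol/L), a one-parameter regression through that intercept;
        otherwise ordinary least squares with a free intercept.
    Na_buffer : float or None
        When fitting freely, warn if the fitted intercept deviates from this
        buffer concentration by more than 2 standard errors (a systematic
        quantification bias would show up exactly there).

    Attributes
    ----------
    a_ : float
        Ions per macromolecule (the slope; the ion excess for Na+-only
        solutions).
    intercept_, se_a_, se_intercept_ : float
    """

    def __init__(self, fix_intercept: float | None = None,
                 Na_buffer: float | None = None):
        self.fix_intercept = fix_intercept
        self.Na_buffer = Na_buffer

    def fit(self, X, y):
        C = _as_1d(X)
        na = np.asarray(y, dtype=float)
        if C.shape != na.shape:
            raise ValueError("C_M and Na_total must have equal length")
        if np.unique(C).size < (1 if self.fix_intercept is not None else 2):
            raise ValueError("all C_M identical: slope unidentifiable")
        n = C.size
        if self.fix_intercept is not None:
            if n < 1:
                raise ValueError("need at least 1 point")
            yy = na - self.fix_intercept
            sxx = float(np.dot(C, C))
            a = float(np.dot(C, yy) / sxx)
            resid = yy - a * C
            dof = max(n - 1, 1)
            s2 = float(np.dot(resid, resid)) / dof
            self.a_ = a
            self.intercept_ = float(self.fix_intercept)
            self.se_a_ = float(np.sqrt(s2 / sxx))
            self.se_intercept_ = 0.0
        else:
            if n < 2:
                raise ValueError("need at least 2 points for a free-intercept fit")
            A = np.column_stack([np.ones(n), C])
            coef, *_ = np.linalg.lstsq(A, na, rcond=None)
            resid = na - A @ coef
            dof = max(n - 2, 1)
            s2 = float(np.dot(resid, resid)) / dof
            cov = s2 * np.linalg.inv(A.T @ A)
            self.intercept_, self.a_ = float(coef[0]), float(coef[1])
            self.se_intercept_ = float(np.sqrt(cov[0, 0]))
            self.se_a_ = float(np.sqrt(cov[1, 1]))
            if (self.Na_buffer is not None and self.se_intercept_ > 0
                    and abs(self.intercept_ - self.Na_buffer)
                    > 2 * self.se_intercept_):
                warnings.warn(
                    "fitted intercept deviates from the buffer Na+ "
                    "concentration by more than 2 SE: possible systematic "
                    "quantification bias", UserWarning)
        self.residuals_ = resid
        self.n_points_ = n
        return self

    def predict(self, X):
        C = _as_1d(X)
        return self.intercept_ + self.a_ * C


def fit_ion_excess(C_M, Na_total_values,
                   fix_intercept: float | None = None,
                   Na_buffer: float | None = None) -> IonExcessFit:
    """Fit the ion-count-per-macromolecule slope; see :class:`IonExcessFit`."""
    return IonExcessFit(fix_intercept=fix_intercept,
                        Na_buffer=Na_buffer).fit(C_M, Na_total_values)


def percent_vs_prediction(a_measured: float, a_predicted: float) -> float:
    """Percent excess of a measured ion count over an electrostatic prediction."""
    if not a_predicted > 0:
        raise ValueError("a_predicted must be positive")
    return 100.0 * (a_measured - a_predicted) / a_predicted
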