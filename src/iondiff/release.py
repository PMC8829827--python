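"""Counterion release upon protein-DNA association.

Comparing the apparent Na+ diffusion coefficient of a protein-DNA sample
(D_PD) against a DNA-only sample at matched DNA concentration (D_D): charge
neutralization by the complex releases ions into the faster free state, so
D_PD > D_D.  Under the two-state model with per-complex atmosphere capacity
reduced from n_c to n_c - n_R, the number of released ions per complex is::

    n_R = n_c (D_PD - D_D) / ((D_f - D_D) p_complex)

where p_complex is the fraction of DNA bound by protein.  Both samples are
assumed to share the same total Na+ (prepared from the same equilibrated
stocks), and the positively charged protein is assumed to carry no Na+
atmosphere of its own.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class ReleaseInputs:
    """Diffusion coefficients (consistent units) and sample composition."""

    D_PD: float
    D_D: float
    D_f: float
    n_c: float
    p_complex: float
    se_D_PD: float = 0.0
    se_D_D: float = 0.0
    se_D_f: float = 0.0

    def __post_init__(self) -> None:
        if not (0 < self.p_complex <= 1):
            raise ValueError("p_complex must be in (0, 1]")
        if self.n_c <= 0:
            raise ValueError("n_c must be positive")


def released_ions(inputs: ReleaseInputs) -> tuple[float, float]:
    """Released ions per complex and its first-order-propagated SE.

    n_c and p_complex are treated as exact; the SE combines the three
    diffusion-coefficient uncertainties through the partial derivatives of
    n_R.  A result outside [0, n_c/p_complex] (i.e. D_PD outside [D_D, D_f])
    is returned but indicates inconsistent inputs.
    """
    D_PD, D_D, D_f = inputs.D_PD, inputs.D_D, inputs.D_f
    if D_f == D_D:
        raise ValueError("D_f == D_D: no bound population to release")
    scale = inputs.n_c / inputs.p_complex
    n_R = scale * (D_PD - D_D) / (D_f - D_D)
    # partial derivatives for first-order error propagation
    d_dPD = scale / (D_f - D_D)
    d_dD = scale * (D_PD - D_f) / (D_f - D_D) ** 2
    d_df = -scale * (D_PD - D_D) / (D_f - D_D) ** 2
    se = float(np.sqrt((d_dPD * inputs.se_D_PD) ** 2
                       + (d_dD * inputs.se_D_D) ** 2
                       + (d_df * inputs.se_D_f) ** 2))
    return float(n_R), se


def complex_fraction(P_total: float, DNA_total: float,
                     K_d: float | None = None) -> float:
    """Fraction of DNA bound by protein for 1:1 binding.

    Tight-binding default min(P, DNA)/DNA; with a finite dissociation
    constant, the exact quadratic solution of the 1:1 equilibrium.
    """
    if not (P_total > 0 and DNA_total > 0):
        raise ValueError("P_total and DNA_total must be positive")
    if K_d is None or K_d == 0:
        return min(P_total, DNA_total) / DNA_total
    if K_d < 0:
        raise ValueError("K_d must be non-negative")
    s = P_total + DNA_total + K_d
    # complex concentration: stable root of c^2 - s c + P*DNA = 0
    c = 2.0 * P_total * DNA_total / (s + np.sqrt(s * s - 4.0 * P_total * DNA_total))
    return float(c / DNA_total)
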