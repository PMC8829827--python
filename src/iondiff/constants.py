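"""Physical constants, nucleus registry, and unit conventions.

Everything downstream works in SI internally (m^2 s^-1 for diffusion,
T m^-1 for gradients, seconds, mol L^-1 for concentrations); conversion to
the conventional reporting units (1e-5 cm^2 s^-1, G cm^-1, mM) happens only
at I/O boundaries.
"""

from __future__ import annotations

from dataclasses import dataclass, field

#: gyromagnetic ratio of 1H, rad s^-1 T^-1
GAMMA_1H = 2.675222e8

#: gamma(23Na) / gamma(1H); 23Na has 26.45% of the proton gyromagnetic ratio
GAMMA_RATIO_23NA = 0.2645

#: molar gas constant in cal mol^-1 K^-1 (entropy-unit scale)
R_CAL = 1.98720

#: default temperature, K
TEMPERATURE_K = 298.15


@dataclass(frozen=True)
class PhysicalConstants:
    """Bundle of the physical constants used across the pipeline."""

    gamma_1H: float = GAMMA_1H
    gamma_ratio_23Na: float = GAMMA_RATIO_23NA
    R_cal: float = R_CAL
    temperature: float = TEMPERATURE_K

    def __post_init__(self) -> None:
        for name in ("gamma_1H", "gamma_ratio_23Na", "R_cal", "temperature"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be strictly positive")


#: gyromagnetic ratios by nucleus label, rad s^-1 T^-1.  23Na is derived from
#: the 1H value through the 26.45% ratio rather than tabulated independently.
GAMMA_REGISTRY: dict[str, float] = {
    "1H": GAMMA_1H,
    "23Na": GAMMA_RATIO_23NA * GAMMA_1H,
}


def gamma_for(nucleus: str) -> float:
    """Gyromagnetic ratio (rad s^-1 T^-1) for a registered nucleus label."""
    try:
        return GAMMA_REGISTRY[nucleus]
    except KeyError:
        known = ", ".join(sorted(GAMMA_REGISTRY))
        raise KeyError(
            f"unknown nucleus {nucleus!r}; registered nuclei: {known}"
        ) from None


# ---------------------------------------------------------------------------
# unit conversions (reporting <-> internal SI)
# ---------------------------------------------------------------------------

def gradient_G_per_cm_to_T_per_m(value: float) -> float:
    """Convert a gradient strength from G cm^-1 to T m^-1 (factor 0.01)."""
    return value * 0.01


def gradient_T_per_m_to_G_per_cm(value: float) -> float:
    return value * 100.0


def diffusion_SI_to_report(d_m2_s: float) -> float:
    """m^2 s^-1 -> units of 1e-5 cm^2 s^-1 (the conventional reporting scale)."""
    return d_m2_s / 1e-9


def diffusion_report_to_SI(d_1e5_cm2_s: float) -> float:
    """Units of 1e-5 cm^2 s^-1 -> m^2 s^-1."""
    return d_1e5_cm2_s * 1e-9


def concentration_mM_to_M(value: float) -> float:
    return value * 1e-3


def concentration_M_to_mM(value: float) -> float:
    return value * 1e3
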