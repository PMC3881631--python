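"""Deterministic assay and yield calculations.

Enzyme activity is computed from blank-corrected absorbance via a molar
extinction coefficient taken in the assay's printed units (M^-1 mL^-1, path
length 1 cm absorbed into epsilon): the product concentration A/epsilon in
mol mL^-1 is converted to umol mL^-1 with the factor 10^6, corrected for
the enzyme dilution (reaction volume / enzyme volume) and divided by the
incubation time, giving U/mL where one unit releases 1 umol mL^-1 min^-1
of product.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

__all__ = ["AssaySpec", "activity_u_per_ml", "pectin_yield_percent"]


@dataclass(frozen=True)
class AssaySpec:
    """Spectrophotometric assay parameters.

    epsilon : molar extinction coefficient (M^-1 mL^-1 as printed)
    reaction_volume / enzyme_volume : mL (only their ratio matters)
    time_min : incubation time in minutes
    wavelength_nm : recorded for provenance only
    """

    epsilon: float
    reaction_volume: float
    enzyme_volume: float
    time_min: float
    wavelength_nm: float | None = None

    def __post_init__(self) -> None:
        if self.epsilon <= 0:
            raise ValueError("extinction coefficient must be positive")
        if self.reaction_volume <= 0 or self.enzyme_volume <= 0:
            raise ValueError("volumes must be positive")
        if self.time_min <= 0:
            raise ValueError("incubation time must be positive")


def activity_u_per_ml(absorbance: float, spec: AssaySpec) -> float:
    """Enzyme activity in U/mL from blank-corrected absorbance.

    U/mL = (A / epsilon) * 1e6 * (V_rxn / V_enz) / t
    """
    if absorbance < 0:
        raise ValueError("absorbance must be blank-corrected and non-negative")
    conc_umol = absorbance / spec.epsilon * 1e6
    return conc_umol * (spec.reaction_volume / spec.enzyme_volume) / spec.time_min


def pectin_yield_percent(extracted_mass: float, sample_mass: float) -> float:
    """Pectin yield: 100 * extracted mass / sample mass (same mass units)."""
    if sample_mass <= 0:
        raise ValueError("sample mass must be positive")
    if extracted_mass < 0:
        raise ValueError("extracted mass cannot be negative")
    if extracted_mass > sample_mass:
        warnings.warn(
            "extracted mass exceeds sample mass; check units", stacklevel=2
        )
    return 100.0 * extracted_mass / sample_mass
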