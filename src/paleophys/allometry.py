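"""Deterministic allometric estimators for fossil mammaliaforms.

Two published cranial scaling relationships bracket body mass:

* the marsupial dentary-length law (natural logs),
  ``ln mass(g) = 2.9677 * ln dentary(mm) - 5.6712``, giving the *maximum*
  estimate, and
* the small-insectivore skull-length law, ``log10 mass(g) =
  3.68 * log10 skull(mm) - 3.83``, giving the *minimum* estimate.

NOTE on the skull law's log base: its published typesetting says "ln", but
only base-10 logarithms reproduce the worked masses that accompany it
(10.7 g and 14.9 g); a natural-log reading yields ~1.6 kg.  It is therefore
implemented in base 10 and the "ln" treated as a typesetting artefact.

Skull length is derived from dentary length by the factor 1.0458 and
carried unrounded downstream; rounding the intermediate skull length
changes the final mass at the first decimal.  Reported masses are rounded
half-up to 0.1 g for display only.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = [
    "DENTARY_MASS_SLOPE",
    "DENTARY_MASS_INTERCEPT",
    "SKULL_MASS_SLOPE",
    "SKULL_MASS_INTERCEPT",
    "SKULL_PER_DENTARY",
    "FEMUR_LENGTH_PER_DIAMETER",
    "mass_from_dentary",
    "skull_from_dentary",
    "mass_from_skull",
    "mean_mass",
    "femur_length_from_diameter",
    "FossilMassEstimate",
    "estimate_fossil_mass",
    "round_half_up",
]

DENTARY_MASS_SLOPE = 2.9677        # natural-log law
DENTARY_MASS_INTERCEPT = -5.6712
SKULL_MASS_SLOPE = 3.68            # base-10 law (see module docstring)
SKULL_MASS_INTERCEPT = -3.83
SKULL_PER_DENTARY = 1.0458
FEMUR_LENGTH_PER_DIAMETER = 10.3


def _require_positive(value: float, name: str) -> float:
    value = float(value)
    if value <= 0:
        raise ValueError(f"{name} must be positive; got {value}")
    return value


def round_half_up(value: float, decimals: int = 1) -> float:
    """Display rounding: round half away from zero (5 rounds up)."""
    factor = 10.0 ** decimals
    return math.floor(abs(value) * factor + 0.5) / factor * (1 if value >= 0 else -1)


def mass_from_dentary(dentary_mm: float) -> float:
    """Maximum body-mass estimate (g) from dentary length (mm)."""
    L = _require_positive(dentary_mm, "dentary length")
    return math.exp(DENTARY_MASS_SLOPE * math.log(L) + DENTARY_MASS_INTERCEPT)


def skull_from_dentary(dentary_mm: float) -> float:
    """Skull length (mm) from dentary length (mm); returned unrounded."""
    return SKULL_PER_DENTARY * _require_positive(dentary_mm, "dentary length")


def mass_from_skull(skull_mm: float) -> float:
    """Minimum body-mass estimate (g) from skull length (mm); base-10 law."""
    S = _require_positive(skull_mm, "skull length")
    return 10.0 ** (SKULL_MASS_SLOPE * math.log10(S) + SKULL_MASS_INTERCEPT)


def mean_mass(min_g: float, max_g: float) -> float:
    """Arithmetic mean of the two mass estimates (g)."""
    return 0.5 * (_require_positive(min_g, "min mass")
                  + _require_positive(max_g, "max mass"))


def femur_length_from_diameter(mid_diaphysial_mm: float) -> float:
    """Femur length (mm) from minimum mid-diaphysial diameter (mm)."""
    d = _require_positive(mid_diaphysial_mm, "mid-diaphysial diameter")
    return FEMUR_LENGTH_PER_DIAMETER * d


@dataclass(frozen=True)
class FossilMassEstimate:
    """Body-mass bracket for one fossil taxon, full precision retained."""

    taxon: str
    dentary_mm: float
    skull_mm: float
    mass_min_g: float   # skull-length law
    mass_max_g: float   # dentary-length law
    mass_mean_g: float

    def rounded(self, decimals: int = 1) -> dict:
        return {
            "taxon": self.taxon,
            "dentary_mm": self.dentary_mm,
            "skull_mm": round_half_up(self.skull_mm, decimals),
            "mass_min_g": round_half_up(self.mass_min_g, decimals),
            "mass_max_g": round_half_up(self.mass_max_g, decimals),
            "mass_mean_g": round_half_up(self.mass_mean_g, decimals),
        }


def estimate_fossil_mass(taxon: str, dentary_mm: float) -> FossilMassEstimate:
    """Run the full mass bracket from a dentary length: dentary law for the
    maximum, unrounded skull length through the skull law for the minimum,
    arithmetic mean for the point value."""
    skull = skull_from_dentary(dentary_mm)
    mmax = mass_from_dentary(dentary_mm)
    mmin = mass_from_skull(skull)
    return FossilMassEstimate(
        taxon=taxon,
        dentary_mm=float(dentary_mm),
        skull_mm=skull,
        mass_min_g=mmin,
        mass_max_g=mmax,
        mass_mean_g=mean_mass(mmin, mmax),
    )
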