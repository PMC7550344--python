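"""Projection of fossil lifespans onto extant comparative regressions.

A fossil's cementum-based maximum lifespan is dropped onto an extant
lifespan-trait regression (msSMR or growth constant K against lifespan,
both on log10 scale) to estimate the trait the fossil would have had if it
followed the extant relationship.  Confidence intervals for the projection
come from the regression's 95% confidence band at that lifespan,
back-transformed to linear scale; fossils are never placed on the
phylogeny.  A fossil's lifespan enters as an exact integer (the increment
count carries no sampling-error model).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .regression import RegressionFit, predict_with_intervals

__all__ = [
    "CAPTIVE_OFFSET_YR",
    "ProjectedTrait",
    "PIMembership",
    "FossilProfile",
    "project_trait",
    "captive_adjust",
    "pi_membership",
]

#: mean excess of maximum captive over maximum wild lifespan (years), for
#: extant taxa under 100 g, used by the captive-data sensitivity variant
CAPTIVE_OFFSET_YR = {"mammal": 3.43, "reptile": 4.38}


@dataclass(frozen=True)
class ProjectedTrait:
    """A back-transformed trait estimate with its 95% confidence interval
    (``None`` bounds when the fit carries no coefficient covariance, e.g. a
    published line known only by its coefficients)."""

    estimate: float
    lo: float | None
    hi: float | None


def project_trait(fit, lifespan_yr: float, interval: str = "confidence"
                  ) -> ProjectedTrait:
    """Evaluate ``10 ** (a + b * log10(lifespan))`` with interval endpoints
    from the regression's confidence (default) or prediction band."""
    if lifespan_yr <= 0:
        raise ValueError("lifespan must be positive")
    if interval not in ("confidence", "prediction"):
        raise ValueError(f"unknown interval type {interval!r}")
    x0 = np.log10(float(lifespan_yr))
    estimate = 10.0 ** (fit.intercept + fit.slope * x0)
    cov = getattr(fit, "cov_params", None)
    if cov is None:
        return ProjectedTrait(float(estimate), None, None)
    bands = predict_with_intervals(fit, x0)
    lo, hi = ((bands.ci_lo, bands.ci_hi) if interval == "confidence"
              else (bands.pi_lo, bands.pi_hi))
    return ProjectedTrait(float(estimate), float(10.0**lo), float(10.0**hi))


def captive_adjust(lifespan_yr: float, clade: str,
                   offsets: dict[str, float] = CAPTIVE_OFFSET_YR) -> float:
    """Wild-to-captive lifespan adjustment: add the clade's mean captive
    excess.  Used only in the captive-data sensitivity variant."""
    if lifespan_yr <= 0:
        raise ValueError("lifespan must be positive")
    if clade not in offsets:
        raise ValueError(f"unknown clade {clade!r}; expected one of {sorted(offsets)}")
    return float(lifespan_yr) + float(offsets[clade])


@dataclass(frozen=True)
class PIMembership:
    """Where a fossil sits relative to a trait-on-mass regression: inside /
    above / below its 95% prediction interval (the boundary counts as
    inside), the signed log10 distance from the regression mean, and every
    extant species' own distance for rank comparisons."""

    classification: str
    distance: float
    extant_distances: pd.Series = field(repr=False)


def pi_membership(fit: RegressionFit, fossil_mass_g: float,
                  fossil_trait: float) -> PIMembership:
    lx, ly = np.log10(fossil_mass_g), np.log10(fossil_trait)
    bands = predict_with_intervals(fit, float(lx))
    if ly > bands.pi_hi:
        cls = "above"
    elif ly < bands.pi_lo:
        cls = "below"
    else:
        cls = "inside"
    distance = float(ly - bands.mean)
    if fit.x is not None and fit.y is not None:
        resid = fit.y - fit.predict(fit.x)
        idx = fit.species or range(len(resid))
        extant = pd.Series(resid, index=idx, name="distance")
    else:
        extant = pd.Series(dtype=float, name="distance")
    return PIMembership(cls, distance, extant)


@dataclass
class FossilProfile:
    """Assembled physiological profile of one fossil taxon."""

    taxon: str
    lifespan_yr: int
    mass_min_g: float
    mass_max_g: float
    mass_mean_g: float
    mssmr_reptile: ProjectedTrait | None = None
    mssmr_mammal: ProjectedTrait | None = None
    k_reptile: ProjectedTrait | None = None
    k_mammal: ProjectedTrait | None = None
    qi_mm3: float | None = None
    pi_flags: dict[str, str] = field(default_factory=dict)

    def __post_init__(self):
        if self.lifespan_yr < 1 or int(self.lifespan_yr) != self.lifespan_yr:
            raise ValueError("lifespan must be an integer >= 1 year")
        for name in ("mass_min_g", "mass_max_g", "mass_mean_g"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    def to_dict(self) -> dict:
        def _proj(p):
            return None if p is None else {
                "estimate": p.estimate, "ci95_lo": p.lo, "ci95_hi": p.hi,
            }

        return {
            "taxon": self.taxon,
            "lifespan_yr": int(self.lifespan_yr),
            "mass_min_g": self.mass_min_g,
            "mass_max_g": self.mass_max_g,
            "mass_mean_g": self.mass_mean_g,
            "mssmr_reptile": _proj(self.mssmr_reptile),
            "mssmr_mammal": _proj(self.mssmr_mammal),
            "k_reptile": _proj(self.k_reptile),
            "k_mammal": _proj(self.k_mammal),
            "qi_mm3": self.qi_mm3,
            "pi_flags": dict(self.pi_flags),
        }
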