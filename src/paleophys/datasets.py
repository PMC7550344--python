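"""Published inputs for the two Early Jurassic mammaliaforms.

These are small tables and regression coefficients transcribed from the
printed record: the toothrow increment counts of the dentulous
Morganucodon specimens, the fossils' dentary lengths and cementum-based
maximum lifespans, and the extant-data regression lines (coefficients
only; the underlying species tables and tree distributions are not
redistributed here, so published lines carry no coefficient covariance and
projections onto them have point estimates only).
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .cementum import IncrementTable

__all__ = [
    "DENTARY_LENGTH_MM",
    "MAX_LIFESPAN_YR",
    "MORGANUCODON_QI_MM3",
    "OBSERVER_CV",
    "EXTANT_CV_SUMMARY",
    "PublishedRegression",
    "PUBLISHED_FITS",
    "morganucodon_toothrow_counts",
    "morganucodon_toothrow_table",
]

#: dentary lengths from published CT reconstructions (mm)
DENTARY_LENGTH_MM = {"Morganucodon": 20.0, "Kuehneotherium": 21.9}

#: cementum-based minimum estimates of maximum lifespan (years)
MAX_LIFESPAN_YR = {"Morganucodon": 14, "Kuehneotherium": 9}

#: blood-flow index of Morganucodon from its six most complete femora
MORGANUCODON_QI_MM3 = 3.829e-7

#: mean intra-observer CV (%) of the tomographic counts per fossil taxon
OBSERVER_CV = {"Morganucodon": 9.32, "Kuehneotherium": 4.89}

#: (n, mean, sd) of CVs from ten earlier thin-section studies of extant mammals
EXTANT_CV_SUMMARY = (10, 21.8, 5.87)


@dataclass(frozen=True)
class PublishedRegression:
    """A log10-log10 regression line known only by its printed summary."""

    slope: float
    intercept: float
    ci95_slope: float | None = None   # printed half-width of the slope CI
    r2: float | None = None
    label: str = ""
    cov_params = None  # no coefficient covariance available

    def predict(self, x0):
        return self.intercept + self.slope * x0


#: printed comparative fits; keys are "<group>_<response>_on_<predictor>"
PUBLISHED_FITS: dict[str, PublishedRegression] = {
    "mammal_lifespan_on_mass": PublishedRegression(
        0.26, 0.16, 0.05, 0.69, "log10 lifespan ~ log10 mass, extant mammals"),
    "reptile_lifespan_on_mass": PublishedRegression(
        0.26, 0.60, 0.08, 0.46, "log10 lifespan ~ log10 mass, extant reptiles"),
    "mammal_mssmr_on_lifespan": PublishedRegression(
        -0.237, -0.083, 0.07, 0.59, "log10 msSMR ~ log10 lifespan, mammals"),
    "reptile_mssmr_on_lifespan": PublishedRegression(
        -0.83, -0.31, 0.255, 0.43, "log10 msSMR ~ log10 lifespan, reptiles"),
    "mammal_k_on_lifespan": PublishedRegression(
        -0.692, -1.171, 0.101, 0.66, "log10 K ~ log10 lifespan, mammals"),
    "reptile_k_on_lifespan": PublishedRegression(
        -0.69, -2.523, 0.339, 0.43, "log10 K ~ log10 lifespan, reptiles"),
    "mammal_qi_on_mass": PublishedRegression(
        0.513, -6.104, None, None, "log10 Qi ~ log10 mass, mammals"),
    "nonvaranid_qi_on_mass": PublishedRegression(
        0.685, -8.139, None, None, "log10 Qi ~ log10 mass, non-varanid reptiles"),
}


_TOOTHROW_ROWS = [
    ("NHMUK PV M 95790", "i4", 7),
    ("NHMUK PV M 95790", "c", 7),
    ("NHMUK PV M 95790", "p1", 8),
    ("NHMUK PV M 95790", "p2", 8),
    ("NHMUK PV M 95790", "p3", 8),
    ("NHMUK PV M 96413", "p3", 5),
    ("NHMUK PV M 96413", "p4", 5),
    ("NHMUK PV M 96413", "m1", 5),
    ("NHMUK PV M 96413", "Dentary", 5),
    ("NHMUK PV M 96396", "p4", 4),
    ("NHMUK PV M 96396", "m1", 4),
    ("NHMUK PV M 96396", "m2", 4),
    ("NHMUK PV M 96396", "m3", 3),
    ("NHMUK PV M 96396", "Dentary", 4),
    ("NHMUK PV M 95809", "m1", 3),
    ("NHMUK PV M 95809", "m2", 3),
    ("NHMUK PV M 104128", "m1", 5),
    ("NHMUK PV M 104128", "m2", 5),
    ("NHMUK PV M 96441", "m1", 5),
    ("NHMUK PV M 96441", "m2", 5),
    ("NHMUK PV M 104130", "m1", 5),
    ("NHMUK PV M 104130", "m2", 5),
    ("NHMUK PV M 104130", "m3", 4),
    ("NHMUK PV M 104129", "m1", 9),
    ("NHMUK PV M 104129", "m2", 9),
    ("NHMUK PV M 104129", "m3", 8),
]


def morganucodon_toothrow_counts() -> pd.DataFrame:
    """Cementum and dentary increment counts for the eight dentulous
    Morganucodon specimens, one row per tooth/dentary element."""
    return pd.DataFrame(_TOOTHROW_ROWS, columns=["specimen", "element", "count"])


def morganucodon_toothrow_table() -> IncrementTable:
    """The toothrow counts as an :class:`IncrementTable` (each element is
    one published reading; a single published observer)."""
    df = morganucodon_toothrow_counts().copy()
    df["observer"] = "published"
    df["section"] = df["element"]
    return IncrementTable(df)
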