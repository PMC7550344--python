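"""Cementochronology: increment-count tables, lifespan aggregation, and
observer-agreement statistics.

One thick + one thin cementum increment pair is deposited per year, so an
increment count maps one-to-one to years of life after tooth eruption.
Counts are read per virtual thin section by several blinded observers; an
observer's final count for a specimen is the *maximum* over that
specimen's sections (splitting/coalescing increments can hide increments
in a single section but cannot add persistent ones), the per-specimen
consensus across observers is the median, and a taxon's maximum-lifespan
estimate is the maximum consensus over specimens.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "IncrementTable",
    "AgreementStats",
    "observer_final_count",
    "observer_final_counts",
    "specimen_consensus",
    "taxon_max_lifespan",
    "cv",
    "one_way_anova",
    "AnovaResult",
    "cohens_d",
    "shapiro_w",
    "agreement_stats",
    "zproject_sum",
]

_COLUMNS = ["specimen", "element", "observer", "section", "count"]


class IncrementTable:
    """Validated table of per-specimen, per-observer, per-section increment
    counts (positive integers; one record per specimen/observer/section)."""

    def __init__(self, records: pd.DataFrame):
        df = pd.DataFrame(records)
        missing = [c for c in _COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"increment table lacks columns: {missing}")
        df = df[_COLUMNS].copy()
        if df.empty:
            raise ValueError("increment table is empty")
        counts = pd.to_numeric(df["count"], errors="raise")
        if (counts < 1).any() or (counts != counts.round()).any():
            raise ValueError("increment counts must be integers >= 1")
        df["count"] = counts.astype(int)
        key = ["specimen", "observer", "section"]
        if df.duplicated(key).any():
            dups = df[df.duplicated(key)][key].iloc[0].tolist()
            raise ValueError(f"duplicate (specimen, observer, section) record: {dups}")
        self.df = df.reset_index(drop=True)

    @classmethod
    def from_csv(cls, path) -> "IncrementTable":
        return cls(pd.read_csv(path))

    def to_csv(self, path) -> None:
        self.df.to_csv(path, index=False)

    @property
    def specimens(self) -> list[str]:
        return sorted(self.df["specimen"].unique())

    @property
    def observers(self) -> list[str]:
        return sorted(self.df["observer"].unique())


def _as_df(table) -> pd.DataFrame:
    return table.df if isinstance(table, IncrementTable) else IncrementTable(table).df


def observer_final_count(table, specimen, observer) -> int:
    """An observer's final count for a specimen: the maximum over sections."""
    df = _as_df(table)
    sel = df[(df["specimen"] == specimen) & (df["observer"] == observer)]
    if sel.empty:
        raise KeyError(f"no records for specimen {specimen!r}, observer {observer!r}")
    return int(sel["count"].max())


def observer_final_counts(table) -> pd.DataFrame:
    """Specimen x observer matrix of final (max-over-sections) counts."""
    df = _as_df(table)
    return df.groupby(["specimen", "observer"])["count"].max().unstack()


def _median_half_up(values) -> int:
    med = float(np.median(np.asarray(values, dtype=float)))
    return int(np.floor(med + 0.5))


def specimen_consensus(table, rule: str = "median") -> pd.Series:
    """Per-specimen consensus count across observers.

    Rules: ``median`` (default; .5 ties rounded half up), ``max``, ``min``.
    """
    finals = observer_final_counts(table)
    if rule == "median":
        out = finals.apply(lambda r: _median_half_up(r.dropna()), axis=1)
    elif rule == "max":
        out = finals.max(axis=1).astype(int)
    elif rule == "min":
        out = finals.min(axis=1).astype(int)
    else:
        raise ValueError(f"unknown consensus rule {rule!r}")
    return out.rename("count")


def taxon_max_lifespan(table, rule: str = "median") -> int:
    """Minimum estimate of maximum lifespan (years) for a taxon: the largest
    per-specimen consensus count in the sample."""
    return int(specimen_consensus(table, rule=rule).max())


# ---------------------------------------------------------------------------
# agreement statistics


def cv(values) -> float:
    """Coefficient of variation in percent: 100 * sample sd (n-1) / mean."""
    v = np.asarray(list(values), dtype=float)
    if v.size < 2:
        raise ValueError("CV needs at least two values")
    m = v.mean()
    if m == 0:
        raise ValueError("CV undefined for zero mean")
    return float(100.0 * v.std(ddof=1) / m)


@dataclass
class AnovaResult:
    fstat: float
    df_between: int
    df_within: int
    pvalue: float


def _group_summary(g):
    """(n, mean, sd) from either a raw sequence or a summary triple."""
    if isinstance(g, tuple) and len(g) == 3 and np.isscalar(g[0]):
        n, mean, sd = g
        return int(n), float(mean), float(sd)
    v = np.asarray(list(g), dtype=float)
    sd = v.std(ddof=1) if v.size > 1 else 0.0
    return int(v.size), float(v.mean()), float(sd)


def one_way_anova(groups) -> AnovaResult:
    """One-way ANOVA accepting raw sequences and/or (n, mean, sd) summary
    triples interchangeably; the summary path reconstructs the between- and
    within-group sums of squares exactly."""
    summaries = [_group_summary(g) for g in groups]
    if len(summaries) < 2:
        raise ValueError("ANOVA needs at least two groups")
    ns = np.array([s[0] for s in summaries], dtype=float)
    means = np.array([s[1] for s in summaries])
    sds = np.array([s[2] for s in summaries])
    N, k = ns.sum(), len(summaries)
    df_within = int(N - k)
    if df_within <= 0:
        raise ValueError("within-group variance undefined (all groups size 1)")
    grand = float((ns * means).sum() / N)
    ss_between = float((ns * (means - grand) ** 2).sum())
    ss_within = float(((ns - 1) * sds**2).sum())
    df_between = k - 1
    F = (ss_between / df_between) / (ss_within / df_within)
    p = float(stats.f.sf(F, df_between, df_within))
    return AnovaResult(float(F), df_between, df_within, p)


def cohens_d(group1, group2) -> float:
    """Cohen's d with the unweighted pooled sd sqrt((sd1^2 + sd2^2) / 2);
    groups may be raw sequences or (n, mean, sd) triples."""
    n1, m1, s1 = _group_summary(group1)
    n2, m2, s2 = _group_summary(group2)
    pooled = np.sqrt((s1**2 + s2**2) / 2.0)
    if pooled == 0:
        raise ValueError("pooled standard deviation is zero")
    return float(abs(m1 - m2) / pooled)


def shapiro_w(values):
    """Shapiro-Wilk (W, p) for n >= 3; returns None for smaller samples,
    where the statistic is not computable."""
    v = np.asarray(list(values), dtype=float)
    if v.size < 3:
        return None
    w, p = stats.shapiro(v)
    return float(w), float(p)


@dataclass
class AgreementStats:
    """Observer-agreement summary for one increment table."""

    cv_across_observers: pd.Series     # per specimen, over observer finals
    cv_within_observers: pd.Series     # per specimen, mean over observers' sections
    mean_cv_across: float
    mean_cv_within: float
    shapiro: tuple[float, float] | None


def agreement_stats(table) -> AgreementStats:
    df = _as_df(table)
    finals = observer_final_counts(table)
    across = finals.apply(lambda r: cv(r.dropna()) if r.dropna().size > 1
                          else np.nan, axis=1).rename("cv_across")

    def _within(spec_df):
        per_obs = [
            cv(g["count"]) for _, g in spec_df.groupby("observer")
            if len(g) > 1 and g["count"].mean() != 0
        ]
        return float(np.mean(per_obs)) if per_obs else np.nan

    within = df.groupby("specimen").apply(_within, include_groups=False) \
               .rename("cv_within")
    across_vals = across.dropna().to_numpy()
    return AgreementStats(
        cv_across_observers=across,
        cv_within_observers=within,
        mean_cv_across=float(np.nanmean(across)) if across.notna().any() else np.nan,
        mean_cv_within=float(np.nanmean(within)) if within.notna().any() else np.nan,
        shapiro=shapiro_w(across_vals) if across_vals.size >= 3 else None,
    )


# ---------------------------------------------------------------------------
# virtual thin sections


def zproject_sum(stack: np.ndarray, start: int = 0, n: int = 10) -> np.ndarray:
    """Sum-slices z-projection: pixelwise sum of ``n`` consecutive slices
    starting at ``start`` (axis 0).  No renormalization, so the output
    dynamic range is ``n`` times the input range.  Ten slices is the default
    window for building a virtual thin section."""
    stack = np.asarray(stack)
    if stack.ndim != 3:
        raise ValueError("stack must be a 3-D array (slices, rows, cols)")
    if start < 0 or n < 1 or start + n > stack.shape[0]:
        raise IndexError(
            f"window [{start}, {start + n}) out of bounds for depth {stack.shape[0]}"
        )
    return stack[start:start + n].sum(axis=0)
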