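"""Generalized least squares regression under a phylogenetic correlation
structure with Pagel's lambda, plus the model-comparison machinery built on
it: restricted-maximum-likelihood lambda estimation, selection of the
best-fitting tree from a tree distribution by maximal regression F, a
nested ANCOVA ladder (common line, varying slope, varying intercept,
varying both), and a plain (identity-covariance) GLS fallback for data with
no phylogenetic signal.

The phylogenetic covariance is used in correlation form: the VCV from
:func:`paleophys.phylo.vcv_from_tree` is normalized by its diagonal, so for
an ultrametric tree the entry for tips i, j is ``lambda *
shared_path / height``.  Coefficient estimates are invariant to this
scaling, and it makes ``sigma2`` the marginal residual variance, which is
what the prediction intervals need.

Definitions that the source data never pin down and are therefore fixed
here: r^2 is ``1 - RSS/TSS`` computed in the whitened (V^{-1/2}) space;
lambda is estimated once on the richest model of an ANCOVA ladder and held
fixed across the ladder so the nested F tests share one covariance.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.linalg import solve_triangular

from .phylo import PhyloTree, vcv_from_tree

__all__ = [
    "RegressionFit",
    "ModelFit",
    "AncovaLadder",
    "TreeSelection",
    "PredictionIntervals",
    "fit_pgls",
    "fit_gls_plain",
    "fit_auto",
    "fit_over_trees",
    "phylo_ancova",
    "predict_with_intervals",
    "reml_loglik",
]

#: below this estimated lambda the phylogenetic structure is treated as absent
LAMBDA_PLAIN_THRESHOLD = 1e-3
_GOLDEN_ITERS = 40


# ---------------------------------------------------------------------------
# containers


@dataclass
class RegressionFit:
    """A fitted (P)GLS line on log10 scale, with everything needed for
    intervals, projection and audit."""

    slope: float
    intercept: float
    se_slope: float
    se_intercept: float
    ci95_slope: float          # half-width
    ci95_intercept: float      # half-width
    r2: float
    fstat: float
    df_num: int
    df_den: int
    pvalue: float
    lam: float | None          # None for plain GLS
    sigma2: float              # marginal residual variance (whitened scale)
    n: int
    model: str                 # "pgls" or "gls"
    tree_id: str | None = None
    reml_loglik: float | None = None
    loglik: float | None = None
    cov_params: np.ndarray | None = field(default=None, repr=False)
    species: list[str] | None = field(default=None, repr=False)
    x: np.ndarray | None = field(default=None, repr=False)
    y: np.ndarray | None = field(default=None, repr=False)

    def predict(self, x0):
        return self.intercept + self.slope * np.asarray(x0, dtype=float)


@dataclass
class ModelFit:
    """One rung of an ANCOVA ladder."""

    label: str
    params: dict[str, float]
    se: dict[str, float]
    rss: float
    loglik: float              # ML log-likelihood (comparable across rungs)
    n: int
    n_params: int


@dataclass
class AncovaLadder:
    """Nested two-group ANCOVA: common line, varying slope, varying
    intercept, varying both, each compared with the baseline by an F test on
    the whitened residual sums of squares."""

    models: dict[str, ModelFit]
    comparisons: pd.DataFrame   # model, F, df1, df2, p, lrt, lrt_p, partial_eta_sq
    lam: float | None
    selected: str
    groups: tuple[str, str]


@dataclass
class TreeSelection:
    fit: RegressionFit
    index: int
    f_values: list[float]


@dataclass
class PredictionIntervals:
    mean: np.ndarray
    ci_lo: np.ndarray
    ci_hi: np.ndarray
    pi_lo: np.ndarray
    pi_hi: np.ndarray


# ---------------------------------------------------------------------------
# internals


def _align(x, y, taxa: list[str]) -> tuple[np.ndarray, np.ndarray]:
    """Align two species-indexed Series to a taxon order, erroring loudly on
    species present in the tree but absent from the data."""
    x = pd.Series(x) if not isinstance(x, pd.Series) else x
    y = pd.Series(y) if not isinstance(y, pd.Series) else y
    missing = [t for t in taxa if t not in x.index or t not in y.index]
    if missing:
        raise ValueError(
            "species in tree but missing from the trait data: "
            + ", ".join(sorted(missing))
        )
    return x.loc[taxa].to_numpy(float), y.loc[taxa].to_numpy(float)


def _chol(C: np.ndarray) -> np.ndarray:
    try:
        return np.linalg.cholesky(C)
    except np.linalg.LinAlgError:
        return np.linalg.cholesky(C + 1e-10 * np.eye(C.shape[0]))


def _gls_core(X: np.ndarray, y: np.ndarray, C: np.ndarray) -> dict:
    """Whitened least squares: beta = (X'C^-1 X)^-1 X'C^-1 y plus the pieces
    the likelihoods need."""
    L = _chol(C)
    Xw = solve_triangular(L, X, lower=True)
    yw = solve_triangular(L, y, lower=True)
    XtX = Xw.T @ Xw
    beta = np.linalg.solve(XtX, Xw.T @ yw)
    resid = yw - Xw @ beta
    rss = float(resid @ resid)
    n, p = X.shape
    logdet_C = 2.0 * float(np.sum(np.log(np.diag(L))))
    sign, logdet_XtX = np.linalg.slogdet(XtX)
    if sign <= 0:
        raise np.linalg.LinAlgError("singular design matrix")
    return {
        "beta": beta,
        "cov_unscaled": np.linalg.inv(XtX),
        "rss": rss,
        "n": n,
        "p": p,
        "logdet_C": logdet_C,
        "logdet_XtX": logdet_XtX,
    }


def _reml_ll(core: dict) -> float:
    n, p, rss = core["n"], core["p"], core["rss"]
    s2 = rss / (n - p)
    return -0.5 * (
        (n - p) * (math.log(2 * math.pi) + math.log(s2) + 1)
        + core["logdet_C"]
        + core["logdet_XtX"]
    )


def _ml_ll(core: dict) -> float:
    n, rss = core["n"], core["rss"]
    s2 = rss / n
    return -0.5 * (n * (math.log(2 * math.pi) + math.log(s2) + 1) + core["logdet_C"])


def _corr_lambda(C1: np.ndarray, lam: float) -> np.ndarray:
    """Pagel transform of a phylogenetic correlation matrix (unit diagonal)."""
    C = C1 * lam
    np.fill_diagonal(C, 1.0)
    return C


def _golden_max(f, lo: float = 0.0, hi: float = 1.0,
                iters: int = _GOLDEN_ITERS) -> float:
    gr = (math.sqrt(5.0) - 1.0) / 2.0
    a, b = lo, hi
    c, d = b - gr * (b - a), a + gr * (b - a)
    fc, fd = f(c), f(d)
    for _ in range(iters):
        if fc > fd:
            b, d, fd = d, c, fc
            c = b - gr * (b - a)
            fc = f(c)
        else:
            a, c, fc = c, d, fd
            d = a + gr * (b - a)
            fd = f(d)
    xm = 0.5 * (a + b)
    candidates = [(f(lo), lo), (f(hi), hi), (f(xm), xm)]
    return max(candidates)[1]


def _estimate_lambda(X: np.ndarray, y: np.ndarray, C1: np.ndarray) -> float:
    return _golden_max(lambda l: _reml_ll(_gls_core(X, y, _corr_lambda(C1, l))))


def _simple_fit(x: np.ndarray, y: np.ndarray, C: np.ndarray, *,
                lam, model: str, tree_id=None, species=None) -> RegressionFit:
    n = len(y)
    if n < 3:
        raise ValueError("need at least 3 observations")
    X = np.column_stack([np.ones(n), x])
    core = _gls_core(X, y, C)
    p = core["p"]
    sigma2 = core["rss"] / (n - p)
    cov = core["cov_unscaled"] * sigma2
    se = np.sqrt(np.diag(cov))
    tcrit = stats.t.ppf(0.975, n - p)

    core0 = _gls_core(np.ones((n, 1)), y, C)
    df_num, df_den = p - 1, n - p
    fstat = ((core0["rss"] - core["rss"]) / df_num) / (core["rss"] / df_den)
    fstat = max(fstat, 0.0)
    pvalue = float(stats.f.sf(fstat, df_num, df_den))
    r2 = 1.0 - core["rss"] / core0["rss"]

    return RegressionFit(
        slope=float(core["beta"][1]),
        intercept=float(core["beta"][0]),
        se_slope=float(se[1]),
        se_intercept=float(se[0]),
        ci95_slope=float(tcrit * se[1]),
        ci95_intercept=float(tcrit * se[0]),
        r2=float(r2),
        fstat=float(fstat),
        df_num=df_num,
        df_den=df_den,
        pvalue=pvalue,
        lam=lam,
        sigma2=float(sigma2),
        n=n,
        model=model,
        tree_id=tree_id,
        reml_loglik=_reml_ll(core),
        loglik=_ml_ll(core),
        cov_params=cov,
        species=list(species) if species is not None else None,
        x=np.asarray(x, float),
        y=np.asarray(y, float),
    )


# ---------------------------------------------------------------------------
# public fitting API


def fit_pgls(x, y, tree: PhyloTree, lambda_mode="estimate",
             tree_id: str | None = None) -> RegressionFit:
    """PGLS of ``y`` on ``x`` (both species-indexed, log10 scale).

    ``lambda_mode`` is either ``"estimate"`` (REML profile over [0, 1] by
    golden-section search) or a fixed numeric lambda.  At ``lambda = 0`` the
    correlation matrix is the identity and the fit equals OLS.
    """
    vcv = vcv_from_tree(tree, 1.0)
    C1 = vcv.correlation()
    xv, yv = _align(x, y, vcv.taxa)
    X = np.column_stack([np.ones(len(yv)), xv])
    if lambda_mode == "estimate":
        lam = _estimate_lambda(X, yv, C1)
    else:
        lam = float(lambda_mode)
        if not (0.0 <= lam <= 1.0):
            raise ValueError(f"lambda must lie in [0, 1]; got {lam}")
    C = _corr_lambda(C1, lam)
    return _simple_fit(xv, yv, C, lam=lam, model="pgls", tree_id=tree_id,
                       species=vcv.taxa)


def fit_gls_plain(x, y, group=None):
    """Non-phylogenetic GLS (identity covariance); the pipeline's automatic
    fallback when the estimated lambda is below ``LAMBDA_PLAIN_THRESHOLD``.

    With ``group`` given, returns the plain-ANCOVA ladder instead of a
    single line.
    """
    x = pd.Series(x) if not isinstance(x, pd.Series) else x
    y = pd.Series(y) if not isinstance(y, pd.Series) else y
    y = y.loc[x.index]
    n = len(x)
    C = np.eye(n)
    if group is None:
        return _simple_fit(x.to_numpy(float), y.to_numpy(float), C,
                           lam=None, model="gls", species=list(x.index))
    group = pd.Series(group).loc[x.index] if not isinstance(group, pd.Series) \
        else group.loc[x.index]
    return _ladder(x.to_numpy(float), y.to_numpy(float),
                   group.to_numpy(), C, lam=None)


def fit_auto(x, y, tree: PhyloTree,
             lambda_threshold: float = LAMBDA_PLAIN_THRESHOLD) -> RegressionFit:
    """PGLS with estimated lambda, downgrading to plain GLS when the
    estimate shows no phylogenetic signal (lambda below the threshold)."""
    fit = fit_pgls(x, y, tree, lambda_mode="estimate")
    if fit.lam is not None and fit.lam < lambda_threshold:
        x = pd.Series(x) if not isinstance(x, pd.Series) else x
        return fit_gls_plain(x.loc[fit.species], pd.Series(y).loc[fit.species])
    return fit


def fit_over_trees(x, y, trees, lambda_mode="estimate") -> TreeSelection:
    """Fit every tree in a distribution and keep the fit with the highest F
    statistic (ties broken by lowest index); all F values are retained."""
    trees = list(trees)
    if not trees:
        raise ValueError("empty tree sequence")
    fits = [
        fit_pgls(x, y, t, lambda_mode=lambda_mode,
                 tree_id=t.label or f"tree{i}")
        for i, t in enumerate(trees)
    ]
    f_values = [f.fstat for f in fits]
    best = int(np.argmax(f_values))  # argmax returns the first maximum
    return TreeSelection(fit=fits[best], index=best, f_values=f_values)


# ---------------------------------------------------------------------------
# ANCOVA ladder

_LADDER_DESIGNS = {
    # label -> (column builder, parameter names)
    "common": (lambda x, g: [np.ones_like(x), x],
               ["intercept", "slope"]),
    "slopes": (lambda x, g: [np.ones_like(x), x, x * g],
               ["intercept", "slope", "slope_diff"]),
    "intercepts": (lambda x, g: [np.ones_like(x), x, g],
                   ["intercept", "slope", "intercept_diff"]),
    "full": (lambda x, g: [np.ones_like(x), x, g, x * g],
             ["intercept", "slope", "intercept_diff", "slope_diff"]),
}


def _ladder(x: np.ndarray, y: np.ndarray, group: np.ndarray,
            C: np.ndarray, lam) -> AncovaLadder:
    labels = sorted(pd.unique(group))
    if len(labels) != 2:
        raise ValueError("ANCOVA requires exactly two groups")
    counts = {lab: int(np.sum(group == lab)) for lab in labels}
    small = [lab for lab, c in counts.items() if c < 3]
    if small:
        raise ValueError(f"groups with fewer than 3 members: {small}")
    g = (group == labels[1]).astype(float)

    models: dict[str, ModelFit] = {}
    cores: dict[str, dict] = {}
    for label, (builder, names) in _LADDER_DESIGNS.items():
        X = np.column_stack(builder(x, g))
        core = _gls_core(X, y, C)
        cores[label] = core
        sigma2 = core["rss"] / (core["n"] - core["p"])
        se = np.sqrt(np.diag(core["cov_unscaled"]) * sigma2)
        models[label] = ModelFit(
            label=label,
            params=dict(zip(names, map(float, core["beta"]))),
            se=dict(zip(names, map(float, se))),
            rss=core["rss"],
            loglik=_ml_ll(core),
            n=core["n"],
            n_params=core["p"],
        )

    base = cores["common"]
    rows = []
    for label in ("slopes", "intercepts", "full"):
        core = cores[label]
        df1 = core["p"] - base["p"]
        df2 = core["n"] - core["p"]
        F = ((base["rss"] - core["rss"]) / df1) / (core["rss"] / df2)
        F = max(F, 0.0)
        p = float(stats.f.sf(F, df1, df2))
        lrt = 2.0 * (models[label].loglik - models["common"].loglik)
        lrt_p = float(stats.chi2.sf(max(lrt, 0.0), df1))
        eta = 1.0 - core["rss"] / base["rss"]
        rows.append((label, F, df1, df2, p, lrt, lrt_p, eta))
    comparisons = pd.DataFrame(
        rows,
        columns=["model", "F", "df1", "df2", "p", "lrt", "lrt_p",
                 "partial_eta_sq"],
    ).set_index("model")

    significant = comparisons[comparisons["p"] < 0.05]
    selected = "common" if significant.empty else str(significant["p"].idxmin())
    return AncovaLadder(models=models, comparisons=comparisons, lam=lam,
                        selected=selected, groups=(str(labels[0]), str(labels[1])))


def phylo_ancova(x, y, group, tree: PhyloTree,
                 lambda_mode="estimate") -> AncovaLadder:
    """Two-group phylogenetic ANCOVA.

    Lambda is estimated (REML) once on the richest model — separate slopes
    and intercepts — and held fixed across the ladder so that the nested F
    tests share a single covariance structure.
    """
    vcv = vcv_from_tree(tree, 1.0)
    C1 = vcv.correlation()
    xv, yv = _align(x, y, vcv.taxa)
    group = pd.Series(group) if not isinstance(group, pd.Series) else group
    missing = [t for t in vcv.taxa if t not in group.index]
    if missing:
        raise ValueError("species missing group labels: " + ", ".join(missing))
    gv = group.loc[vcv.taxa].to_numpy()

    labels = sorted(pd.unique(gv))
    if len(labels) != 2:
        raise ValueError("ANCOVA requires exactly two groups")
    gind = (gv == labels[1]).astype(float)
    Xfull = np.column_stack(_LADDER_DESIGNS["full"][0](xv, gind))
    if lambda_mode == "estimate":
        lam = _estimate_lambda(Xfull, yv, C1)
    else:
        lam = float(lambda_mode)
    return _ladder(xv, yv, gv, _corr_lambda(C1, lam), lam=lam)


# ---------------------------------------------------------------------------
# prediction


def predict_with_intervals(fit: RegressionFit, x0, level: float = 0.95
                           ) -> PredictionIntervals:
    """Mean, confidence interval and prediction interval at ``x0``.

    The CI uses the coefficient covariance; the PI adds the residual
    variance ``sigma2``, treating the new observation as independent of the
    fitted sample.  The PI always contains the CI.
    """
    if fit.cov_params is None:
        raise ValueError("fit carries no coefficient covariance")
    x0 = np.asarray(x0, dtype=float)
    scalar = x0.ndim == 0
    x0 = np.atleast_1d(x0)
    X0 = np.column_stack([np.ones_like(x0), x0])
    mean = X0 @ np.array([fit.intercept, fit.slope])
    var_mean = np.einsum("ij,jk,ik->i", X0, fit.cov_params, X0)
    tcrit = stats.t.ppf(0.5 + level / 2.0, fit.df_den)
    half_ci = tcrit * np.sqrt(var_mean)
    half_pi = tcrit * np.sqrt(var_mean + fit.sigma2)
    out = PredictionIntervals(mean, mean - half_ci, mean + half_ci,
                              mean - half_pi, mean + half_pi)
    if scalar:
        out = PredictionIntervals(*(float(v[0]) for v in
                                    (out.mean, out.ci_lo, out.ci_hi,
                                     out.pi_lo, out.pi_hi)))
    return out


def reml_loglik(x, y, tree: PhyloTree, lam: float) -> float:
    """Restricted log-likelihood of the simple regression at a fixed lambda
    (the quantity the lambda search maximizes)."""
    vcv = vcv_from_tree(tree, 1.0)
    C1 = vcv.correlation()
    xv, yv = _align(x, y, vcv.taxa)
    X = np.column_stack([np.ones(len(yv)), xv])
    return _reml_ll(_gls_core(X, yv, _corr_lambda(C1, lam)))
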