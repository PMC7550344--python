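"""Synthetic data with known ground truth for every pipeline stage.

The generator emulates the statistical structure of the comparative data
the pipeline consumes: log-log allometric trait relations whose residuals
are phylogenetically correlated (Brownian motion attenuated by Pagel's
lambda), two clades sharing a slope but differing in intercept, integer
growth-increment counts with observer noise, and log-normal nutrient
foramen radii.  Defaults follow the study conditions the package targets:
a lifespan-on-mass slope of 0.26 with clade intercepts 0.16 (mammals) and
0.60 (reptiles), msSMR and growth-constant relations declining with
lifespan, and a 325.5 Myr mammal-reptile root for two-clade trees.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .phylo import PhyloTree, parse_newick, vcv_from_tree

__all__ = [
    "SimConfig",
    "simulate_tree",
    "simulate_two_clade_tree",
    "simulate_traits",
    "simulate_increment_table",
    "write_dataset",
]


@dataclass(frozen=True)
class SimConfig:
    """Ground-truth parameters for all simulators.

    Identical configs (including ``seed``) produce bit-identical outputs.
    """

    n_tips: int = 100              # tips per clade
    birth_rate: float = 0.05       # Yule speciation rate, Myr^-1
    tree_height: float = 100.0     # clade root-to-tip depth, Myr
    graft_age: float = 325.5       # two-clade root age, Myr

    slope: float = 0.26            # log10 lifespan per log10 mass
    intercepts: tuple[float, float] = (0.16, 0.60)   # clade A, clade B
    sigma: float = 0.15            # residual sd of log10 lifespan
    lam: float = 1.0               # Pagel's lambda of the residuals
    mass_log10_range: tuple[float, float] = (0.5, 5.0)   # log10 grams

    mssmr_slope: float = -0.83     # log10 msSMR per log10 lifespan
    mssmr_intercept: float = -0.31
    mssmr_sigma: float = 0.2
    k_slope: float = -0.692        # log10 K per log10 lifespan
    k_intercept: float = -1.171
    k_sigma: float = 0.2

    p_miss: float = 0.1            # per-section chance an increment is missed
    p_accessory: float = 0.02      # Poisson rate of spurious extra increments
    foramen_log_mu: float = -3.0   # ln mm; median radius ~0.05 mm
    foramen_log_sigma: float = 0.4

    seed: int = 0

    def __post_init__(self):
        if self.n_tips < 2:
            raise ValueError("n_tips must be at least 2")
        if not (0.0 <= self.lam <= 1.0):
            raise ValueError("lambda must lie in [0, 1]")
        for name in ("sigma", "mssmr_sigma", "k_sigma"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        for name in ("p_miss", "p_accessory"):
            if not (0.0 <= getattr(self, name) <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.birth_rate <= 0 or self.tree_height <= 0:
            raise ValueError("birth_rate and tree_height must be positive")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


# ---------------------------------------------------------------------------
# trees


def _yule_newick(n_tips: int, rate: float, height: float,
                 rng: np.random.Generator, prefix: str) -> str:
    """Pure-birth tree conditioned on ``n_tips``, rescaled to ``height``.

    The root splits at time zero; with ``k`` lineages the next split waits
    Exp(rate*k) and hits a uniformly chosen lineage.  After the last split
    the tree is extended by one more exponential wait and all node times are
    rescaled so the root-to-tip depth equals ``height``.
    """
    # node: [birth_time, end_time, children or tip-id]
    root = [0.0, None, []]
    active = []
    for _ in range(2):
        child = [0.0, None, []]
        root[2].append(child)
        active.append(child)
    t = 0.0
    while len(active) < n_tips:
        t += rng.exponential(1.0 / (rate * len(active)))
        i = rng.integers(len(active))
        node = active.pop(i)
        node[1] = t
        for _ in range(2):
            child = [t, None, []]
            node[2].append(child)
            active.append(child)
    t_end = t + rng.exponential(1.0 / (rate * len(active)))
    scale = height / t_end
    labels = iter(f"{prefix}{i + 1}" for i in range(n_tips))

    def render(node) -> str:
        start = node[0] * scale
        end = (node[1] if node[1] is not None else t_end) * scale
        if not node[2] or node[1] is None:  # leaf lineage
            return f"{next(labels)}:{end - start:.12g}"
        inner = ",".join(render(c) for c in node[2])
        return f"({inner}):{end - start:.12g}"

    inner = ",".join(render(c) for c in root[2])
    return f"({inner});"


def simulate_tree(config: SimConfig, rng: np.random.Generator | None = None,
                  prefix: str = "t") -> PhyloTree:
    """One ultrametric pure-birth (Yule) clade with ``config.n_tips`` tips."""
    rng = config.rng() if rng is None else rng
    text = _yule_newick(config.n_tips, config.birth_rate, config.tree_height,
                        rng, prefix)
    return parse_newick(text)


def simulate_two_clade_tree(
    config: SimConfig, rng: np.random.Generator | None = None
) -> tuple[PhyloTree, dict[str, str]]:
    """Two Yule clades grafted at ``config.graft_age``; returns (tree, clade map).

    Clade "A" tips are named ``A1..An``, clade "B" tips ``B1..Bn``.
    """
    from .phylo import graft_clades

    rng = config.rng() if rng is None else rng
    a = simulate_tree(config, rng, prefix="A")
    b = simulate_tree(config, rng, prefix="B")
    tree = graft_clades(a, b, config.graft_age)
    clades = {tip: tip[0] for tip in tree.tip_labels}
    return tree, clades


# ---------------------------------------------------------------------------
# traits


def _mvn_phylo(rng: np.random.Generator, V: np.ndarray, sigma: float) -> np.ndarray:
    """Draw from N(0, sigma^2 V) via Cholesky, with a 1e-10 diagonal jitter
    retry if the factorization fails."""
    if sigma == 0.0:
        return np.zeros(V.shape[0])
    try:
        L = np.linalg.cholesky(V)
    except np.linalg.LinAlgError:
        L = np.linalg.cholesky(V + 1e-10 * np.eye(V.shape[0]))
    return sigma * (L @ rng.standard_normal(V.shape[0]))


def simulate_traits(
    tree: PhyloTree,
    config: SimConfig,
    clades: dict[str, str] | None = None,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Trait table with phylogenetically correlated residuals.

    log10 mass is uniform on ``config.mass_log10_range``; log10 lifespan is
    ``a_clade + b * log10 mass + eps`` with ``eps ~ N(0, sigma^2 V(lambda))``
    where ``V`` comes from :func:`paleophys.phylo.vcv_from_tree` on the same
    tree (shared code path).  log10 msSMR and log10 K are linear in log10
    lifespan with their own residual draws under the same covariance.
    """
    rng = config.rng() if rng is None else rng
    tips = tree.tip_labels
    if clades is None:
        clades = {t: "A" for t in tips}
    labels = sorted(set(clades.values()))
    if len(labels) > 2:
        raise ValueError("at most two clades are supported")
    intercept_of = {lab: config.intercepts[i] for i, lab in enumerate(labels)}

    # correlation-scaled covariance so sigma is the marginal residual sd
    V = vcv_from_tree(tree, config.lam).correlation()

    log_mass = rng.uniform(*config.mass_log10_range, size=len(tips))
    a = np.array([intercept_of[clades[t]] for t in tips])
    log_life = a + config.slope * log_mass + _mvn_phylo(rng, V, config.sigma)
    log_mssmr = (config.mssmr_intercept + config.mssmr_slope * log_life
                 + _mvn_phylo(rng, V, config.mssmr_sigma))
    log_k = (config.k_intercept + config.k_slope * log_life
             + _mvn_phylo(rng, V, config.k_sigma))

    return pd.DataFrame(
        {
            "clade": [clades[t] for t in tips],
            "mass_g": 10.0 ** log_mass,
            "lifespan_yr": 10.0 ** log_life,
            "mssmr": 10.0 ** log_mssmr,
            "k_per_day": 10.0 ** log_k,
        },
        index=pd.Index(tips, name="species"),
    )


# ---------------------------------------------------------------------------
# increment tables


def simulate_increment_table(
    config: SimConfig,
    true_ages,
    rng: np.random.Generator | None = None,
    n_observers: int = 3,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Observer-noisy increment counts plus a ground-truth sidecar.

    Each specimen gets 3-5 sections read by ``n_observers`` observers; every
    reading is ``true_age - Bernoulli(p_miss) + Poisson(p_accessory)``
    floored at 1 (cementum starts at eruption, so a count is never zero).
    Returns ``(table, truth)`` where ``truth`` maps specimen to true age.
    """
    true_ages = [int(a) for a in true_ages]
    if not true_ages:
        raise ValueError("true_ages must be non-empty")
    if min(true_ages) < 1:
        raise ValueError("true ages must be >= 1")
    rng = config.rng() if rng is None else rng

    records = []
    for s, age in enumerate(true_ages, start=1):
        specimen = f"spec{s:03d}"
        n_sections = int(rng.integers(3, 6))
        for obs in range(1, n_observers + 1):
            for sec in range(1, n_sections + 1):
                count = (age
                         - int(rng.random() < config.p_miss)
                         + int(rng.poisson(config.p_accessory)))
                records.append((specimen, "m2", f"obs{obs}", sec, max(count, 1)))
    table = pd.DataFrame(
        records, columns=["specimen", "element", "observer", "section", "count"]
    )
    truth = pd.DataFrame(
        {"specimen": [f"spec{s:03d}" for s in range(1, len(true_ages) + 1)],
         "true_age": true_ages}
    )
    return table, truth


# ---------------------------------------------------------------------------
# on-disk bundle


def write_dataset(config: SimConfig, outdir, true_ages=None) -> dict[str, str]:
    """Write a complete synthetic study (tree, traits, increments, truth) to
    ``outdir`` and return the file paths."""
    import os

    os.makedirs(outdir, exist_ok=True)
    rng = config.rng()
    tree, clades = simulate_two_clade_tree(config, rng)
    traits = simulate_traits(tree, config, clades, rng)
    if true_ages is None:
        true_ages = list(rng.integers(1, 16, size=30))
    increments, truth = simulate_increment_table(config, true_ages, rng)

    from .phylo import write_newick

    paths = {
        "tree": os.path.join(outdir, "tree.nwk"),
        "traits": os.path.join(outdir, "traits.csv"),
        "increments": os.path.join(outdir, "increments.csv"),
        "truth": os.path.join(outdir, "increments_truth.csv"),
    }
    with open(paths["tree"], "w") as fh:
        fh.write(write_newick(tree) + "\n")
    traits.to_csv(paths["traits"])
    increments.to_csv(paths["increments"], index=False)
    truth.to_csv(paths["truth"], index=False)
    return paths
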