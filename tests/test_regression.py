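"""PGLS core: OLS equivalence, closed-form oracle, lambda profile sanity,
tree selection, the ANCOVA ladder, and interval behaviour."""

import shutil
import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest

from paleophys.phylo import parse_newick, vcv_from_tree
from paleophys.regression import (
    fit_auto,
    fit_gls_plain,
    fit_over_trees,
    fit_pgls,
    phylo_ancova,
    predict_with_intervals,
    reml_loglik,
)
from paleophys.simulate import (
    SimConfig,
    simulate_traits,
    simulate_tree,
    simulate_two_clade_tree,
)


def _sim_xy(n_tips=30, seed=0, lam=1.0, sigma=0.15):
    cfg = SimConfig(n_tips=n_tips, seed=seed, lam=lam, sigma=sigma)
    tree = simulate_tree(cfg)
    traits = simulate_traits(tree, cfg)
    return tree, np.log10(traits["mass_g"]), np.log10(traits["lifespan_yr"]), cfg


class TestPGLSCore:
    def test_lambda_zero_equals_ols(self):
        import statsmodels.api as sm

        tree, x, y, _ = _sim_xy(seed=1)
        fit = fit_pgls(x, y, tree, lambda_mode=0.0)
        ols = sm.OLS(y.loc[fit.species],
                     sm.add_constant(x.loc[fit.species])).fit()
        assert fit.slope == pytest.approx(ols.params.iloc[1], abs=1e-8)
        assert fit.intercept == pytest.approx(ols.params.iloc[0], abs=1e-8)
        assert fit.se_slope == pytest.approx(ols.bse.iloc[1], abs=1e-8)
        assert fit.fstat == pytest.approx(ols.fvalue, rel=1e-8)

    def test_closed_form_oracle_small_n(self):
        """Explicit-inversion GLS on n <= 6 tips matches to 1e-10."""
        for seed in range(5):
            cfg = SimConfig(n_tips=6, seed=seed, lam=1.0, sigma=0.2)
            tree = simulate_tree(cfg)
            traits = simulate_traits(tree, cfg)
            x = np.log10(traits["mass_g"])
            y = np.log10(traits["lifespan_yr"])
            lam = 0.7
            fit = fit_pgls(x, y, tree, lambda_mode=lam)

            v = vcv_from_tree(tree, 1.0)
            C = v.correlation() * lam
            np.fill_diagonal(C, 1.0)
            Ci = np.linalg.inv(C)
            X = np.column_stack([np.ones(6), x.loc[v.taxa]])
            yv = y.loc[v.taxa].to_numpy()
            beta = np.linalg.inv(X.T @ Ci @ X) @ X.T @ Ci @ yv
            assert fit.intercept == pytest.approx(beta[0], abs=1e-10)
            assert fit.slope == pytest.approx(beta[1], abs=1e-10)

    def test_species_mismatch_lists_names(self):
        tree, x, y, _ = _sim_xy()
        x2 = x.drop(x.index[:2])
        with pytest.raises(ValueError, match=x.index[0]):
            fit_pgls(x2, y, tree)

    def test_reml_profile_beats_grid(self):
        """The estimated lambda's restricted likelihood is >= the grid."""
        for lam_true in (0.0, 0.5, 1.0):
            tree, x, y, _ = _sim_xy(n_tips=40, seed=3, lam=lam_true, sigma=0.3)
            fit = fit_pgls(x, y, tree, lambda_mode="estimate")
            for lam in (0.0, 0.5, 1.0):
                assert fit.reml_loglik >= reml_loglik(x, y, tree, lam) - 1e-8

    def test_plain_gls_equals_lambda_zero(self):
        tree, x, y, _ = _sim_xy(seed=4)
        f0 = fit_pgls(x, y, tree, lambda_mode=0.0)
        fp = fit_gls_plain(x.loc[f0.species], y.loc[f0.species])
        assert fp.slope == pytest.approx(f0.slope, abs=1e-10)
        assert fp.intercept == pytest.approx(f0.intercept, abs=1e-10)
        assert fp.sigma2 == pytest.approx(f0.sigma2, abs=1e-10)

    def test_auto_fallback_on_independent_data(self):
        tree, x, y, _ = _sim_xy(n_tips=60, seed=5, lam=0.0, sigma=0.3)
        fit = fit_auto(x, y, tree, lambda_threshold=0.2)
        # independent residuals: lambda estimate small, plain model returned
        assert fit.model == "gls"

    def test_matches_r_gls_corpagel(self, tmp_path):
        """Independent oracle: nlme::gls with ape::corPagel at fixed lambda."""
        if shutil.which("Rscript") is None:
            pytest.skip("Rscript not available")
        from paleophys.phylo import write_newick

        tree, x, y, _ = _sim_xy(n_tips=20, seed=6, lam=1.0, sigma=0.3)
        fit = fit_pgls(x, y, tree, lambda_mode=0.7)
        (tmp_path / "tree.nwk").write_text(write_newick(tree) + "\n")
        pd.DataFrame({"x": x, "y": y}).to_csv(tmp_path / "dat.csv",
                                              index_label="species")
        script = textwrap.dedent("""
            suppressMessages({library(ape); library(nlme)})
            tree <- read.tree("tree.nwk")
            dat <- read.csv("dat.csv", row.names = 1)
            dat <- dat[tree$tip.label, ]
            cs <- corPagel(0.7, phy = tree, fixed = TRUE)
            m <- gls(y ~ x, data = dat, correlation = cs)
            cat(sprintf("%.12f %.12f\\n", coef(m)[1], coef(m)[2]))
        """)
        (tmp_path / "oracle.R").write_text(script)
        out = subprocess.run(["Rscript", "oracle.R"], cwd=tmp_path,
                             capture_output=True, text=True, check=True)
        r_int, r_slope = map(float, out.stdout.split())
        assert fit.intercept == pytest.approx(r_int, abs=1e-6)
        assert fit.slope == pytest.approx(r_slope, abs=1e-6)


class TestTreeSelection:
    def test_single_tree(self):
        tree, x, y, _ = _sim_xy(seed=7)
        sel = fit_over_trees(x, y, [tree])
        assert sel.index == 0
        assert sel.f_values == [sel.fit.fstat]

    def test_tie_break_lowest_index(self):
        tree, x, y, _ = _sim_xy(seed=8)
        sel = fit_over_trees(x, y, [tree, tree.copy(), tree.copy()])
        assert sel.index == 0
        assert max(sel.f_values) - min(sel.f_values) < 1e-6 * max(sel.f_values)

    def test_empty_sequence_raises(self):
        tree, x, y, _ = _sim_xy()
        with pytest.raises(ValueError):
            fit_over_trees(x, y, [])

    def test_generating_tree_preferred(self):
        """Among candidate trees, the data-generating tree wins the F race
        more often than the 1-in-k chance level."""
        k, reps, wins = 8, 20, 0
        for rep in range(reps):
            cfg = SimConfig(n_tips=30, seed=rep, lam=1.0, sigma=0.4)
            gen_tree = simulate_tree(cfg)
            traits = simulate_traits(gen_tree, cfg)
            x = np.log10(traits["mass_g"])
            y = np.log10(traits["lifespan_yr"])
            others = [simulate_tree(SimConfig(n_tips=30, seed=1000 + rep * k + i))
                      for i in range(k - 1)]
            sel = fit_over_trees(x, y, [gen_tree] + others,
                                 lambda_mode=1.0)
            wins += sel.index == 0
        assert wins / reps > 1.0 / k + 0.1


class TestIntervals:
    def test_ci_narrowest_at_mean_x(self):
        tree, x, y, _ = _sim_xy(seed=9)
        fit = fit_pgls(x, y, tree, lambda_mode=0.0)
        grid = np.linspace(x.min(), x.max(), 41)
        bands = predict_with_intervals(fit, grid)
        widths = bands.ci_hi - bands.ci_lo
        xbar = float(np.mean(fit.x))
        assert abs(grid[np.argmin(widths)] - xbar) <= (grid[1] - grid[0])

    def test_zero_noise_pi_equals_ci(self):
        cfg = SimConfig(n_tips=10, seed=10, sigma=0.0)
        tree = simulate_tree(cfg)
        traits = simulate_traits(tree, cfg)
        fit = fit_gls_plain(np.log10(traits["mass_g"]),
                            np.log10(traits["lifespan_yr"]))
        bands = predict_with_intervals(fit, 2.0)
        assert bands.pi_hi - bands.pi_lo == pytest.approx(
            bands.ci_hi - bands.ci_lo, abs=1e-8)

    def test_pi_contains_ci(self):
        tree, x, y, _ = _sim_xy(seed=11)
        fit = fit_pgls(x, y, tree)
        bands = predict_with_intervals(fit, np.linspace(0, 5, 11))
        assert (bands.pi_lo <= bands.ci_lo).all()
        assert (bands.pi_hi >= bands.ci_hi).all()


class TestAncova:
    def test_loglik_monotone_in_parameters(self):
        cfg = SimConfig(n_tips=15, seed=12)
        tree, clades = simulate_two_clade_tree(cfg)
        traits = simulate_traits(tree, cfg, clades)
        ladder = phylo_ancova(np.log10(traits["mass_g"]),
                              np.log10(traits["lifespan_yr"]),
                              traits["clade"], tree)
        lls = {m.n_params: m.loglik for m in ladder.models.values()}
        assert lls[3] >= lls[2] - 1e-8
        assert lls[4] >= lls[3] - 1e-8
        assert lls[4] >= max(lls[2], lls[3]) - 1e-8

    def test_detects_intercept_shift_not_slope(self):
        """Equal slopes, well-separated intercepts: the intercept rung is
        selected and the slope rung is not significant."""
        cfg = SimConfig(n_tips=30, seed=13, sigma=0.1,
                        intercepts=(0.16, 0.16 + 0.5))
        tree, clades = simulate_two_clade_tree(cfg)
        traits = simulate_traits(tree, cfg, clades)
        ladder = phylo_ancova(np.log10(traits["mass_g"]),
                              np.log10(traits["lifespan_yr"]),
                              traits["clade"], tree)
        assert ladder.comparisons.loc["intercepts", "p"] < 0.05
        assert ladder.comparisons.loc["slopes", "p"] > 0.05

    def test_small_group_rejected(self):
        cfg = SimConfig(n_tips=10, seed=14)
        tree = simulate_tree(cfg)
        traits = simulate_traits(tree, cfg)
        group = pd.Series("A", index=traits.index)
        group.iloc[:2] = "B"
        with pytest.raises(ValueError, match="fewer than 3"):
            phylo_ancova(np.log10(traits["mass_g"]),
                         np.log10(traits["lifespan_yr"]), group, tree)

    def test_plain_ancova_matches_lambda_zero(self):
        cfg = SimConfig(n_tips=12, seed=15)
        tree, clades = simulate_two_clade_tree(cfg)
        traits = simulate_traits(tree, cfg, clades)
        x = np.log10(traits["mass_g"])
        y = np.log10(traits["lifespan_yr"])
        plain = fit_gls_plain(x, y, traits["clade"])
        phylo = phylo_ancova(x, y, traits["clade"], tree, lambda_mode=0.0)
        for label in plain.models:
            for name, value in plain.models[label].params.items():
                assert phylo.models[label].params[name] == pytest.approx(
                    value, abs=1e-8)
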