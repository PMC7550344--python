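"""Configuration-driven orchestration of the inference chain.

Stages run in dependency order: cementochronology (increment tables to
lifespans), allometry (dentary lengths to mass brackets), comparative fits
(PGLS / ANCOVA on extant trait tables), fossil projection (lifespans onto
the lifespan-trait fits), and blood flow (foramen tables to Qi and group
regressions).  A stage runs only when its inputs are configured; missing
inputs for a requested stage fail fast naming the stage.  Every
paper-gap decision (consensus rule, lambda threshold, captive offsets, Qi
radius rule) is a config key, so sensitivity analyses are one-flag
changes, and the run log records the settings in force.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from . import __version__
from .allometry import estimate_fossil_mass
from .bloodflow import ForamenSet, blood_flow_index, qi_group_regression, \
    position_fossil
from .cementum import IncrementTable, agreement_stats, taxon_max_lifespan
from .fossil import CAPTIVE_OFFSET_YR, FossilProfile, captive_adjust, \
    pi_membership, project_trait
from .phylo import parse_newick, prune_to_taxa
from .regression import fit_auto, fit_over_trees, phylo_ancova

__all__ = ["RunConfig", "ValidationReport", "PipelineError",
           "validate_inputs", "run_pipeline"]


class PipelineError(RuntimeError):
    pass


@dataclass
class RunConfig:
    """All inputs and decision knobs for one pipeline run."""

    outdir: str = "paleophys_out"
    trait_csv: str | None = None        # species,clade,mass_g,lifespan_yr[,mssmr,k_per_day]
    tree_path: str | None = None        # one Newick file or a directory of them
    increment_csv: str | None = None    # specimen[,taxon],element,observer,section,count
    fossil_csv: str | None = None       # taxon,dentary_mm[,lifespan_yr]
    foramen_csv: str | None = None      # specimen,group,femur_length_mm,radii_mm ("a;b")

    seed: int = 0
    consensus_rule: str = "median"
    lambda_threshold: float = 1e-3
    qi_rule: str = "sum_radii"
    use_captive_offsets: bool = False
    captive_offsets: dict = field(default_factory=lambda: dict(CAPTIVE_OFFSET_YR))
    display_decimals: int = 1


@dataclass
class ValidationReport:
    findings: list[tuple[str, str]] = field(default_factory=list)  # (severity, message)

    def add(self, severity: str, message: str) -> None:
        self.findings.append((severity, message))

    @property
    def fatal(self) -> list[str]:
        return [m for s, m in self.findings if s == "fatal"]

    @property
    def warnings(self) -> list[str]:
        return [m for s, m in self.findings if s == "warning"]


def _load_trees(path):
    if os.path.isdir(path):
        files = sorted(f for f in os.listdir(path)
                       if f.endswith((".nwk", ".newick", ".tre", ".tree")))
        trees = []
        for f in files:
            with open(os.path.join(path, f)) as fh:
                t = parse_newick(fh.read(), label=f)
            trees.append(t)
        return trees
    with open(path) as fh:
        return [parse_newick(fh.read(), label=os.path.basename(path))]


def validate_inputs(config: RunConfig) -> ValidationReport:
    """Schema, unit-sanity and tree/table-overlap checks.  Always returns a
    report; fatal findings are flagged, never raised here."""
    report = ValidationReport()
    for name in ("trait_csv", "increment_csv", "fossil_csv", "foramen_csv",
                 "tree_path"):
        path = getattr(config, name)
        if path is not None and not os.path.exists(path):
            report.add("fatal", f"{name} does not exist: {path}")

    traits = None
    if config.trait_csv and os.path.exists(config.trait_csv):
        traits = pd.read_csv(config.trait_csv)
        needed = {"species", "clade", "mass_g", "lifespan_yr"}
        missing = needed - set(traits.columns)
        if missing:
            report.add("fatal", f"trait table lacks columns {sorted(missing)}")
        else:
            for col in ("mass_g", "lifespan_yr"):
                bad = traits[traits[col] <= 0]
                if not bad.empty:
                    report.add("fatal",
                               f"non-positive {col} for species "
                               f"{bad['species'].tolist()}")
            if (traits["mass_g"] < 0.1).any():
                report.add("warning", "masses below 0.1 g; are units grams?")

    if config.tree_path and os.path.exists(config.tree_path) and traits is not None \
            and "species" in traits.columns:
        try:
            trees = _load_trees(config.tree_path)
        except Exception as exc:
            report.add("fatal", f"could not read tree(s): {exc}")
        else:
            from .phylo import normalize_label

            species = {normalize_label(s) for s in traits["species"]}
            tips = set(trees[0].tip_labels)
            unmatched = sorted(species - tips)
            if unmatched:
                report.add("warning",
                           f"{len(unmatched)}/{len(species)} trait species "
                           f"not in tree: {', '.join(unmatched[:10])}")

    if config.increment_csv and os.path.exists(config.increment_csv):
        try:
            IncrementTable.from_csv(config.increment_csv)
        except Exception as exc:
            report.add("fatal", f"increment table invalid: {exc}")

    if config.foramen_csv and os.path.exists(config.foramen_csv):
        fdf = pd.read_csv(config.foramen_csv)
        needed = {"specimen", "group", "femur_length_mm", "radii_mm"}
        missing = needed - set(fdf.columns)
        if missing:
            report.add("fatal", f"foramen table lacks columns {sorted(missing)}")
    return report


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    raise TypeError(f"not JSON serializable: {type(o)}")


def _write_json(path, obj) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, default=_json_default)


def _fit_summary(fit) -> dict:
    return {
        "slope": fit.slope, "intercept": fit.intercept,
        "ci95_slope": fit.ci95_slope, "r2": fit.r2, "F": fit.fstat,
        "p": fit.pvalue, "lambda": fit.lam, "sigma2": fit.sigma2,
        "n": fit.n, "model": fit.model, "tree": fit.tree_id,
    }


def run_pipeline(config: RunConfig) -> dict:
    """Execute all configured stages; returns the report bundle (also
    written as JSON/CSV files under ``config.outdir``)."""
    report = validate_inputs(config)
    if report.fatal:
        raise PipelineError("input validation failed: " + "; ".join(report.fatal))
    os.makedirs(config.outdir, exist_ok=True)
    bundle: dict = {"stages": [], "skipped": [], "warnings": report.warnings}

    # -- cementochronology ------------------------------------------------
    lifespans: dict[str, int] = {}
    if config.increment_csv:
        raw = pd.read_csv(config.increment_csv)
        taxa = raw["taxon"].unique() if "taxon" in raw.columns else ["taxon"]
        stats_out = {}
        for taxon in taxa:
            sub = raw[raw["taxon"] == taxon] if "taxon" in raw.columns else raw
            table = IncrementTable(sub)
            lifespans[str(taxon)] = taxon_max_lifespan(
                table, rule=config.consensus_rule)
            ag = agreement_stats(table)
            stats_out[str(taxon)] = {
                "max_lifespan_yr": lifespans[str(taxon)],
                "mean_cv_across_observers": ag.mean_cv_across,
                "mean_cv_within_observers": ag.mean_cv_within,
            }
        _write_json(os.path.join(config.outdir, "lifespan.json"), stats_out)
        bundle["lifespan"] = stats_out
        bundle["stages"].append("cementochronology")
    else:
        bundle["skipped"].append("cementochronology")

    # -- allometry --------------------------------------------------------
    masses: dict[str, dict] = {}
    if config.fossil_csv:
        fossils = pd.read_csv(config.fossil_csv)
        rows = []
        for _, row in fossils.iterrows():
            est = estimate_fossil_mass(str(row["taxon"]), float(row["dentary_mm"]))
            masses[est.taxon] = {
                "mass_min_g": est.mass_min_g,
                "mass_max_g": est.mass_max_g,
                "mass_mean_g": est.mass_mean_g,
            }
            rows.append(est.rounded(config.display_decimals))
        pd.DataFrame(rows).to_csv(
            os.path.join(config.outdir, "allometry.csv"), index=False)
        bundle["allometry"] = masses
        bundle["stages"].append("allometry")
        if "lifespan_yr" in fossils.columns:
            for _, row in fossils.iterrows():
                lifespans.setdefault(str(row["taxon"]), int(row["lifespan_yr"]))
    else:
        bundle["skipped"].append("allometry")

    # -- comparative fits -------------------------------------------------
    fits: dict[str, object] = {}
    if config.trait_csv and config.tree_path:
        traits = pd.read_csv(config.trait_csv).set_index("species")
        from .phylo import normalize_label

        traits.index = [normalize_label(s) for s in traits.index]
        trees = _load_trees(config.tree_path)
        fit_report = {}
        for clade, sub in traits.groupby("clade"):
            pruned = [prune_to_taxa(t, sub.index) for t in trees]
            x = np.log10(sub["mass_g"])
            y = np.log10(sub["lifespan_yr"])
            if len(pruned) > 1:
                sel = fit_over_trees(x, y, pruned)
                fit = sel.fit
            else:
                fit = fit_auto(x, y, pruned[0],
                               lambda_threshold=config.lambda_threshold)
            fits[f"{clade}_lifespan_on_mass"] = fit
            life = np.log10(sub["lifespan_yr"])
            for trait_col, tag in (("mssmr", "mssmr"), ("k_per_day", "k")):
                if trait_col in sub.columns and sub[trait_col].notna().all():
                    fits[f"{clade}_{tag}_on_lifespan"] = fit_auto(
                        life, np.log10(sub[trait_col]), pruned[0],
                        lambda_threshold=config.lambda_threshold)
        fit_report = {k: _fit_summary(f) for k, f in fits.items()}
        clades = sorted(traits["clade"].unique())
        if len(clades) == 2:
            ladder = phylo_ancova(np.log10(traits["mass_g"]),
                                  np.log10(traits["lifespan_yr"]),
                                  traits["clade"], _load_trees(config.tree_path)[0])
            fit_report["ancova_lifespan_on_mass"] = {
                "selected": ladder.selected,
                "lambda": ladder.lam,
                "comparisons": ladder.comparisons.reset_index().to_dict("records"),
            }
        _write_json(os.path.join(config.outdir, "fits.json"), fit_report)
        bundle["fits"] = fit_report
        bundle["stages"].append("comparative_fits")
    else:
        bundle["skipped"].append("comparative_fits")

    # -- fossil projection ------------------------------------------------
    if masses and lifespans and fits:
        profiles = {}
        for taxon, mass in masses.items():
            if taxon not in lifespans:
                continue
            life = lifespans[taxon]
            profile = FossilProfile(
                taxon=taxon, lifespan_yr=life,
                mass_min_g=mass["mass_min_g"], mass_max_g=mass["mass_max_g"],
                mass_mean_g=mass["mass_mean_g"],
            )
            for clade in ("mammal", "reptile"):
                used_life = (captive_adjust(life, clade, config.captive_offsets)
                             if config.use_captive_offsets else life)
                key = f"{clade}_mssmr_on_lifespan"
                if key in fits:
                    setattr(profile, f"mssmr_{clade}",
                            project_trait(fits[key], used_life))
                key = f"{clade}_k_on_lifespan"
                if key in fits:
                    setattr(profile, f"k_{clade}",
                            project_trait(fits[key], used_life))
                key = f"{clade}_lifespan_on_mass"
                if key in fits:
                    member = pi_membership(fits[key], mass["mass_mean_g"], life)
                    profile.pi_flags[f"lifespan_vs_{clade}"] = member.classification
            profiles[taxon] = profile.to_dict()
        _write_json(os.path.join(config.outdir, "profiles.json"), profiles)
        bundle["profiles"] = profiles
        bundle["stages"].append("fossil_projection")
    else:
        bundle["skipped"].append("fossil_projection")

    # -- blood flow -------------------------------------------------------
    if config.foramen_csv:
        fdf = pd.read_csv(config.foramen_csv)
        qi_rows = []
        for _, row in fdf.iterrows():
            radii = tuple(float(r) for r in str(row["radii_mm"]).split(";"))
            fs = ForamenSet(str(row["specimen"]), str(row["group"]),
                            float(row["femur_length_mm"]), radii)
            qi_rows.append({"specimen": fs.specimen, "group": fs.group,
                            "qi_mm3": blood_flow_index(fs, rule=config.qi_rule)})
        qi_df = pd.DataFrame(qi_rows)
        qi_df.to_csv(os.path.join(config.outdir, "bloodflow.csv"), index=False)
        out = {"qi": qi_rows}
        if "mass_g" in fdf.columns:
            reg_table = fdf.assign(
                qi=qi_df["qi_mm3"].to_numpy()).set_index("specimen")
            extant = reg_table[reg_table["group"] != "fossil"]
            if extant["group"].nunique() >= 1 and \
                    extant.groupby("group").size().min() >= 3:
                group_fits = qi_group_regression(extant)
                out["fits"] = {g: _fit_summary(f) for g, f in group_fits.items()}
                fossil_rows = reg_table[reg_table["group"] == "fossil"]
                positions = {}
                for spec, row in fossil_rows.iterrows():
                    pos = position_fossil(group_fits, row["mass_g"], row["qi"])
                    positions[str(spec)] = (
                        pos[pos["species"] == "<fossil>"]
                        .set_index("group")["residual"].to_dict())
                out["fossil_positions"] = positions
        _write_json(os.path.join(config.outdir, "bloodflow.json"), out)
        bundle["bloodflow"] = out
        bundle["stages"].append("bloodflow")
    else:
        bundle["skipped"].append("bloodflow")

    # -- run log ----------------------------------------------------------
    log = {
        "version": __version__,
        "config": {k: v for k, v in asdict(config).items()},
        "stages_run": bundle["stages"],
        "stages_skipped": bundle["skipped"],
        "warnings": report.warnings,
    }
    _write_json(os.path.join(config.outdir, "run_log.json"), log)
    bundle["run_log"] = log
    return bundle
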