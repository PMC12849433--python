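"""End-to-end pipeline: simulate/load -> scores -> cMetS -> features ->
SCFA pathways -> associations -> mediation.

A single YAML/dict config drives every stage. Requested stages write
tidy TSVs into the output directory, each accompanied by a provenance
JSON (sha256 of the stage inputs and outputs, the seed, the package
version); prerequisite results for a requested stage are computed in
memory without writing. Reruns with an identical config are
byte-identical.

Default covariate sets mirror a cross-sectional diet-microbiome study:
diet->cMetS models adjust for age, sex and study cohort (plus energy
intake for the median-based aMED, which is not kcal-standardized);
diversity/beta-diversity models additionally adjust for BMI, stool form
and sequencing depth; mediation models adjust for age, sex, stool form,
study cohort and energy intake.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
from skbio import TreeNode

from . import __version__
from ._utils import read_tsv, write_tsv
from .associations import (bh_fdr, fit_adjusted_lm, hurdle_diff_abundance,
                           permanova)
from .clinical import cmets
from .diet import score_all
from .features import (beta_diversity, clr, feature_table, filter_genera)
from .mediation import mediation_scan
from .scfa import pathway_abundance
from .synthetic import SimulationParams, generate_cohort

logger = logging.getLogger("dietbiome.pipeline")

__all__ = ["ConfigError", "STAGES", "run_pipeline"]

STAGES = ["scores", "cmets", "features", "pathways", "associations",
          "mediation"]

DIET_INDICES = ["hei_mon", "phei_mon", "amed"]
BASE_COVARIATES = ["age", "sex", "study_cohort"]
DIVERSITY_EXTRA = ["bmi", "bristol", "log_depth"]
MEDIATION_COVARIATES = ["age", "sex", "bristol", "study_cohort",
                        "energy_kcal"]


class ConfigError(ValueError):
    """Invalid pipeline configuration; the message names the field."""


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _provenance(outdir: Path, stage: str, inputs: list[Path],
                outputs: list[Path], seed: int) -> None:
    prov = {
        "stage": stage,
        "seed": seed,
        "version": __version__,
        "inputs": {p.name: _sha256(p) for p in inputs if p.exists()},
        "outputs": {p.name: _sha256(p) for p in outputs},
    }
    (outdir / f"{stage}.prov.json").write_text(
        json.dumps(prov, indent=2, sort_keys=True) + "\n")


def _validate(config: dict, stages: list[str]) -> None:
    for s in stages:
        if s not in STAGES:
            raise ConfigError(f"unknown stage {s!r}")
    if "simulate" in config:
        return
    inputs = config.get("inputs")
    if not inputs:
        raise ConfigError("config needs either a 'simulate' block or an "
                          "'inputs' block")
    needed = {"scores": ["intakes", "cohort"], "cmets": ["cohort"],
              "features": ["genus_counts", "tree"],
              "pathways": ["genus_counts", "traits"],
              "associations": ["cohort", "intakes", "genus_counts", "tree",
                               "traits"],
              "mediation": ["cohort", "intakes", "genus_counts", "tree",
                            "traits"]}
    for s in stages:
        for key in needed[s]:
            if key not in inputs:
                raise ConfigError(f"stage {s!r} requires 'inputs.{key}'")
            if not Path(inputs[key]).exists():
                raise ConfigError(f"'inputs.{key}' path does not exist: "
                                  f"{inputs[key]}")


def _load_data(config: dict, seed: int, outdir: Path):
    if "simulate" in config:
        sim = dict(config.get("simulate") or {})
        sim.setdefault("seed", seed)
        params = SimulationParams(**sim)
        cohort = generate_cohort(params)
        datadir = outdir / "data"
        cohort.write(datadir)
        return (cohort.cohort, cohort.intakes, cohort.genus_counts,
                cohort.tree, cohort.traits,
                [datadir / n for n in ("cohort.tsv", "intakes.tsv",
                                       "genus_counts.tsv", "tree.nwk",
                                       "traits.tsv")])
    inp = config["inputs"]
    cohort = read_tsv(inp["cohort"]) if "cohort" in inp else None
    intakes = read_tsv(inp["intakes"]) if "intakes" in inp else None
    counts = tree = traits = None
    if "genus_counts" in inp:
        counts = read_tsv(inp["genus_counts"], index_col="subject_id")
    if "tree" in inp:
        tree = TreeNode.read(inp["tree"])
    if "traits" in inp:
        traits = read_tsv(inp["traits"], index_col="taxon")
    paths = [Path(v) for v in inp.values()]
    return cohort, intakes, counts, tree, traits, paths


def run_pipeline(config: dict, outdir=None, seed: int | None = None,
                 stages: list[str] | None = None) -> Path:
    """Execute the requested stages (default: all) and return the output
    directory. Validation happens before any computation."""
    stages = list(STAGES) if stages is None else list(stages)
    _validate(config, stages)
    seed = int(config.get("seed", 0) if seed is None else seed)
    outdir = Path(config.get("outdir", "pipeline_out")
                  if outdir is None else outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    cohort, intakes, counts, tree, traits, input_paths = \
        _load_data(config, seed, outdir)

    filt = config.get("filter", {})
    min_prev = float(filt.get("min_prevalence", 0.10))
    min_abund = float(filt.get("min_mean_rel_abund", 0.01))
    n_perm = int(config.get("associations", {}).get("n_perm", 999))
    n_sims = int(config.get("mediation", {}).get("n_sims", 1000))
    n_boot = int(config.get("eds_bootstrap", 20))

    results: dict[str, pd.DataFrame] = {}

    def need_scores():
        if "scores" not in results:
            sex = cohort.set_index("subject_id")["sex"] \
                .loc[intakes["subject_id"]].reset_index(drop=True)
            results["scores"] = score_all(intakes, sex)
        return results["scores"]

    def need_cmets():
        if "cmets" not in results:
            results["cmets"] = cmets(cohort)
        return results["cmets"]

    def need_features():
        if "features" not in results:
            results["features"] = feature_table(counts, tree, seed=seed,
                                                n_boot=n_boot)
            results["distance"] = beta_diversity(counts)
        return results["features"]

    def need_pathways():
        if "pathways" not in results:
            results["pathways"] = pathway_abundance(counts, traits) \
                .rename_axis("subject_id").reset_index()
        return results["pathways"]

    def joined_table():
        df = cohort.merge(need_scores(), on="subject_id") \
                   .merge(need_cmets()[["subject_id", "cmets"]],
                          on="subject_id") \
                   .merge(need_features(), on="subject_id") \
                   .merge(need_pathways(), on="subject_id") \
                   .merge(intakes[["subject_id", "energy_kcal"]],
                          on="subject_id")
        return df

    for stage in STAGES:
        if stage not in stages:
            continue
        logger.info("stage: %s", stage)
        written: list[Path] = []
        if stage == "scores":
            write_tsv(need_scores(), p := outdir / "scores.tsv")
            written = [p]
        elif stage == "cmets":
            write_tsv(need_cmets(), p := outdir / "cmets.tsv")
            written = [p]
        elif stage == "features":
            need_features()
            write_tsv(results["features"], p1 := outdir / "features.tsv")
            write_tsv(results["distance"], p2 := outdir / "distance.tsv",
                      index=True)
            written = [p1, p2]
        elif stage == "pathways":
            write_tsv(need_pathways(), p := outdir / "pathways.tsv")
            written = [p]
        elif stage == "associations":
            written = _run_associations(joined_table(), counts,
                                        results_distance(results, counts),
                                        outdir, seed, n_perm,
                                        min_prev, min_abund)
        elif stage == "mediation":
            written = _run_mediation(joined_table(), counts, outdir, seed,
                                     n_sims, min_prev, min_abund)
        _provenance(outdir, stage, input_paths, written, seed)
    return outdir


def results_distance(results: dict, counts) -> pd.DataFrame:
    if "distance" not in results:
        results["distance"] = beta_diversity(counts)
    return results["distance"]


def _diet_covariates(index: str, extra=()):
    cov = [*BASE_COVARIATES, *extra]
    if index == "amed":   # aMED is not kcal-standardized
        cov = cov + ["energy_kcal"]
    return cov


def _run_associations(df: pd.DataFrame, counts, dist, outdir: Path,
                      seed: int, n_perm: int, min_prev: float,
                      min_abund: float) -> list[Path]:
    rows = []
    # diet -> cMetS (family: diet_cmets)
    fam = []
    for index in DIET_INDICES:
        r = fit_adjusted_lm(df, "cmets", index,
                            covariates=_diet_covariates(index),
                            family="diet_cmets")
        fam.append(r)
    for r, q in zip(fam, bh_fdr([r.p for r in fam])):
        rows.append(("diet_cmets", r.exposure, "cmets", r.std_beta,
                     r.ci_low, r.ci_high, r.p, q, r.n))
    # diet -> alpha diversity / EDS / PB ratio / pathways
    for family, outcomes in (
            ("diet_alpha", ["shannon", "faith_pd"]),
            ("diet_structure", ["eds", "pb_ratio"]),
            ("diet_scfa", ["but", "buk", "acetyl_coa", "pdiol",
                           "succinate"])):
        fam = []
        for index in DIET_INDICES:
            for outcome in outcomes:
                fam.append(fit_adjusted_lm(
                    df, outcome, index,
                    covariates=_diet_covariates(index, DIVERSITY_EXTRA),
                    family=family))
        for r, q in zip(fam, bh_fdr([r.p for r in fam])):
            rows.append((family, r.exposure, r.outcome, r.std_beta,
                         r.ci_low, r.ci_high, r.p, q, r.n))
    # cMetS -> alpha/structure/pathways
    fam = []
    for outcome in ["shannon", "faith_pd", "eds", "pb_ratio", "buk"]:
        fam.append(fit_adjusted_lm(
            df, outcome, "cmets",
            covariates=[*BASE_COVARIATES, "bristol", "log_depth"],
            family="cmets_microbiome"))
    for r, q in zip(fam, bh_fdr([r.p for r in fam])):
        rows.append(("cmets_microbiome", r.exposure, r.outcome, r.std_beta,
                     r.ci_low, r.ci_high, r.p, q, r.n))
    assoc = pd.DataFrame(rows, columns=["family", "exposure", "outcome",
                                        "std_beta", "ci_low", "ci_high",
                                        "p", "q", "n"])
    write_tsv(assoc, p_assoc := outdir / "associations.tsv")

    # PERMANOVA per diet index + cMetS
    dsub = dist.loc[df["subject_id"], df["subject_id"]]
    prows = []
    for term in DIET_INDICES + ["cmets"]:
        cov = [*BASE_COVARIATES, "bmi", "bristol"] if term != "cmets" \
            else [*BASE_COVARIATES, "bristol"]
        if term == "amed":
            cov = cov + ["energy_kcal"]
        res = permanova(dsub.to_numpy(), df, term, covariates=cov,
                        n_perm=n_perm, seed=seed)
        prows.append((term, res.r2, res.pseudo_f, res.p_perm, res.df,
                      res.n_perm))
    perma = pd.DataFrame(prows, columns=["term", "r2", "pseudo_f", "p_perm",
                                         "df", "n_perm"])
    perma["q"] = bh_fdr(perma["p_perm"].to_numpy())
    write_tsv(perma, p_perma := outdir / "permanova.tsv")

    # hurdle differential abundance per diet index and for cMetS
    da_frames = []
    counts_sub = counts.loc[df["subject_id"]]
    data_idx = df.set_index("subject_id")
    for term in DIET_INDICES + ["cmets"]:
        cov = [*BASE_COVARIATES, "bristol"]
        if term == "amed":
            cov = cov + ["energy_kcal"]
        da = hurdle_diff_abundance(counts_sub, data_idx, term,
                                   covariates=cov,
                                   min_prevalence=min_prev,
                                   min_mean_rel_abund=min_abund)
        da.insert(0, "exposure", term)
        da_frames.append(da)
    da_all = pd.concat(da_frames, ignore_index=True)
    write_tsv(da_all, p_da := outdir / "diff_abundance.tsv")
    return [p_assoc, p_perma, p_da]


def _run_mediation(df: pd.DataFrame, counts, outdir: Path, seed: int,
                   n_sims: int, min_prev: float,
                   min_abund: float) -> list[Path]:
    kept = filter_genera(counts.loc[df["subject_id"]], min_prev, min_abund)
    genus_clr = clr(counts.loc[df["subject_id"]])[kept.columns]
    med_df = df.set_index("subject_id").join(
        genus_clr.add_prefix("genus_"))
    feature_meds = ["shannon", "faith_pd", "pb_ratio", "eds",
                    "but", "buk", "acetyl_coa", "pdiol", "succinate"]
    taxa_meds = [f"genus_{g}" for g in kept.columns]
    scan = mediation_scan(med_df.reset_index(), "cmets", DIET_INDICES,
                          feature_meds + taxa_meds,
                          covariates=MEDIATION_COVARIATES,
                          taxa_mediators=taxa_meds, n_sims=n_sims,
                          seed=seed)
    scan["seed"] = seed
    write_tsv(scan, p := outdir / "mediation.tsv")
    return [p]
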