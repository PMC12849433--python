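"""Synthetic cross-sectional diet–microbiome–metabolic-risk cohort.

Emulates the statistical structure of a 269-subject adult cohort (ages
25–76, ~62% female) with genus-level 16S count data, so that every
downstream stage — diet scoring, cMetS, microbiome features, association
testing and causal mediation — can be exercised and validated against a
*known* generating model.

The planted mediation structure is a linear path model on a latent
diet-quality variable ``Q ~ N(0,1)``:

* food-group intakes are log-linear in ``Q`` (so the computed diet indices
  are noisy monotone images of ``Q``);
* a latent mediator ``U = a·Q + ε_m`` drives the log-abundance of a few
  designated "mediator" genera (three beneficial, one risk-associated,
  with opposite signs);
* a metabolic-risk latent ``L = −b·U − c'·Q`` enters every clinical
  marker on top of linear age/sex trends and marker-specific noise.

For this system the true average causal mediation effect of ``Q`` on the
risk latent is ``−a·b``, the direct effect is ``−c'``, and the proportion
mediated is ``a·b / (a·b + c')`` — recorded in the truth block.

Counts are drawn Dirichlet-multinomial around logistic-normal expected
compositions at lognormal sequencing depth, so rows are integer, row sums
equal the drawn depths exactly, and taxa are overdispersed relative to a
plain multinomial. All randomness flows from one root seed through named
child streams (see :mod:`dietbiome._utils`).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from skbio import TreeNode

from ._utils import child_rng, write_tsv

__all__ = [
    "ParameterError",
    "SimulationParams",
    "SyntheticCohort",
    "generate_cohort",
    "generate_tree",
    "simulate_linear_mediation",
    "FOOD_GROUPS",
    "SCFA_PATHWAYS",
]


class ParameterError(ValueError):
    """Invalid simulation parameter; the message names the field."""


SCFA_PATHWAYS = ["but", "buk", "acetyl_coa", "pdiol", "succinate"]

# (log-mean g/day, slope on latent diet quality Q, log-SD)
FOOD_GROUPS: dict[str, tuple[float, float, float]] = {
    "vegetables": (5.30, 0.35, 0.40),
    "fruits": (5.00, 0.30, 0.45),
    "legumes": (3.00, 0.30, 0.60),
    "nuts": (2.70, 0.35, 0.70),
    "whole_grains": (4.10, 0.40, 0.50),
    "cereals": (5.00, 0.10, 0.40),
    "side_dishes": (4.80, 0.00, 0.40),
    "potatoes": (4.40, -0.05, 0.50),
    "dairy": (5.30, 0.05, 0.50),
    "cheese": (3.70, 0.00, 0.50),
    "eggs": (3.20, -0.05, 0.50),
    "fish": (3.40, 0.30, 0.60),
    "poultry": (3.40, 0.00, 0.50),
    "red_processed_meat": (4.40, -0.40, 0.50),
    "free_sugars": (3.90, -0.40, 0.50),
    "vegetable_oils": (3.20, 0.15, 0.40),
    "sweetened_beverages": (5.00, -0.45, 0.80),
}

_BENEFICIAL = ["BeneGenus1", "BeneGenus2", "BeneGenus3"]
_RISK = ["RiskGenus1"]
_SPECIAL_LOGMEAN = {
    "Bacteroides": 3.2,
    "Phocaeicola": 2.2,
    "Prevotella": 2.8,
    "Faecalibacterium": 2.5,
    "BeneGenus1": 1.5,
    "BeneGenus2": 1.2,
    "BeneGenus3": 1.0,
    "RiskGenus1": 1.2,
}

#: number of "common" genera (incl. specials); the remainder form a rare
#: tail, giving ~45 genera past the default 10% / 1% filter at n=120
_N_COMMON = 50


@dataclass(frozen=True)
class SimulationParams:
    """Tunable knobs of the cohort generator.

    ``diet_effect_on_mediator`` (path a), ``mediator_effect_on_outcome``
    (path b) and ``direct_effect`` (path c') are in per-SD units of the
    latent diet-quality variable.
    """

    n_subjects: int = 269
    n_genera: int = 120
    seed: int = 0
    diet_effect_on_mediator: float = 0.5
    mediator_effect_on_outcome: float = 0.4
    direct_effect: float = 0.5
    depth_log_mean: float = 9.9   # exp(9.9) ~ 2.0e4 reads
    depth_log_sd: float = 0.5
    sex_ratio: float = 0.62       # proportion female
    concentration: float = 150.0  # Dirichlet-multinomial overdispersion
    noise_sds: dict = field(default_factory=lambda: {
        "mediator": 0.866,    # SD of e_m in U = a*Q + e_m (Var(U)=1 at a=0.5)
        "clinical": 1.0,      # multiplier on marker-specific noise SDs
        "composition": 0.6,   # logistic-normal per-entry SD
    })

    def validate(self) -> None:
        if self.n_subjects < 10:
            raise ParameterError("n_subjects must be >= 10")
        if self.n_genera < 10:
            raise ParameterError("n_genera must be >= 10")
        if not (0.0 <= self.sex_ratio <= 1.0):
            raise ParameterError("sex_ratio must lie in [0, 1]")
        if self.depth_log_sd <= 0:
            raise ParameterError("depth_log_sd must be > 0")
        if self.concentration <= 0:
            raise ParameterError("concentration must be > 0")
        for key, value in self.noise_sds.items():
            if value <= 0:
                raise ParameterError(f"noise_sds[{key!r}] must be > 0")


@dataclass
class SyntheticCohort:
    """All tables of one simulated study population, plus ground truth."""

    cohort: pd.DataFrame       # covariates + clinical markers, subject_id key
    intakes: pd.DataFrame      # food groups g/day + nutrient totals
    genus_counts: pd.DataFrame  # subjects x genera integer counts
    tree: TreeNode             # phylogeny over the genera
    traits: pd.DataFrame       # genus x SCFA pathway presence
    truth: dict                # planted paths and derived quantities

    def write(self, outdir) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_tsv(self.cohort, outdir / "cohort.tsv")
        write_tsv(self.intakes, outdir / "intakes.tsv")
        counts = self.genus_counts.rename_axis("subject_id").reset_index()
        write_tsv(counts, outdir / "genus_counts.tsv")
        self.tree.write(str(outdir / "tree.nwk"))
        write_tsv(self.traits.rename_axis("taxon").reset_index(),
                  outdir / "traits.tsv")
        (outdir / "truth.json").write_text(
            json.dumps(self.truth, indent=2, sort_keys=True) + "\n")


def _genus_names(n: int) -> list[str]:
    special = list(_SPECIAL_LOGMEAN)
    generic = [f"Genus{i:03d}" for i in range(1, n - len(special) + 1)]
    return special + generic


def generate_tree(genus_names, seed: int) -> TreeNode:
    """Random rooted bifurcating phylogeny over the given genus names.

    Built by sequentially joining uniformly chosen clades; branch lengths
    are shifted exponentials, so every branch is strictly positive.
    """
    names = list(genus_names)
    if len(names) < 2:
        raise ParameterError("n_genera must be >= 2 to build a tree")
    rng = child_rng(seed, "tree")
    nodes = [TreeNode(name=n, length=round(rng.exponential(0.05) + 0.01, 6))
             for n in sorted(names)]
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        right = nodes.pop(j)
        left = nodes.pop(i)
        parent = TreeNode(length=round(rng.exponential(0.05) + 0.01, 6),
                          children=[left, right])
        nodes.append(parent)
    root = nodes[0]
    root.length = None
    return root


def generate_cohort(params: SimulationParams) -> SyntheticCohort:
    """Draw one full synthetic cohort under the planted path model."""
    params.validate()
    n = params.n_subjects
    a = params.diet_effect_on_mediator
    b = params.mediator_effect_on_outcome
    cp = params.direct_effect
    clin_mult = params.noise_sds["clinical"]

    subjects = [f"S{i:04d}" for i in range(1, n + 1)]

    # --- covariates -----------------------------------------------------
    rng = child_rng(params.seed, "covariates")
    female = (rng.random(n) < params.sex_ratio)
    # women in the emulated cohort skew older (median ~61 vs ~49)
    age = np.where(
        female,
        25 + 51 * rng.beta(3.0, 1.5, size=n),
        25 + 51 * rng.beta(2.0, 2.0, size=n),
    )
    study_cohort = rng.choice(["A", "B", "C"], size=n, p=[0.4, 0.35, 0.25])
    bristol = np.clip(np.rint(rng.normal(3.8, 1.2, size=n)), 1, 7).astype(int)

    # --- planted latent paths ------------------------------------------
    rng_q = child_rng(params.seed, "latent")
    Q = rng_q.standard_normal(n)
    U = a * Q + params.noise_sds["mediator"] * rng_q.standard_normal(n)
    L = -b * U - cp * Q          # metabolic-risk latent

    # --- food-group intakes and nutrients ------------------------------
    rng_i = child_rng(params.seed, "intakes")
    intakes = {"subject_id": subjects}
    for group, (mu, beta, sd) in FOOD_GROUPS.items():
        intakes[group] = np.exp(mu + beta * Q + sd * rng_i.standard_normal(n))
    energy = np.exp(np.log(2100) + 0.15 * (~female)
                    + 0.12 * rng_i.standard_normal(n))
    intakes["energy_kcal"] = energy
    intakes["mufa_g"] = np.exp(np.log(30) + 0.15 * Q
                               + 0.20 * rng_i.standard_normal(n))
    intakes["sfa_g"] = np.exp(np.log(32) - 0.15 * Q
                              + 0.20 * rng_i.standard_normal(n))
    intakes["alcohol_g"] = np.exp(np.log(6) + 0.5 * (~female)
                                  + 0.5 * rng_i.standard_normal(n))
    intakes = pd.DataFrame(intakes)

    # --- clinical markers ----------------------------------------------
    rng_c = child_rng(params.seed, "clinical")
    male = (~female).astype(float)
    ac = age - 50.0

    def noise(sd):
        return clin_mult * sd * rng_c.standard_normal(n)

    wc = 88 + 0.15 * ac + 10 * male + 5.0 * L + noise(9.0)
    sbp = 125 + 0.50 * ac + 4 * male + 4.0 * L + noise(11.0)
    dbp = 78 + 0.15 * ac + 2 * male + 2.5 * L + noise(8.0)
    dbp = np.minimum(dbp, sbp - 5.0)  # keep sbp > dbp
    hdl = np.maximum(
        1.55 + 0.002 * ac - 0.25 * male - 0.12 * L + noise(0.28), 0.4)
    tg = np.exp(np.log(1.2) + 0.004 * ac + 0.10 * male + 0.18 * L
                + noise(0.35))
    glucose = np.maximum(
        5.4 + 0.010 * ac + 0.08 * male + 0.12 * L + noise(0.35), 3.5)
    insulin = np.exp(np.log(8) + 0.15 * L + noise(0.40))
    bmi = np.clip(25.5 + 0.03 * ac + 0.5 * male + 1.2 * L + noise(3.0),
                  17.5, 47.6)

    cohort = pd.DataFrame({
        "subject_id": subjects,
        "age": np.round(age, 4),
        "sex": np.where(female, "F", "M"),
        "study_cohort": study_cohort,
        "bristol": bristol,
        "bmi": bmi,
        "wc_cm": wc,
        "sbp_mmhg": sbp,
        "dbp_mmhg": dbp,
        "hdl_mmol": hdl,
        "tg_mmol": tg,
        "glucose_mmol": glucose,
        "insulin_uU_ml": insulin,
    })

    # --- genus counts ---------------------------------------------------
    genera = _genus_names(params.n_genera)
    rng_g = child_rng(params.seed, "genera")
    n_common = min(_N_COMMON, params.n_genera)
    base = np.concatenate([
        rng_g.normal(1.5, 0.4, size=n_common),
        rng_g.normal(-1.5, 0.8, size=params.n_genera - n_common),
    ])
    for name, mu in _SPECIAL_LOGMEAN.items():
        base[genera.index(name)] = mu

    # three community types: Prevotella-, Firmicutes- and
    # Bacteroides/Phocaeicola-dominated compositions
    etype = rng_g.choice(3, size=n, p=[0.26, 0.50, 0.24])
    eta = np.tile(base, (n, 1))
    eta[etype == 0, genera.index("Prevotella")] += 2.2
    eta[etype == 1, genera.index("Faecalibacterium")] += 1.5
    eta[etype == 1, genera.index("Bacteroides")] += 0.3
    eta[etype == 2, genera.index("Bacteroides")] += 1.4
    eta[etype == 2, genera.index("Phocaeicola")] += 0.9
    for g in _BENEFICIAL:
        eta[:, genera.index(g)] += U
    for g in _RISK:
        eta[:, genera.index(g)] -= U
    eta += params.noise_sds["composition"] * rng_g.standard_normal(eta.shape)

    comp = np.exp(eta - eta.max(axis=1, keepdims=True))
    comp /= comp.sum(axis=1, keepdims=True)

    depth = np.maximum(
        np.rint(rng_g.lognormal(params.depth_log_mean, params.depth_log_sd,
                                size=n)), 1000).astype(np.int64)
    counts = np.empty((n, params.n_genera), dtype=np.int64)
    for i in range(n):
        p = rng_g.dirichlet(params.concentration * comp[i] + 1e-9)
        counts[i] = rng_g.multinomial(depth[i], p)
    genus_counts = pd.DataFrame(counts, index=pd.Index(subjects,
                                                       name="subject_id"),
                                columns=genera)

    # --- phylogeny and trait table -------------------------------------
    tree = generate_tree(genera, params.seed)

    rng_t = child_rng(params.seed, "traits")
    base_rate = {"but": 0.15, "buk": 0.10, "acetyl_coa": 0.35,
                 "pdiol": 0.10, "succinate": 0.20}
    traits = pd.DataFrame(
        {p: (rng_t.random(params.n_genera) < r).astype(int)
         for p, r in base_rate.items()},
        index=pd.Index(genera, name="taxon"))[SCFA_PATHWAYS]
    traits.loc[_BENEFICIAL, ["buk", "acetyl_coa"]] = 1
    traits.loc[_RISK, "pdiol"] = 1

    denom = a * b + cp
    truth = {
        "a": a,
        "b": b,
        "c_prime": cp,
        "proportion_mediated": (a * b / denom) if denom != 0 else None,
        "beneficial_genera": _BENEFICIAL,
        "risk_genera": _RISK,
        "seed": params.seed,
        "n_subjects": n,
    }
    return SyntheticCohort(cohort=cohort, intakes=intakes,
                           genus_counts=genus_counts, tree=tree,
                           traits=traits, truth=truth)


def simulate_linear_mediation(n: int, a: float, b: float, c_prime: float,
                              seed: int, sd_m: float = 1.0,
                              sd_y: float = 1.0) -> pd.DataFrame:
    """Direct draw from the planted linear mediation system.

    ``m = a·x + ε_m``, ``y = b·m + c'·x + ε_y`` with standard-normal
    ``x``. The true ACME is ``a·b``, the direct effect ``c'``, and the
    proportion mediated ``a·b / (a·b + c')``.
    """
    if n < 10:
        raise ParameterError("n must be >= 10")
    rng = child_rng(seed, "linear-mediation")
    x = rng.standard_normal(n)
    m = a * x + sd_m * rng.standard_normal(n)
    y = b * m + c_prime * x + sd_y * rng.standard_normal(n)
    return pd.DataFrame({"x": x, "m": m, "y": y})
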