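# dietbiome

A tested, reusable implementation of the computational chain of a
cross-sectional **diet → gut microbiome → metabolic risk** study:
diet-quality scoring, a continuous metabolic-syndrome score, genus-level
microbiome feature engineering, covariate-adjusted association testing,
and quasi-Bayesian causal mediation — exercised end-to-end on a
synthetic cohort generator with *planted*, recoverable mediation
structure.

It is written for nutrition/microbiome epidemiologists who want the full
analysis pipeline of such a study as importable, unit-tested Python
rather than a one-off script collection, and for methodologists who want
a simulation bench where every downstream estimate can be checked
against known ground truth.

## What it computes

**Diet quality.** From food-group intakes (g/day, FFQ-style
`frequency × portion / 28`):

- **HEI-MON** — ten components, each scored 0–100 against intake anchors
  (adequacy / moderation / range-optimum, linear between anchors, per
  1000 kcal), index = mean of components;
- **PHEI-MON** — same machinery with 14 planetary-health components;
- **aMED** — nine binary components: seven adequacy rules score 1 iff
  intake strictly exceeds the pooled sample median (vegetables, legumes,
  fruits, nuts, whole grains, fish, MUFA/SFA ratio), red/processed meat
  scores 1 iff below its median, alcohol scores 1 below sex-specific
  cutoffs (<10 g/d women, <25 g/d men). Range 0–9.

**Metabolic risk.** The continuous metabolic syndrome score

  cMetS = z(WC) + z(MAP) − z(HDL) + z(TG) + z(glucose),

where each z is the standardized residual of the marker regressed on age
and sex by OLS, MAP = DBP + (SBP − DBP)/3, and HOMA-IR =
glucose[mmol/L]·insulin[µU/mL]/22.5 is available as an auxiliary marker.

**Microbiome features.** TSS and CLR (pseudocount 1) normalization,
prevalence/abundance filtering (defaults ≥10% prevalence, ≥1% mean
relative abundance), Shannon diversity (nats), Faith's phylogenetic
diversity, Bray–Curtis dissimilarity of min-shifted CLR values
(Aitchison distance by flag), the Prevotella/Bacteroides log-ratio,
PAM enterotypes on Jensen–Shannon divergence (k = 2 or 3) with fuzzy
memberships, and a bootstrap enterotype-dysbiosis score (EDS-analog,
rescaled to [0, 1]).

**SCFA potential.** Per-sample abundance-weighted share of taxa carrying
each of five short-chain fatty-acid pathways (*but*, *buk*, acetyl-CoA,
*pdiol*, succinate), from a taxon × pathway trait table.

**Statistics.** Standardized-beta OLS with delta-method CIs, BH-FDR and
Bonferroni adjustment with explicit test families, covariate-adjusted
PERMANOVA (marginal SS, Freedman–Lane permutation), partial Spearman
correlation, two-part (hurdle) differential abundance (logistic
presence/absence + OLS on log relative abundance among non-zeros), and
quasi-Bayesian Monte-Carlo mediation: draw coefficient vectors from each
fitted model's asymptotic normal, per draw ACME = a·b, ADE = c′,
total = a·b + c′, proportion mediated = median ACME/total with a sign
guard.

## Worked example

The numbered scripts under `analysis/` run the full study on the default
synthetic 269-subject cohort (planted paths a = 0.5, b = 0.4, c′ = 0.5,
hence a true per-mediator proportion mediated of
a·b/(a·b + c′) = 28.6%):

```sh
python analysis/01_simulate_cohort.py
python analysis/02_diet_and_metabolic_scores.py
python analysis/04_association_tests.py
python analysis/05_mediation_analysis.py
```

prints, among other lines:

```
simulated n=269 subjects (64% female, median age 56)
median sequencing depth 20398 reads (IQR 14551-28824)
amed: median 5 (IQR 3-7)
hei_mon -> cMetS: std beta -0.46 [-0.57, -0.36], q=1.8e-15
PERMANOVA amed: R2=0.0085, q=0.001
  amed -> genus_BeneGenus1 -> cMetS: ACME -0.119 [-0.184, -0.062], prop. mediated 20.7%, q=0.033
planted mediator genera recovered among significant taxa: ['BeneGenus1', ...]
```

Diet indices are strongly protective against cMetS (that is the planted
direct + indirect effect), composition shifts along diet quality
(PERMANOVA), and the mediation scan ranks exactly the four planted
mediator genera on top — with cohort-level proportions mediated
attenuated below the latent-path truth because the mediator is observed
only through noisy CLR count data.

The same chain is available as a CLI over a YAML config:

```sh
dietbiome run-all --config config.yaml --seed 7 --outdir results/run
```

Every stage writes tidy TSVs plus a provenance JSON (input/output
hashes, seed, version); reruns with the same config are byte-identical.

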