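# Methods

This note documents the models, defaults and design choices behind
`dietbiome`, in the order the pipeline runs them.

## Synthetic cohort generator

The generator (`dietbiome.synthetic`) draws a cross-sectional adult
cohort with the dependency structure the downstream analyses assume.
Defaults emulate a 269-subject population: ages bounded on [25, 76]
(Beta-shaped, women skewing older), 62% female, three study cohorts,
Bristol stool form 1–7, and lognormal sequencing depth
(log-mean 9.9 ≈ 20k reads, log-SD 0.5).

**Planted path model.** A latent diet-quality variable Q ~ N(0,1)
drives everything:

- food-group intakes are log-linear in Q (`FOOD_GROUPS` lists the
  per-group log-mean, slope and log-SD) so the computed diet indices are
  noisy monotone images of Q;
- a latent mediator U = a·Q + ε_m (ε_m SD 0.866, so Var(U) = 1 at the
  default a = 0.5) raises the log-abundance of three "beneficial" genera
  and lowers one "risk" genus;
- a risk latent L = −b·U − c′·Q enters every clinical marker on top of
  linear age/sex trends and marker-specific noise.

For this linear system ACME = a·b, ADE = c′ and proportion mediated
= a·b/(a·b + c′), recorded in `truth.json`. `simulate_linear_mediation`
exposes the bare three-variable system for exact recovery experiments;
the full cohort necessarily *attenuates* recovered effects because the
mediator is observed only through Dirichlet-multinomial counts and CLR.

**Counts.** Expected compositions are logistic-normal: a two-tier base
(50 "common" genera, log-abundance N(1.5, 0.4); the rest a rare tail
N(−1.5, 0.8)) plus a three-level community-type latent (Prevotella-,
Firmicutes- or Bacteroides/Phocaeicola-dominated, probabilities
0.26/0.50/0.24) and per-entry noise (SD 0.6). Counts are
Dirichlet-multinomial (concentration 150) at the drawn depth, so rows
are integers summing exactly to depth and taxa are overdispersed. The
two-tier base was chosen so that roughly 35–45 of 120 genera pass the
default 10%-prevalence/1%-mean-abundance filter, matching the scale of
genus-level 16S datasets after filtering.

**Randomness.** Everything flows from one root seed through named child
streams (`SeedSequence([seed, crc32(label)])`), so adding a stream never
perturbs the others and a fixed seed is byte-reproducible.

The generator emulates marginal shapes and the planted dependency
structure, not real intake or taxon distributions: passing tests show
the *estimators* behave correctly under a known truth, not that any
biological effect size is realistic.

## Diet indices

HEI-MON and PHEI-MON are entirely threshold-table-driven
(`data/diet_thresholds.yaml`): each component maps a (possibly
energy-standardized) intake to 0–100 by linear interpolation between a
worst and a best anchor (adequacy), the reverse (moderation), or a
plateau between two anchors (range-optimum); the index is the component
mean. The shipped anchors are *editable placeholder defaults* chosen
for plausibility against food-based dietary guidelines; users holding
the indices' original scoring publications can replace the YAML without
touching code. Energy standardization divides intakes by energy/1000
before comparison, which makes both indices invariant to proportional
rescaling of intakes and energy.

aMED uses pooled (not sex-stratified) medians and strict inequalities —
ties at the median score 0, a literal reading of "exceeds the median";
consequently each median component awards a point to at most half the
sample. The MUFA/SFA ratio requires SFA > 0. Missing-component policy
defaults to excluding the subject (logged), with mean-imputation of the
remaining components by flag. Mixed dishes are split by a configurable
allocation map (default: 50% of burger/doner portions to meat).

## cMetS

Five components: waist circumference, MAP = DBP + (SBP−DBP)/3, HDL,
triglycerides, fasting glucose. Each is regressed on intercept + age +
a single binary sex indicator by OLS; residuals are divided by the
residual SD (n−p denominator by default, population SD by flag) and
re-normalized to exactly unit SD; HDL is negated; the score is the
column sum. Standardization is pooled across study cohorts — cohort
enters later models as a covariate instead; within-cohort
standardization would absorb genuine between-cohort risk differences
and is intentionally not the default. Because every component is
z-scored, the score is invariant to affine unit changes of any marker
(asserted to 1e−10 in tests).

## Microbiome features

- **CLR** uses pseudocount 1 and exact row-centering (rows sum to 0).
  Note TSS, not CLR, is exactly invariant to row scaling of counts.
- **Filtering** keeps a genus iff prevalence ≥ 10% *and* mean TSS
  abundance ≥ 1%; whether "1%" should read mean or maximum abundance is
  genuinely ambiguous in the field — mean is the default, `rule="max"`
  the alternative.
- **Beta diversity**: Bray–Curtis is undefined on negative values, so
  the default min-shifts the CLR matrix by its global minimum before BC
  (the choice is logged); Euclidean-on-CLR (Aitchison) is the principled
  alternative by flag. BC is bounded in [0,1] but not a metric; no
  triangle inequality is asserted.
- **Enterotypes**: PAM (greedy BUILD + best-improvement SWAP; the
  objective never increases, asserted by a local-optimality test) on
  Jensen–Shannon divergence with natural logs; machine-epsilon mass
  handles zeros. Hard labels are named after the dominant genus of each
  medoid; fuzzy memberships are normalized inverse divergences with
  fuzzifier 2.
- **EDS-analog**: raw instability = mean over the full-sample
  clustering plus 20 bootstrap re-clusterings of (1 − max membership),
  z-standardized (against the analytic sample by default; an external
  reference mean/SD is injectable) and min–max rescaled to [0,1]. The
  published dysbiosis score comes from a reference-trained web
  classifier whose exact formula is not public; this analog matches its
  scale and monotone intent, not its values, and outputs are labelled
  accordingly.

## SCFA-pathway potential

Sample-level aggregation only: value(s,p) = Σ_t trait(t,p)·count(s,t) /
depth(s), for the five-pathway vocabulary (but, buk, acetyl-CoA, pdiol,
succinate). Fractional (probabilistic) traits flow through the same
weighted sum. Upstream phylogenetic placement / hidden-state prediction
is out of scope — the trait table is an input, and the synthetic
generator emits a consistent one. Aggregation is at genus level to
match the shared count matrix (finer taxa work unchanged if the inputs
are finer).

## Association engine

- **Standardized betas**: β·SD(x)/SD(y) with the raw-coefficient CI
  mapped through the same fixed-SD scale (delta method treating the two
  SDs as constants). Sex/cohort expand to indicator columns, reference
  = first observed level.
- **Multiple testing**: BH step-up (statsmodels) and Bonferroni; the
  test family is always an explicit argument, mirroring
  correction-within-analysis-question practice. q ≥ p elementwise;
  corrections are *not* asserted idempotent.
- **PERMANOVA**: squared distances are Gower-centered; the exposure's
  pseudo-F uses marginal (type-III-like) SS given the covariates by
  default, with the sequential decomposition (whose R² terms + residual
  sum to 1) always attached for reporting and available as the test SS
  by `by="terms"`. Permutation p-values use the Freedman–Lane scheme —
  permute the reduced-model residual structure E = (I−H_r)G(I−H_r) —
  with p = (1 + #{F* ≥ F})/(1 + n_perm), so the smallest attainable p
  is 1/(n_perm+1). Null calibration is verified by simulation (200
  replicates inside binomial 99% bounds of the nominal 0.05).
- **Partial Spearman** rank-transforms x, y *and* numeric covariates
  before residualizing (all-variable rank transform), then Pearson on
  residuals with a t approximation on n−2−k df.
- **Hurdle differential abundance**: logistic presence/absence and OLS
  on log TSS among non-zero samples (no pseudocount), BH across genera
  separately per part. Genera present in (almost) all samples — outside
  5–95% prevalence — skip the presence part with a note rather than
  fitting a separating logistic model.

## Mediation

Linear–linear only (continuous mediator and outcome), matching the
analyses it serves; the draw loop is structured so other model families
could slot in. Coefficient vectors are drawn from each OLS model's
asymptotic multivariate normal with the classical covariance (robust
HC1 by flag); per draw ACME = a·b, ADE = c′, total = a·b + c′, so
ACME + ADE = total holds to machine precision per draw and in the
point estimates (across-draw means). CIs are percentile intervals;
p_acme = 2·min(frac ≤ 0, frac ≥ 0), floored at 1/n_sims with no
interpolation. Proportion mediated is the across-draw median of
ACME/total restricted to draws whose total agrees in sign with the
point-estimate total; results with a majority of sign-discordant draws
are flagged unstable instead of raised. The scan adjusts ACME p-values
per exposure: BH across feature mediators, Bonferroni across taxa.
One RNG stream per seed (not per pair) makes duplicate mediator columns
yield identical estimates.

Verified by simulation: mean ACME over 50 seeds at n = 2000 recovers
a·b = 0.20 within 5%; 95% CI coverage at n = 500 lies in [92%, 98%]
over 200 replicates; the type-I error under b = 0 stays inside binomial
99% bounds of 0.05.

## Pipeline and problem sizes

`run_pipeline` executes stages in dependency order from one YAML/dict
config; requested stages write TSVs plus a provenance JSON (sha256 of
inputs and outputs, seed, version), and prerequisite results are
computed in memory without being written. Fixed float formatting makes
reruns byte-identical.

Default problem sizes were chosen so the full simulation-backed test
suite and the acceptance script each complete in a few minutes on one
core: cohort n = 269 with 120 genera; PERMANOVA 999 permutations (99 in
calibration sweeps); mediation 1000 draws; EDS 20 bootstrap iterations;
calibration/coverage experiments use 100–200 replicates at n = 60–500.

## Known limitations

- HEI-MON/PHEI-MON anchor values are placeholders (see above); absolute
  index levels should not be compared against published cohorts until
  the YAML is populated with the original anchors.
- The EDS-analog is not numerically the published dysbiosis score.
- The hurdle model omits random effects and joint prevalence-abundance
  p-values of full-featured differential-abundance frameworks.
- Mediation assumes sequential ignorability and no exposure–mediator
  interaction; no sensitivity (rho-curve) analysis is provided.
- Cohort-level mediation estimates are attenuated relative to the
  planted latent paths (measurement error through counts); exact
  recovery claims apply to the linear path system only.
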