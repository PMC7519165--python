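# Methods

This note documents the models, defaults, numerical choices and known
limitations of `omicfuse`. It is the package's own account; every number
quoted here is recomputed by the test suite or `scripts/acceptance.py`.

## Synthetic cohort model

The generator (`omicfuse.synthetic`) emulates a post-mortem multi-omic
case/control study of cortex:

- **Subjects and samples.** Defaults: 30 case and 17 control subjects
  (the size of a fully observed reference cohort in this design); each
  subject contributes paired frontal + temporal samples with probability
  `p_paired_regions = 0.85`, otherwise one sample of a random region.
- **Subtypes.** `round(frac_convergent · n_case)` case subjects (ties to
  even; default fraction 2/3) are *convergent*: they carry a latent
  severity score `z_s ~ Normal(1, 0.2)` propagated into the truly
  differential features of all four layers. Per layer the severity is
  `1 + ρ (z_s − 1) + √(1−ρ²) · Normal(0, 0.2)` with cross-layer loading
  correlation ρ = 0.9, so layers agree on who is severe without being
  identical. Disparate cases and controls carry no signal. An optional
  knob (`frac_region_discordant`) silences the signature in one region of
  some convergent subjects, creating region-discordant individuals.
- **Features.** Per layer, feature values are
  `baseline + covariate loadings + subject intercept (SD 0.4) +
  sign_f · effect · severity · carrier + Normal(0,1)`; the default effect
  is 2 SD on 10 % of features per layer. Methylation is squashed through
  a logistic into (0, 1) (beta scale); expression/acetylation stay on the
  unbounded (log-like) latent scale. Effect sizes are free parameters of
  the emulation — the magnitude of a real convergent signature is not an
  input we possess — and are set for test power. The severity spread
  (0.2) is calibrated so that a convergent subject is almost never drawn
  indistinguishable from controls (probability ≈ 0.6 % of a severity
  below the practical decision boundary), which keeps recovery tests
  meaningful while preserving heterogeneity.
- **Covariates.** Age, sex, region, batch, bank, RIN, PMI, neuronal
  proportion (CET) and a sequencing PC are drawn from simple documented
  distributions and injected additively with per-feature Gaussian
  loadings (SD 0.2–0.4 per covariate). Each covariate perturbs exactly
  the layers whose differential model adjusts for it, so planted null
  features are genuinely null. Real data additionally contain residual
  confounding by *unmodeled* covariates; the generator deliberately does
  not emulate that, so passing tests certify the pipeline under a
  correctly specified model, not robustness to hidden confounders.
- **Missingness.** Each sample is unobserved in each layer independently
  (default 0.15), redrawn so that the availability pattern is always one
  the study design permits (never "miRNA only", never
  miRNA+methylation+acetylation, never fully unobserved). Complete-case
  samples (~52 %) form the fusion reference set.
- **Toy genome.** Genes tile one chromosome every 20 kb with random
  strand and length; CpG probes fall in promoters and gene bodies with
  Poisson counts (a configurable minimum makes the ≥2-probe collapse rule
  deterministic); H3K27ac peaks are split into promoter-resident and
  distal peaks, a fraction of which carry eSNPs or significant (FDR<1 %)
  contacts to promoters within 1 Mb. Promoter peaks of differential
  genes are made differential *with the same sign*, planting the positive
  promoter-acetylation/expression coupling the linkage analysis measures.

Not emulated: read-level data, linkage disequilibrium, GWAS summary
statistics, real probe/peak density, and any non-additive noise.

## Coordinates and collapsing

All intervals are 0-based half-open (BED); probes are 1-bp intervals at
the CpG. Promoters are the 2 kb upstream of the TSS (strand-aware,
clamped at 0); gene bodies are TSS→TES. Probe→region collapsing averages
member probes per sample, drops regions with fewer than two probes,
skips missing values in the mean, and lets a probe inside two promoters
contribute to both. A probe exactly at the TSS belongs to the gene body,
not the promoter, by half-open membership — the convention is declared
rather than inferred.

## Differential models

Per feature we fit `y = Xβ + Zb + e` with a random intercept per brain
(subject). Because all features of a layer share (X, Z), the covariance
is diagonalised once (`ZZᵀ = U D Uᵀ`) and each feature's REML reduces to
a bounded 1-D optimization of the variance ratio λ = σ²_b/σ²_e, with GLS
in the rotated basis. This is an exact REML fit; the suite cross-checks
coefficient and standard error against statsmodels' MixedLM. Features
whose λ estimate pins to zero are flagged (`lmm_ok = False`) and are
plain OLS fits.

Inference is a Wald t-test with residual degrees of freedom (n − q).
Under a null with genuine subject-level correlation the p-values are
uniform (verified by KS over 50 simulations); at the σ²_b = 0 boundary
the test is mildly conservative (≈3 % type-I at nominal 5 %), the safe
direction. FDR is Benjamini–Hochberg within each layer and contrast;
"FDR" is not otherwise specified in this field's reports, and BH is the
standard choice.

Categorical covariates are treatment-coded against the first sorted
level; for subtype contrasts the control level is always the reference,
so the coefficient is case-minus-control. Rank-deficient designs raise
an error naming the aliased columns.

**Outlier screening** standardizes each sample's mean correlation to all
others and removes the low-connectivity side (Z < −3); removing on
magnitude would delete well-connected samples. One removal pass is
followed by a single re-check. **ChIP-seq QC** keeps a sample iff it
violates none of six strict thresholds (reads < 1e7, alignment < 75 %,
duplication > 30 %, NSC < 1.03, RSC < 0.5, FRiP < 11 %).

## Fusion and subtyping

Feature restriction uses per-layer FDR thresholds of 10 % (mRNA, miRNA,
methylation) and 20 % (acetylation) on the all-case-vs-control screen.
Kernel, neighbourhood and fusion defaults are K = 20 (reduced to n − 1
for small cohorts, logged), μ = 0.5, T = 15, two clusters. Numerical
choices:

- The kernel is the published exponential form
  `exp(−ρ²/(μ·ε))` — not the Gaussian-density dialect some
  implementations use; a three-point hand-computed example
  (W₁₂ = e⁻², W₂₃ = e⁻⁴·⁸, W₁₃ = e⁻⁹) pins the dialect in the tests.
- ε has a floor of 1e-12 so duplicate samples cannot divide by zero.
- Neighbour-rank ties break by sample index (stable sort).
- `P` carries diagonal mass ½; `S` excludes self from the K neighbours.
- The raw update `S · meanP · Sᵀ` does not preserve row sums, so each
  iteration re-symmetrizes and re-applies the half-diagonal
  normalization; whether to symmetrize per-step or only at the end was
  an open choice and per-step is what we do. The fused output is the
  layer mean, symmetrized (total mass n; rows no longer exactly 1).
- Spectral clustering embeds in the top-k eigenvectors of
  `D^{−1/2} W D^{−1/2}`, row-normalizes, and runs k-means with 50 seeded
  restarts; a graph with more components than clusters is an error.
  Group 2 is oriented to the cluster with the higher mean
  differential-signature loading, making "Group 2 = convergent
  candidate" deterministic.

## Classifier cascade

PC1 scores are computed by SVD of the feature-centered differential
matrix, sign-oriented so the reference Group-2 mean is positive, and
Z-scored over the union of training and test samples (training-only
moments are available as a switch; the union is the default because test
samples are scored together with the reference cohort in this design).
Twelve availability patterns are modelled (3 triples, 6 pairs, 3
singles; miRNA-only and miRNA+meth+acetyl never occur). Maximum
likelihood logistic fits fall back to a Firth-penalized Newton iteration
under separation — inevitable at strong planted effects. The decision
cutoff is the accuracy-maximizing midpoint between sorted leave-one-out
probabilities, ties resolved toward 0.5; a predicted probability exactly
at the cutoff goes to Group 2.

## Regulatory linkage

Promoter assignment is any-overlap (≥1 bp), not containment. Distal
evidence: an eSNP inside the peak (eQTL), or a contact at FDR < 1 % with
the peak on one anchor and the gene's promoter on the other (either
orientation), each within 1 Mb of the TSS measured from the peak
midpoint (the edge-vs-midpoint convention is unstated upstream; midpoint
is ours). All evidence-supported links are kept even when sources
disagree. Heritability annotation intervals are gene body ±10 kb or peak
±1 kb, clamped at zero, sorted and merged.

## Networks

Biweight midcorrelation uses tuning constant 9 with a Pearson fallback
for MAD-zero features (flagged); signed adjacency is ((1+cor)/2)^β with
β = 9 for promoters and 8 for gene bodies; TOM is the standard
min-degree normalized form with unit diagonal. The consensus TOM is the
edge-wise median over sample bootstraps (100 by default, 10 in tests);
a bootstrap that makes a feature constant contributes no edges for it.

Module detection deliberately replaces the dynamic-hybrid tree cut with
a documented static cut: among candidate heights (quantiles of the merge
heights of the average-linkage tree on 1 − TOM) the cut maximizing
Newman modularity on the TOM graph is chosen; clusters below
`min_module_size` become grey; modules whose eigengenes correlate above
1 − merge_threshold (default 0.9) merge iteratively. The module
*statistics* — eigengenes, trait associations, kME, hubs, enrichments —
are the analysis surface; the branch-analysis cut heuristic is an
internal we intentionally simplified. Eigengenes are the first singular
direction of the standardized module submatrix, oriented to correlate
positively with the module's mean profile (the orientation is declared,
not inferred from any upstream convention). Hub selection takes members
with kME at or above the empirical (1 − 0.25) quantile, ties included.

Gene-set enrichment regresses membership indicators over a shared
background by logistic regression; under separation it falls back to the
Haldane-corrected odds ratio with a Fisher exact p (flagged). The
two-sided Fisher test uses the probability-mass rule (sum of tables with
probability ≤ observed), the standard exact-test convention; the test
suite checks it against full enumeration over all small-margin tables.

## Problem sizes

Test and acceptance runs use the default cohort (47 subjects, ~87
samples, 600/150/400/500 features per layer), ten cohorts for subtype
recovery, twenty for null calibration, 200 features × 40 samples for
effect-recovery, and 50 simulations for p-value calibration. These sizes
give stable pass/fail behaviour for the statistical properties while the
whole suite stays desk-scale.

## Known limitations

- The generator's additive Gaussian latent model has no heavy tails,
  no count noise, and no unmodeled confounding; robustness claims beyond
  a correctly specified model are not certified by these tests.
- Wald-t inference is conservative at the zero-variance-ratio boundary;
  Satterthwaite/Kenward–Roger corrections are not implemented.
- The static module cut can split long-thin modules that a
  branch-analysis cut would keep; module counts are therefore not
  comparable to dynamic-hybrid output, only the downstream statistics
  are.
- Partitioned-heritability analysis itself (LD-score regression) is out
  of scope; only the annotation intervals are produced.
- symNMF as an alternative clustering of the fused graph is not
  implemented.
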