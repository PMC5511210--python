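# Methods

`neuronet` reimplements, as a tested pipeline on synthetic data with known
ground truth, a covariate-aware differential expression (DE) and weighted
gene co-expression network analysis (WGCNA) of neuronal-nuclei total
RNA-seq from a small post-mortem case/control cohort (17 controls, 19 cocaine
cases). This note records the models, the parameter choices that matter, and
the places where the design was genuinely open.

## Synthetic data model

Each gene g has a baseline log2-CPM `b_g ~ N(mean_log_expression,
gene_mean_sd)` and a latent per-sample deviation

    z[g, s] = latent_scale * ( sqrt(c) * f_m[s] + sqrt(1 - c) * e[g, s] )

for a member of module m with within-correlation target `c` (`f_m`, `e`
standard normal), and `latent_scale * e[g, s]` for background genes. Case
samples add `status_shift` (in factor sd units) to the module factor, a
fixed signed `log2fc` to each planted DE gene, and per-gene linear effects of
standardized covariates (RIN, PMI, age; categorical race enters as centred
level offsets). Counts are gamma-Poisson (negative binomial):
`mean = library_size * 2**(b_g + z) / 1e6`, `var = mean + dispersion * mean^2`.

Parameter defaults and why:

- `latent_scale = 0.6` log2 units. This is the biological between-subject sd
  of a transcript. It makes a planted log2FC of 1 a standardized effect of
  ~1.5 at the study's n = 36 — consistent with the study detecting hundreds
  of transcripts at nominal p < 0.05 — while keeping the factor construction
  exact for the correlation target.
- `dispersion = 0.005`, `mean_log_expression = 6.0` (log2 CPM),
  `gene_mean_sd = 1.2`, library sizes uniform on 1.5–2.5 million. Biological
  variability lives in the latent layer, so the NB layer carries only
  residual technical overdispersion. These values keep count-level noise
  small enough that a planted within-module correlation of 0.6 is realized
  (0.55 ± 0.05 across replicates) after the count observation layer — the
  generator's own calibration requirement.
- The emitted `CountMatrix` carries the *nominal* simulated depth as
  `library_size` rather than the column sums: the simulated transcripts are
  a 2,000-gene subset of a full library, and sum-normalization of a small
  panel both rescales CPM arbitrarily and removes part of a large planted
  module's shared factor (a compositional artifact that does not exist at
  real 550-of-20,000 scale).
- Covariates are **matched** between status groups, as in the study cohort
  (race composition allocated per group, continuous covariate group means
  equalized). Independent draws occasionally produce severe chance
  confounding (e.g. one case vs nine controls in a race level) that a
  matched case/control design rules out.
- DE genes are planted outside modules when possible so the two planted
  signals stay separately identifiable; module genes still acquire DE
  through `status_shift`, which is the biologically interesting route.

What the generator does *not* emulate: isoform structure, gene-length and GC
effects, sample-specific normalization artifacts (TMM-style composition
bias), heavy-tailed expression noise, and correlated covariates. Passing
tests therefore demonstrate correctness and calibration of the *methods*
under a clean factor-model world, not performance on real tissue data.

## Preprocessing

- **Filter**: a transcript is removed iff the number of samples with
  CPM < `cpm_threshold` (default 1, computed without prior count) exceeds
  `max_low_samples` (default 10). Library sizes are kept from the unfiltered
  matrix; filtering does not redefine depth. The rule is idempotent.
- **log-CPM**: `log2((count + 0.5) / (library + 1) * 1e6)`. A TMM
  (trimmed-mean-of-M-values) scaling option exists (`normalize="tmm"`) but is
  off by default: the reference analysis states no between-sample
  normalization step, and inventing one would change the filter and DE
  inputs.
- **Covariate screen**: per covariate, per-gene single-covariate F tests
  (regression F for continuous, one-way ANOVA for categorical), then a
  one-sample Kolmogorov-Smirnov test of the p-values against Uniform(0,1).
  `widespread` means KS p < 0.01. With thousands of genes the KS test is
  sensitive to small systematic effects; covariates touching ~10–15% of
  genes are usually flagged too, which is the intended reading ("strongly
  influence the expression of many transcripts").
- **Variance decomposition**: one joint fixed-effects linear model per gene;
  a covariate's share is its drop-one increment in R², rescaled so shares
  sum to the full-model R² (exact under orthogonality); residual = 1 − R².
  This is a fixed-effects analogue of mixed-model variance partitioning —
  chosen because the design here has no repeated measures — and the shares
  are invariant to affine rescaling of continuous covariates.
- **Surrogate variables**: expression is residualized on the full known
  design (including status, so the surrogate space is orthogonal to the
  protected coefficient by construction); the number of components is chosen
  by permutation parallel analysis on singular-value *proportions*
  (per-gene sample shuffles; keep leading components whose proportion beats
  the null at p < 0.05, stopping at the first failure). Raw singular values
  against a permutation null grossly over-select on correlated data; the
  proportion statistic self-deflates once leading components absorb real
  structure.

## Differential expression

Voom-style precision weighting: per-gene OLS on the design, lowess (span
0.5) of the square-root residual sd against mean log2 count, per-observation
predicted sd from fitted values mapped through the trend, weights = sd^-4.
Then per-gene weighted least squares and empirical-Bayes moderation: a
scaled inverse-chi-square prior moment-matched on the log residual variances
(trigamma inversion, Newton); moderated t with residual + prior df; BH FDR
across genes. If the observed log-variance spread does not exceed the
chi-square sampling spread the prior df is infinite and the fit collapses to
the pooled-variance t (this limit is asserted against an independent closed
form in the tests). The DE signature is defined by *nominal* p < 0.05, the
study's convention; BH FDR is reported alongside. Status is coded
control = 0, case = 1, so positive log2FC means higher in cases.

## Co-expression network

- **Adjacency**: unsigned, `|pearson|^beta`. The study selected beta = 9 and
  that is the pipeline default; `beta="auto"` scans powers 1–20 for
  scale-free fit (R² of log10 p(k) on log10 k over 10 equal-width
  connectivity bins, empty bins dropped) and takes the smallest power
  reaching R² ≥ 0.8 with negative slope. A signed option
  `((1 + r)/2)^beta` exists but is off by default.
- **TOM**: `TOM_ij = (l_ij + a_ij) / (min(k_i, k_j) + 1 − a_ij)` with
  `l_ij` the shared-neighbour sum; unit diagonal. Clique TOM = 1 and
  star-graph leaf-leaf TOM = 0.5 exactly.
- **Module detection**: average-linkage clustering of 1 − TOM provides
  candidate branches. A fixed-height branch cut is unreliable here: with
  beta = 9 and count-attenuated correlations the merge heights compress into
  a narrow data-dependent band near 1, and no single height separates a
  strong module (whose spurious "hangers-on" attach low) from a weak module
  (whose own branch only forms higher). Instead every branch of at least
  `min_module_size` (default 30) genes is scored by the variance its first
  principal component explains, compared against same-size branches of
  dendrograms grown on sample-permuted data (a selection-aware null;
  permuted rows are projected back onto the observed row space so the null
  has the right matrix rank). Branches with a null z-score ≥ 4 are claimed
  greedily by descending coherence mass `(PVE − null mean) * sqrt(size)`,
  which peaks at the true boundary of a planted block; finally, detected
  modules whose eigengenes correlate at |r| ≥ 0.8 are merged (the
  close-module merge familiar from WGCNA practice). Everything else is grey.
  Modules are named by decreasing size through the conventional color list
  (turquoise, blue, brown, ...). An explicit numeric `cut_height` performs
  the literal static cut instead. The detection null uses a fixed internal
  random state, so results are reproducible for identical input.
- **Eigengene**: unit-norm first right singular vector of the standardized
  module submatrix, sign-aligned to the module mean profile;
  `variance_explained` is the first squared singular value over the total.
- **Robustness**: samples are repeatedly split in half; adjacency is rebuilt
  in each half; per module two preservation statistics (cross-half
  correlation of intramodular connectivity; mean within-module adjacency in
  the test half) are standardized against random same-size gene sets and the
  median Z is averaged over splits. Z < 2 is weak, Z > 10 strong evidence —
  planted cor-0.7 modules score ≈ 13–66, random sets ≈ 0.
- **Hubs**: top `ceil(0.10 * size)` members by intramodular connectivity,
  boundary ties broken by gene id. (For a 550-gene module this rule yields
  55 hubs; a published analysis reporting 53 for that size evidently used a
  different rounding or membership convention, which is not recoverable.)
- **Status association**: tie-corrected Kruskal-Wallis H of the eigengene
  across status groups with a chi-square p (an exact enumeration variant is
  provided for small n). The screening order follows the study: Fisher
  enrichment of DE genes per module with Bonferroni correction over modules
  (over-representation only, OR > 1 — a module can also pass Bonferroni by
  depletion, which is not a status-module candidate), then eigengene-KW on
  the enriched modules.
- The network is built on the covariate-corrected matrix: log-CPM
  residualized on RIN, PMI, age and race (not status, not surrogate
  variables), with gene means retained.

## Enrichment

All intersection analyses share one exact 2×2 machinery: two-sided Fisher p
by summing hypergeometric probabilities no larger than the observed table's
(relative tie tolerance 1e-7); sample odds ratio ad/bc with Haldane-Anscombe
0.5 correction when any cell is zero; Woolf logit 95% CI on the (corrected)
table. Published odds ratios computed with a conditional-MLE estimator need
not match the sample OR exactly. Backgrounds: the filtered transcriptome for
biotype and module tests; all network genes for the hub test (a hub OR is
only interpretable against a universe much larger than the module). Module
tests use Bonferroni over modules; gene-set (GMT) tests use BH across sets,
with an optional named negative-control set flagged in the report (default
name "Height", the study's control phenotype).

## Pipeline and determinism

`run_pipeline` executes filter → log-CPM → covariate screen → variance
decomposition → surrogate variables → voom/moderated DE → residualized
network → soft threshold (if auto) → TOM → modules → eigengenes →
robustness → module-DE enrichment → eigengene-KW cascade → hubs → hub-DE
enrichment → optional GMT enrichments. Every stage writes a TSV;
`manifest.json` records the seed, all parameters and a SHA-256 of every
output, and is byte-identical across reruns with the same config. The
top-level seed is fanned out to per-stage child seeds by stable hashing of
stage names, so stages are individually reproducible.

Default problem sizes for the shipped studies (chosen to make replicated
calibration experiments comfortable on a laptop): 2,000 transcripts ×
36 samples for pipeline-scale runs; 400–500 genes for replicated
power/robustness studies; robustness with 10–20 splits and 50–100
permutations. The statistical behaviour at these sizes is the object of
interest — the cohort size (n = 36) is always the study's real one.

## Known limitations

- Module detection power at n = 36 is bounded: planted within-correlation
  0.6 modules of ≥ 50 genes are recovered reliably (ARI ≈ 0.95); much
  smaller or weaker modules blur into the permutation null.
- A status-shifted module's detectability is capped by the realized factor
  shift: with a 1-sd latent shift, the eigengene-KW stage is a two-sample
  location test with standardized effect ≤ 1 at n = 17 + 19, whose power is
  ≈ 0.80 even with a perfect eigengene; the full
  enrichment-then-KW cascade flags such a module in roughly 85% of
  replicates, not almost always.
- The variance decomposition is fixed-effects only; the SVA variant is the
  residual-SVD + parallel-analysis form, not iteratively reweighted SVA.
- Fisher CIs are Woolf approximations; exact conditional CIs are not
  computed.
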