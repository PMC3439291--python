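# Methods

This note records the statistical models the package implements, the defaults
it ships, the design choices that were genuinely open, and what the synthetic
cohorts can and cannot demonstrate.

## Study design assumed throughout

All discovery stages compare two patient groups defined by recurrence-free
survival after resection: *recurrence* = relapse observed within 12 months,
*non-recurrence* = relapse-free for at least 36 months. Patients between the
cutoffs do not fit the two-group design and are excluded. An optional
*healthy* control group shares the non-recurrence baseline distribution and is
ignored by the discovery stages. Expression is assumed already normalized and
on a log scale; the package performs no probe-level preprocessing.

## Random-variance-model moderated t-test

Per-gene precisions are modelled as draws from a gamma distribution,
1/σ²ᵍ ~ Γ(a, scale b), equivalently σ²ᵍ inverse-gamma. The observed pooled
residual variance with d = n₁+n₂−2 degrees of freedom then satisfies
s²ᵍ·ab ~ F(d, 2a). `fit_rvm_prior` maximizes the exact F-likelihood of the
gene-wise variances over (log a, log b) (Nelder–Mead, xatol 1e−8); the fit is
accurate to a few percent at 5000 genes (unit-tested against variances drawn
from the model). The moderated statistic uses

  s̃²ᵍ = (d·s²ᵍ + 2/b) / (d + 2a),  t = (x̄₁ − x̄₂)/√(s̃²(1/n₁+1/n₂)),

two-sided p from Student's t with d + 2a degrees of freedom. Limiting
behavior: a→0 (with matching prior mean) recovers the pooled two-sample
t-test; a→∞ shrinks every gene to the common prior variance 1/(ab). When the
observed variances are *less* dispersed than the χ²_d sampling noise allows
(effectively equal true variances), the likelihood is maximized at a→∞; the
optimizer is bounded at a = 10⁴, the scale is re-profiled there, and the fit
is flagged `at_boundary`. Differential genes are those with p < 0.05 **and**
BH FDR < 10%; no fold-change gate is applied by default (one is available via
`min_abs_log_ratio`) because the selection rule is significance-based.

Heatmap ordering uses agglomerative clustering with correlation distance
(1 − r) and average linkage — the expression-heatmap convention; neither the
distance nor the linkage is forced by the analysis, so both are parameters.
Samples are compared on gene-centered values, since between-sample
correlations of raw values are dominated by gene-specific baselines.
Constant rows are assigned zero correlation (distance 1) to every partner.

## Enrichment

For a category with N_f members among N annotated universe genes, of which
n_f fall in the n annotated differential genes, Rₑ = (n_f/n)/(N_f/N).
Definitional choices, both recorded in every output table: `n` counts
differential genes annotated to at least one term and `N` universe genes
annotated to at least one term, so numerator and denominator rates share a
background; an empty category with empty overlap scores Rₑ = 0 by convention.
Significance per category comes from the 2×2 table
[[n_f, n−n_f], [N_f−n_f, N−n−N_f+n_f]]: a two-sided Fisher exact test under
the point-probability (minimum-likelihood) rule — chosen because it is the
most common convention and makes results bit-reproducible — and a Pearson
chi-square without continuity correction, which reproduces published 2×2
test statistics better than the Yates correction. Up- and down-regulated
sets are scored separately; BH is applied across terms within a direction,
with raw p always reported alongside (no term-level correction is implied by
the analysis itself). LgP is log₁₀ of the Fisher p.

## Differential co-expression networks and DiffK

Within each group, Pearson correlation is computed for every unordered gene
pair (requires ≥3 samples; p from the t-transform of r with m−2 df). An edge
is kept when p < 0.05 **and** |r| ≥ 0.7. The magnitude gate matters: with
tiny groups a pure significance gate is vacuous, and co-expression practice
keys on strong correlations; both thresholds are configuration keys and are
logged on every run. Network 1 is the recurrence group, network 2 the
non-recurrence group, so genes gaining connectivity in recurrence receive
positive DiffK. Connectivity is plain degree; K(i) = k(i)/max k within each
network; DiffK(i) = K₁(i) − K₂(i) ∈ [−1, 1]. Ranking is by signed descending
DiffK (ties: descending k₁, then gene ID); an |DiffK| ranking is emitted
alongside for symmetric use. The k-core decomposition (iterative removal of
nodes with degree < k; a node's core number is the largest k it survives) is
reported in full rather than at one fixed k. If either network has maximum
degree 0 the normalization is undefined and the computation refuses with an
explicit message rather than guessing.

Because DiffK has no analytic null, `permutation_significance` permutes group
labels and re-runs the full correlation→threshold→degree→DiffK pipeline per
permutation; p(i) = (1 + #{|DiffK*| ≥ |DiffK|})/(B+1), never exactly zero.
One caveat discovered during development and worth knowing: when the
thresholds leave a permuted network nearly empty, max-degree normalization
maps any lone spurious edge to K = 1, so |DiffK*| ties the observed extreme
and the permutation p saturates. The test is therefore only informative when
the networks retain a reasonable edge count — use larger groups or relax
|r| before trusting small permutation p-values on sparse networks.

## Survival validation

Marker cutoffs maximize Youden's J = sensitivity + specificity − 1 on the
empirical ROC (AUC by trapezoid); the cutoff sits midway between adjacent
observed values, ties resolve to the lowest cutoff, and a fixed-quantile rule
is available as an alternative. "High" means strictly greater than the
cutoff — percentages in the dichotomization tables depend on this convention,
so it is fixed and documented. Downstream: Pearson chi-square (no continuity
correction) and two-sided Fisher on the 2×2 class-by-outcome table;
Mann–Whitney U (exact enumeration when both groups ≤ 8 and tie-free) or
Kruskal–Wallis for group comparisons; Kaplan–Meier product-limit curves with
at-risk accounting; the two-group log-rank test; Spearman rank correlation.
Cox proportional-hazards fits report HR = exp(β) with Wald 95% intervals.
Ties are handled by the Efron approximation — with continuous simulated
times ties are absent almost surely, where Efron and Breslow coincide.
Monotone likelihood (perfect separation) raises a dedicated diagnostic
instead of returning a divergent estimate; the pipeline records it per-model
and continues. Note the ROC cutoff is derived on the same cohort it then
classifies; on real data this is optimistic and an external validation split
is the user's responsibility.

## Synthetic cohorts

`generate_expression` draws Gaussian log-expression with SD `noise_sd` (1.0):
a shared marginal for all genes, which is exactly the structure the Pearson/t
machinery assumes. Planted structure:

- **Differential genes** — `n_de_up`/`n_de_down` genes (100 + 100 of 2000 by
  default) shifted by ±`de_effect`·`noise_sd` (default 2 SD) in the
  recurrence group only, so non-recurrence and healthy samples share one
  baseline. The defaults give a few hundred differential genes in a
  2000-gene panel, matching the scale of structure the pipeline targets at a
  desk-scale problem size.
- **Modules** — each module realizes its target within-module correlation r
  through a single latent factor per group: member loading √r gives
  member–member correlation r; hubs load r¼ so hub–member correlation r¾ ≥ r.
  Per-group loadings make co-expression, not just mean, differ between
  groups. The default two modules (20 genes, 5 hubs each; r = 0.9 in one
  group, 0 in the other) are additionally mean-shifted up/down respectively
  (`de_direction`), because a credible recurrence marker — like the ones this
  kind of analysis has nominated — is both differentially expressed and
  differentially connected, and the survival stage needs markers that carry
  signal.
- **Survival** — event times are exponential with rate
  h₀·exp(β·marker score), h₀ = 0.02/month, β = log 2 by default, where the
  marker score is the standardized mean expression of the marker genes
  (default: the first module's hubs). Follow-up ends administratively at a
  per-patient time uniform on [36, `censor_time_max` = 60] months (staggered
  entry); no informative censoring mechanism is modelled. With
  `match_expression_groups=True` (pipeline default) times are redrawn until
  the ≤12/≥36 rule label matches the sample's expression group, and failures
  are discarded and counted — this keeps clinical labels consistent with the
  group-conditional expression but *conditions* the time distribution, so it
  is not the cohort to use for estimator calibration. For that,
  `match_expression_groups=False` returns the unconditional
  proportional-hazards cohort with rule-derived labels (between-cutoff rows
  marked `excluded`); the hazard-ratio recovery and CI-coverage checks use
  this mode.
- **Annotations** — random terms with log-uniform sizes, one positive-control
  term equal to the planted differential set, and a size-matched random
  negative control.

What passing tests on these cohorts do **not** show: robustness to heavy-
tailed or count-distributed expression, batch effects, missing values,
probe-level artifacts, correlated null genes outside planted modules, or
informative censoring. The generators are calibration instruments for the
statistics, not a microarray emulator.

## Problem sizes and numerical choices

The shipped checks run at desk scale, chosen so the full suite executes in a
few minutes: null calibration at 2000 genes (3 vs 3 for the moderated t;
binomial 99% band around α = 0.05), permutation-null uniformity at 100 genes
× 20+20 samples with 199 permutations and the p-gate only (|r| ≥ 0 — a
magnitude gate at this depth empties the permuted networks and the
Kolmogorov–Smirnov comparison would test granularity, not calibration),
hub recovery at 400 genes × 40+40 samples (modules r = 0.9 vs 0.0),
hazard-ratio recovery and 95%-CI coverage at n = 500 with HR = 3 (coverage
over 1000 replicates), Fisher equivalence against exhaustive hypergeometric
enumeration for every 2×2 table with total ≤ 40 (tolerance 1e−12), and
k-core equivalence against a per-k brute-force oracle on 500 random graphs
up to 50 nodes. Small-n power at the 3-vs-3 discovery scale is checked
against a closed-form normal-approximation oracle (BH threshold by fixed
point; expected recovery ≈ 0.80 at a 3-SD shift) rather than a folklore
round number.

Optimization and tolerance constants: RVM fit bounds a ≤ 10⁴ (boundary
flagged), Nelder–Mead xatol 1e−8/fatol 1e−10; correlation r clipped to
[−1, 1] before the t-transform; BH via the standard step-up; Cox Newton
iterations to lifelines' default gradient tolerance with the convergence
warning escalated to an error. All randomness flows from explicit integer
seeds through `numpy.random.default_rng`; identical config + seed reproduces
every output file byte for byte (the report carries a config hash and seed
for provenance, and the manifest carries SHA-256 checksums).

## Known limitations

- Degree-based connectivity ignores edge weights; soft-thresholded weighted
  connectivity (WGCNA-style) is out of scope by design.
- The enrichment stage treats categories as flat sets; gene-ontology graph
  structure (ancestor propagation) is not modelled.
- Cox diagnostics are limited to the separation check; proportionality of
  hazards is assumed, not tested.
- The permutation test re-estimates nothing about the edge thresholds per
  permutation; thresholds are treated as fixed analysis policy.
- Whether the published analysis ranked by signed or absolute DiffK, and
  which correlation threshold defined its "significant pairs", is not
  recoverable; both choices are explicit parameters here, with the defaults
  argued above.
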