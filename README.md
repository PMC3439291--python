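# recurnet

Discovery and validation of tumor-recurrence biomarkers from gene expression,
built around differential co-expression network analysis. The pipeline was
designed for the two-group recurrence study design used in hepatocellular
carcinoma (HCC) cohorts: patients who relapse within 12 months of surgical
resection ("recurrence") versus patients relapse-free for at least 36 months
("non-recurrence"), with expression measured in peripheral blood mononuclear
cells or tissue. It is aimed at computational biologists who want each stage
of that analysis — and the statistics behind it — as tested, reusable
functions rather than a point-and-click workflow.

## What it computes

1. **Moderated differential expression.** A random-variance-model (RVM)
   t-test: per-gene precisions are modelled as 1/σ²ᵍ ~ Γ(a, b) across genes,
   so the residual variances satisfy s²ᵍ·ab ~ F(d, 2a) with d = n₁+n₂−2.
   After a maximum-likelihood fit of (a, b), each gene is tested with the
   moderated variance s̃² = (d·s² + 2/b)/(d + 2a) on d + 2a degrees of
   freedom — the extra 2a degrees of freedom are what make a 3-vs-3 design
   workable. Genes with p < 0.05 and Benjamini–Hochberg FDR < 10% are the
   differentially expressed set, split into up- and down-regulated halves.
2. **Category enrichment.** For a gene-set category (GMT), the enrichment
   ratio Rₑ = (n_f/n)/(N_f/N) compares the category's rate inside the
   differential set to its universe rate, with a two-sided Fisher exact test
   (point-probability rule) and a Pearson chi-square test; LgP = log₁₀ p.
3. **Differential co-expression networks.** Per-group Pearson networks over
   the differential genes (edges: correlation p < 0.05 and |r| ≥ 0.7),
   degree connectivity k(i), max-normalized K(i) = k(i)/max k, and the
   differential connectivity **DiffK(i) = K₁(i) − K₂(i)** ranking genes that
   are hubs in the recurrence network but not in the non-recurrence network.
   A k-core decomposition summarizes each network's dense modules, and an
   optional label-permutation test attaches empirical p-values to DiffK.
4. **Survival validation.** ROC-derived cutoffs (Youden's J), high/low
   dichotomization with contingency tests, Kaplan–Meier recurrence-free
   survival with the log-rank test, and Cox proportional-hazards models
   reporting hazard ratios with 95% confidence intervals. The
   immunohistochemistry indices AIOD = positive area × OD / total area and
   LI (positive cells per 1000 counted) are provided as plain arithmetic.

A synthetic-data module generates expression matrices with planted
differential genes and differentially co-expressed modules, clinical tables
with exponential proportional-hazards survival tied to planted marker genes,
and GMT annotations with positive- and negative-control terms — so the whole
pipeline is testable end to end without any external download.

## Worked example

```sh
cat > config.yaml <<'YAML'
simulation:
  n_genes: 2000
  n_recurrence: 35
  n_nonrecurrence: 45
  n_de_up: 100
  n_de_down: 100
  de_effect: 2.0
seed: 1
YAML
recurnet run --config config.yaml --out out/
```

prints

```
DEGs: 133 up, 128 down
marker G0200: 85.7% high among recurrence; log-rank p=1.89e-14
marker G0201: 80.0% high among recurrence; log-rank p=2.65e-11
marker G0202: 82.9% high among recurrence; log-rank p=1.16e-18
marker G0203: 80.0% high among recurrence; log-rank p=2.87e-18
marker G0204: 91.4% high among recurrence; log-rank p=7.42e-16
report: out/report.json
```

The simulation plants 240 differential genes (200 shifted singletons plus two
20-gene differentially co-expressed modules); the selection recovers them with
a handful of false positives (133 + 128 selected). Genes G0200–G0204 are the
planted hub genes of the up-regulated module: they top the DiffK ranking
(DiffK = 1.0 in `out/node_metrics.tsv`), and the survival stage then validates
them as markers — e.g. G0200 is called high in 85.7% of recurrence patients at
its ROC cutoff (AUC 0.93), separates the Kaplan–Meier curves at log-rank
p ≈ 2·10⁻¹⁴, and keeps a large hazard ratio in a Cox model adjusted for AFP
class. `out/` also contains the DE table, enrichment table, per-group edge
lists, node metrics, and a checksum manifest; re-running with the same config
and seed reproduces `report.json` byte for byte.

The same pipeline runs on real data by replacing the `simulation:` block with
`expression_path`, `groups_path`, `clinical_path`, and `gmt_path` (formats:
TSV expression with gene rows and sample-ID header, two-column sample→group
TSV, clinical CSV with `time_months`/`event`/`group` and `marker_<gene>`
columns, standard GMT).

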