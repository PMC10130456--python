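# Methods

## Scope and data model

`mediatornet` analyses serum soluble-mediator concentrations (pg/mL) from
a fixed 27-analyte multiplex panel, partitioned into chemokines (7),
pro-inflammatory cytokines (7), regulatory cytokines (6) and growth
factors (7), measured in two groups (HC, COVID) stratified by pregnancy
trimester. Subgroup sizes are always taken from the data, never assumed;
the default simulated design is HC 21/10/21 and COVID 7/34/48. Missing
concentrations are kept explicit (NaN) at intake; each stage defines its
own complete-case rule (below). Analyte names are normalised through an
alias table covering ASCII spellings of Greek letters ("TNF-alpha",
"IL1b") so that external CSVs load robustly.

## Standardisation and signatures

Z-scores are computed per analyte as (x − mean)/SD (SD with ddof=1) over a
reference population. The default reference is the **combined** HC+COVID
cohort on **raw** pg/mL: it places both groups on one scale, and under the
right skew typical of serum cytokines it makes all HC median cut-offs
negative — the expected pattern for this data type. HC-only reference and
a log10 transform are config options; log10 turns non-positive values into
missing with a warning. Cut-offs are per-analyte medians of HC Z-scores
(pooled "global" mode or trimester-matched), with the even-count median
defined as the mean of the two central values.

"Above the cut-off" is strict (>): an exact tie does not count, which
reserves exactly-50% for the "unaltered" category and guarantees the
median property the tests rely on — with HC-only standardisation and
global cut-offs the pooled-HC proportion can never exceed 50%.
Proportions are computed over non-missing values only and reported with
`n_evaluated`.

The %COVID/%HC ratio is displayed rounded to one decimal below 1 and to
the nearest integer (half away from zero) at or above 1; classes are
decreased (display ≤ 0.3), increased (display ≥ 3) and unaltered
otherwise. The rounding rule makes the three published-style bins
contiguous: raw ratios in (2, 3) would otherwise be unclassifiable, while
after rounding every positive ratio maps to exactly one class. A ratio is
not evaluable when %HC = 0 or either proportion is missing. Cohort
summary percentages ("% (n)" cells) also round half away from zero, the
convention that reproduces 86/89 → 97%.

## Correlation networks

All 351 analyte pairs are computed on pairwise-complete cases with both
Pearson r and Spearman ρ (average ranks for ties). Pairs with fewer than
`min_n = 5` complete cases are flagged and excluded from edge calling.
Two-sided p-values use the t approximation for n > 9 and the full
permutation distribution (all n! orderings, vectorised) for n ≤ 9, where
asymptotic p-values are unreliable — the smallest default subgroup has
n = 7. When a subgroup is complete (no missing cells) and n > 9 the whole
matrix is computed in one pass.

An edge requires |coef| ≥ 0.67 (inclusive) and p < 0.05 (strict). The
default rule gates on Spearman alone, since the data are treated as
nonparametric throughout; `pearson`, `either` and `both` rules are
provided because a single correlation filter can reasonably combine the
two tests in several ways. No multiple-testing correction is applied
across the 351 pairs by default; a Benjamini–Hochberg option
(`adjust="bh"`, via scipy) is exposed.

Connectivity uses the **degree-sum convention**: a category's count is the
summed degree of its member nodes, so the four category counts always add
to the network total, which equals 2×|edges| — the only convention under
which per-category counts and a per-network total are mutually consistent.
Hubs are nodes with degree ≥ 5 (inclusive). Preserved/lost/acquired sets
are plain set algebra on trimester-matched hub sets. Networks export as
edge-list CSV, SIF (interaction type `corr`) and GraphML with node
attributes (display index 1–27, category, degree) and edge attributes
(r, ρ, both p-values, n) for Cytoscape-style rendering.

## PCA and univariate tests

PCA runs on the same Z-score matrix as the signature stage (complete-case
rows), keeping scales consistent across stages. Zero-variance analytes
are dropped with a warning; all components are retained; each component's
sign is fixed so its largest-magnitude loading is positive, making output
deterministic. Analysis focuses on the PC2/PC3 plane, where group
structure is typically visible once the dominant overall-abundance axis
is set aside. Because "clustering apart" has no standard numeric
criterion, separation is operationalised as an explicit index: distance
between HC and COVID centroids divided by the mean within-subgroup spread
(mean distance of samples to their own centroid); values above 1 indicate
subgroups further apart than their internal scatter. Loading vectors on
PC2/PC3 are reported with the centroid they best align with (cosine
similarity) as a transparent stand-in for reading a biplot; zero loadings
are flagged rather than assigned.

Univariate contrasts per analyte: Kruskal–Wallis across all usable
subgroups (≥3 non-missing values each), Dunn's post-test on the pooled
ranking with tie correction for the three within-group trimester
contrasts (Bonferroni-adjusted ×3 by default, configurable to
unadjusted), and two-sided Mann–Whitney per trimester (scipy's exact
method when both samples are ≤8 and tie-free). Kruskal–Wallis p-values
switch to full permutation enumeration when the pooled sample is ≤9, so
small-sample p-values are exact. Significance markers follow the common
figure convention: letters a/b/c for intragroup trimester differences,
an asterisk for an HC/COVID difference at p<0.05.

## Synthetic cohorts

The generator emulates the three structural features the analysis
depends on: strictly positive right-skewed marginals (log-normal, since
serum cytokines are positive and skewed), multiplicative group effects
(COVID fold change on the trimester-matched HC median), and
subgroup-specific rank correlation (Gaussian copula with the exact
conversion r = 2·sin(πρ/6) from target Spearman to latent Pearson, so
planted rank correlations are recovered in the large-sample limit).
Missingness, when requested, is completely at random — no informative
missingness mechanism is modelled.

Planted hub structure is feasibility-checked: a hub correlated ρ with k
partners forces partner–partner correlations of at least
(kρ²−1)/(k−1) (Schur complement), so `plant_network` pre-fills
within-clique partner pairs at ρ² (single common factor) before the PSD
repair (iterated eigenvalue clipping + diagonal rescaling). Planted
edges that still move by more than 0.05 during repair raise an error
recommending a sparser plan. A corollary worth knowing when designing
simulations: partners of a strong hub are necessarily inter-correlated
near the strong threshold themselves, so clique members can sporadically
reach hub status — that is geometry, not a detection artefact.

`paperlike_config()` encodes the qualitative profile of a convalescent
COVID-19 pregnancy cohort: HC log-medians declining by 0.18 log10 per
trimester for most analytes (rising for CCL4/CCL5/CXCL10/G-CSF, flat for
IL-15/IL-2), log10 SD 0.35 (a typical serum-cytokine dispersion), COVID
fold changes of 3–15× concentrated in the 3rd trimester (15× FGF-basic,
9× IL-9/GM-CSF, 7× CCL2/TNF-α, …) with mild decreases (0.5×) for
CCL4/CCL5/CXCL10/G-CSF/IL-7, and per-subgroup hub cliques (mutual ρ 0.85,
baseline 0.15) whose preserved/lost/acquired decomposition per trimester
mirrors the reported pattern (e.g. IL-1Ra/GM-CSF preserved throughout;
IL-17/FGF-basic/VEGF lost; IL-6/CXCL8/CCL2 acquired at the 3rd
trimester). Absolute levels (log10 medians ≈1.2–2.0) are the package's
own choices — the qualitative directions, not the absolute
concentrations, are what the downstream stages exercise.

What passing tests on synthetic data do and do not show: the copula
reproduces rank correlation and medians faithfully, but real serum panels
have assay floors/ceilings, batch effects, heavier-than-log-normal tails
and clinically structured missingness, none of which are simulated. Tests
on synthetic cohorts therefore validate the *pipeline's correctness and
power to recover planted structure*, not distributional claims about any
real cohort.

## Determinism and numerics

A single integer seed drives one `numpy` Generator through the fixed
subgroup order, so identical configs give identical cohorts and
byte-identical pipeline CSVs. PSD repair is deterministic (eigenvalue
clipping, tolerance 1e−10, ≤200 iterations); Cholesky factorisation adds
a 1e−10 jitter to tolerate exactly singular targets. Exact permutation
p-values compare |coef| with a 1e−12 slack so ties at the observed value
count as at-least-as-extreme. Percentages and display ratios round half
away from zero.

## Known limitations

- With 27 analytes the permutation-exact path is limited to n ≤ 9; for
  10 ≤ n ≤ 15 the t approximation is used although it is still only
  approximate.
- Pairwise-complete correlation matrices need not be PSD; records are
  used pair-by-pair, never as a joint matrix, so this is harmless here
  but the edge lists should not be fed to methods requiring a PSD input.
- The separation index and cosine-alignment reports are explicit
  operationalisations of otherwise visual judgements; they are reported,
  not thresholded, by the pipeline.
- `summarize_cohort` requires cohort-wide unique subject identifiers;
  longitudinal designs with repeated subjects across trimesters must
  disambiguate ids first.
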