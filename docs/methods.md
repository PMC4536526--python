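# Methods

This note documents the models, defaults and numerical choices behind
`panconserve`, and what the synthetic-data suite does and does not show.

## Synthetic multi-cancer generator

**Expression.**  Each cohort is a genes × samples matrix on a log2-like
scale with standard-normal marginals.  A planted module of size *m* with
target within-correlation ρ follows a single-factor model: for member
cohort samples, gene *g* takes `x_g = a_g f + sqrt(1 − a_g²) ε`, with
*f* a per-sample N(0,1) factor and ε independent N(0,1) noise, so
`cor(x_g, x_h) = a_g a_h`.  Loadings are drawn once per module (shared
by all member cohorts) as `a_g = sqrt(ρ) + 0.1 u_g` with centered
uniform `u_g`, clipped to (0.05, 0.999).  Centering makes the module's
mean loading exactly `sqrt(ρ)`, so the expected pairwise correlation is
ρ and the empirical mean |cor| lands within ±0.05 of ρ at n = 200.  The
small spread gives genes a reproducible intramodular-connectivity
ranking, as real co-expression data have; with exactly equal loadings
the connectivity ranking inside a module is pure noise and the
connectivity half of the preservation statistic is uninformative by
construction.  An option flips half the loadings negative (to exercise
unsigned networks) and a missing-at-random mask is available.  Genes not
in any member module are independent noise.

**Survival.**  Each sample's latent risk score is the mean of the
direction-aligned risk-gene values.  Event times are exponential with
hazard `λ(s) = λ₀ exp(γ s)` per day (`λ₀` = 1/900 by default, i.e. a
~2.5-year mean at score 0; `γ` = ln 2.5 in the standard conditions).
Censoring is administrative: entry times uniform on (0, C), with C
solved numerically (Brent) so the expected censored fraction at score 0
equals the configured rate.  Proportional hazards hold by construction.

**What the simulations do not emulate.**  Batch effects, platform/probe
noise, heavy-tailed intensities, informative censoring, copy-number or
mutation structure, and overlapping/nested modules.  Passing the
parameter-recovery suite shows the pipeline's stages are correct and
calibrated under the stated generative assumptions, not that any
particular real-data gene list would be reproduced.

## Network construction and module detection

Pearson correlation; unsigned adjacency `|cor|^β`, default β = 6 (the
historical unsigned convention).  The scale-free criterion
(`select_soft_threshold`: signed R² of log-frequency vs log-binned
connectivity, smallest power reaching R² ≥ 0.8, else the maximizer) is
available and tested, but is not the pipeline default: on block-planted
data it legitimately selects small powers (β ≈ 2) at which the TOM of
uncorrelated genes is too large for a static dendrogram cut, so module
calls degrade even though the fit index is high.  Zero-variance genes
are dropped with a warning.

TOM uses the standard shared-neighbor form; `1 − TOM` feeds
average-linkage clustering.  The dynamic hybrid tree cut is **not**
reimplemented; a static cut at dissimilarity 0.99 is used (the
static-cut convention).  At β = 6, uncorrelated genes merge at
`1 − TOM ≈ 1` and stay singletons, while blocks with within-correlation
≥ 0.6 merge far below the cut.  Branches smaller than
`min_module_size` (default 30) become "unassigned"; named modules are
numbered by decreasing size with ties broken by smallest member id,
which makes labels equivariant under gene permutations.

## Preservation statistics

For reference module *m* evaluated in a test cohort, four observed
statistics on the shared gene universe: mean within-module |cor| and
mean within-module adjacency in the test cohort (density), plus the
ref-vs-test correlation of intramodular connectivity vectors and of the
vectorized within-module correlation matrices (connectivity).  The null
resamples gene sets of size |m| from the shared universe (random-gene
null — it preserves the test cohort's correlation structure); modules of
the same size share one null sample within a ref→test evaluation, which
is also exactly the exchangeability the calibration tests measure.
`Z = (obs − null mean)/null sd` per statistic; Zdensity and
Zconnectivity are the means of their pairs and Zsummary their average.
medianRank is the median of the module's 1-is-best ranks on the four
observed statistics.  A zero null sd yields Z = +inf with a warning;
modules with < 3 shared genes are skipped.

Classification: strong iff Zsummary > 10 and medianRank < 10; moderate
iff 2 < Zsummary ≤ 10 and medianRank < 10; boundary values fall to the
lower class (the published rule uses strict inequalities, leaving the
boundaries unassigned; assigning them downward is the conservative
completion).  The percent-preservation matrix counts strong *and*
moderate modules by default (configurable), cell (A,B) =
`preserved(A in B) / total(A) × 100`, rounded to 2 decimals.

Note that the random-gene null is *conditional on the data*: when a
tested gene set is drawn from a different pool than the null (e.g. pure
background genes in a dataset that contains planted modules), its Z is
legitimately negative — the set is less coherent than a typical random
draw.  Calibration therefore holds for sets exchangeable with the null
draws, which is what the calibration suite samples.

## Conserved sets, hubs, classifiers

Module matching across cohorts uses one-sided Fisher exact tests
(hypergeometric upper tail) on the 2×2 cross-tabulation over shared
genes; no multiple-testing correction (raw p ≤ 0.05 by default).  A
conserved set is the gene intersection along a chain: the
lexicographically first cohort of the group anchors each chain (making
the output independent of how the group is listed); every other cohort
contributes its best-overlap module, required strongly preserved in both
directions of every anchor pair.  Interaction networks keep TOM edges
above an absolute threshold (default 0.02; a percentile mode is natural
when comparing differently sized modules).  Hubs are nodes with degree
≥ 10 — the inclusive bound — sorted by degree then id.  Classifiers are
the intersection of hub sets across the group, partitioned by conserved
set.

## Stratification and survival testing

Per-sample set score = mean per-gene z-score over classifier genes.
Two-set classes: (up, up) → 1, (up, down) → 2, (down, up) → 3, else 4;
a score of exactly 0 counts as down (deterministic and conservative);
one-set mode gives up/down classes 1/2.  The Kaplan–Meier estimator,
log-rank test (multi-group, hypergeometric variance with the standard
multi-death correction for ties), Fisher, McNemar and PCA are
implemented in `survstats` and cross-checked in the test suite against
lifelines, scipy and statsmodels.  McNemar switches from the exact
two-sided binomial to the continuity-corrected χ² at b + c = 25.  PCA
centers but does not scale by default and makes the largest-magnitude
loading of each component positive.

## Risk genes, prediction, panel

Per-gene screen: dichotomize at the gene's median (ties to the high
group), two-group log-rank, keep p ≤ threshold (default 0.01);
direction +1 when the above-median group has the lower Kaplan–Meier
survival at the horizon (default: median follow-up).  The screen is
invariant to affine rescaling of a gene.  Common risk genes are the
intersection across a group, with an `allowed_outliers` parameter (0 by
default; 1 reproduces "common in all but one cohort" semantics).
Actual risk uses a per-cancer horizon in years: death before it = high,
follow-up reaching it = low, censored before it = indeterminate
(excluded from confusion counts, logged).  Predicted risk is a majority
vote of risky-side exceedances vs the cohort median; an exact half votes
low.  Panels follow per-cancer composition rules (common set-1 genes,
common set-2 genes, both, or common + the cancer's most significant
individual genes, ties by gene id), de-duplicated per cancer and in the
pan-cancer union.

## Resampling validation

RDs are patient subsets drawn without replacement (bootstrap behind a
flag); risk is re-predicted *within* each RD (medians recomputed on the
subsample) and tested by two-group log-rank; the summary is the
fraction of RDs with p < α (default 0.05).  RDs with a degenerate
single predicted group count as non-significant.  RDs from one cohort
overlap, so their p-values are positively dependent: null-calibration
checks average the significant fraction over independent cohorts.

## Problem sizes and standard conditions

The simulation suites use: two-cohort fixtures at 200 samples × 200
genes; the six-cohort recovery conditions at 200 samples per cohort,
330 genes (three shared modules of 40/35/30 plus background), nine risk
genes inside the first module, hazard ratio 2.5 per unit score, 20%
censoring, 100 permutations for preservation, 20 seeds; resampling at
one 400-sample cohort, 100 RDs of 200.  These sizes were fixed as the
package's standard desk-scale study conditions.

## Known limitations

* Static cut is a deterministic approximation of the dynamic hybrid
  tree cut; nested or close modules that the dynamic algorithm would
  split can merge under a single static cut.
* The preservation composite uses the canonical 2+2 density/
  connectivity statistics; exact numerical parity with the reference R
  implementation is out of scope.
* The risk-gene screen and the majority-vote risk predictor are the
  simplest procedures consistent with the K-M/log-rank machinery;
  a Cox-score screen is a natural alternative.
* Blockwise computation for very large gene universes (> 20k genes) is
  not implemented; matrices are dense.
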