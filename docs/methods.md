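# Methods

This note documents the models and numerical conventions behind `cwgcna`,
the parameters that matter, and what the synthetic benchmark does and does
not establish.

## Consensus co-expression model

Each cohort is a genes × samples matrix of log-scale expression. Gene–gene
similarity is the Pearson correlation `r_ij` (pairwise-complete when values
are missing; constant genes get zero correlations with a warning rather
than an error, since a hard failure on one degenerate gene would be
disproportionate). Soft thresholding turns correlations into a weighted
adjacency:

* signed (default): `a_ij = ((1 + r_ij)/2)^β` — anti-correlated genes get
  near-zero weight, so up- and down-regulated programs form separate
  modules. This is the default because the analyses this package targets
  treat direction-coherent modules (an up-regulated and a down-regulated
  disease module) as distinct objects.
* unsigned: `a_ij = |r_ij|^β`.

β is chosen per cohort as the smallest candidate power whose connectivity
distribution fits a power law with signed R² ≥ 0.8 (equal-width binning of
`k` into 10 bins, regression of `log10 p(k)` on `log10 k̄`, statistic
`−sign(slope)·R²`); if no candidate qualifies, the argmax is used and
flagged. For a consensus run the per-cohort choices are combined as their
maximum — the more aggressive threshold is applied to every cohort so that
no cohort's network is left denser than its own scale-free fit demands.

The topological overlap matrix

```
TOM_ij = (l_ij + a_ij) / (min(k_i, k_j) + 1 − a_ij),
l_ij = Σ_{u≠i,j} a_iu a_uj,   k_i = Σ_{u≠i} a_iu
```

rewards shared neighbourhoods and is computed by matrix multiplication
(the O(n³) definition is kept as a test oracle).

**Calibration.** Cohorts differ in overall TOM scale. With the first cohort
as reference, cohort *s* is rescaled by `TOM_s ^ e_s` with
`e_s = log Q_ref / log Q_s`, where `Q` is the q = 0.95 quantile of the
off-diagonal entries. The quantile is taken as an order statistic (no
interpolation): a monotone power map carries order statistics exactly, so
after calibration all cohorts' 0.95-quantiles agree to machine precision,
which would not hold under interpolated quantiles. The calibration exponent
is a deterministic function of the data, so calibrating already-calibrated
TOMs returns exponents of 1 (idempotence). The consensus TOM is the
element-wise minimum — an edge is only as strong as its weakest cohort.
`tom_qq_divergence` (max quantile gap on an even probability grid) is the
compatibility screen for deciding whether a cohort belongs in a consensus
at all.

## Module detection

Average-linkage hierarchical clustering of `1 − consensusTOM` is cut
statically at `cut_height_fraction = 0.99` of the maximum merge height;
branches with ≥ `min_module_size = 30` genes seed provisional modules. The
full dynamic branch-splitting heuristic of the reference tree-cut
implementation is deliberately replaced by a simpler, fully specified rule:
after provisional modules are found, *every* gene is assigned by consensus
kME — it joins the module whose eigengene correlation (minimum across
cohorts) is highest, provided that exceeds `kme_rescue_threshold = 0.3`,
and is grey otherwise. The demotion half of this rule matters: under a
static cut, weakly connected background genes attach to module branches
(their overlap with a hub-rich branch exceeds their overlap with other
background genes), and kME reassignment removes them cleanly. Modules that
fall below the minimum size afterwards dissolve into grey, which also makes
pure-noise input return an all-grey assignment.

The cut/eigengene/reassignment cycle is repeated on the genes still grey
(at most 5 cycles, stopping when no new branch seeds a module or the
assignment stabilises). One pass is not enough when a single branch holds
two modules plus background: its one provisional eigengene is dominated by
the larger module and the minority module is demoted wholesale; re-cutting
the grey remainder isolates it, and the next global reassignment places
every gene against the full module set. Module labels follow the
conventional color sequence in decreasing size order (ties broken by first
gene in matrix order), so names are deterministic.

The module eigengene is the first right singular vector of the
standardized (mean 0, sd 1 per gene) member matrix, sign-oriented so it
correlates positively with the module's mean profile, rescaled to unit
variance; `var_explained` is the leading squared singular value over the
total. Modules whose eigengenes correlate above `merge_cor = 0.75` in
*every* cohort are merged iteratively (most correlated pair first,
eigengenes recomputed after each merge); the operation is a fixed point
under repetition.

## Trait association and hub genes

Module–trait association correlates each eigengene with the binary
phenotype (point-biserial, in every cohort) and with FVC and DL_CO where a
cohort measured them. P-values are asymptotic — Fisher
(`z = atanh(r)·√(n−3)`) for module selection, Student
(`t = r·√((n−2)/(1−r²))`) for per-gene significance — and BH-adjusted per
(cohort, trait) family across modules. A candidate module must reach
`|cor| ≥ 0.5` and adjusted `p ≤ 0.05` for the phenotype in **all** cohorts
and for **both** lung-function traits; the conjunction is what makes
candidates reproducible rather than cohort-idiosyncratic.

Per-gene quantities: kME (correlation with the own-module eigengene, per
cohort) with consensus = smallest-magnitude value when signs agree across
cohorts and 0 on sign conflict; GS = correlation of the gene with each
trait. The HubScore combines them as

```
HubScore = |consensus kME| × mean over available traits |GS| ∈ [0, 1]
```

(product by default; `mean` and `rank-average` variants are available —
the product is the strictest, demanding both connectivity and trait signal).
Hubs are genes at or above the linear-interpolation 95th percentile of
their module's scores; ties at the threshold are all kept and every module
retains at least its top gene. With 100 distinct scores this yields exactly
5 hubs; small modules yield 1.

## Module preservation

For a module defined in a reference cohort, seven statistics are computed
in a test cohort: four density statistics (mean intra-module adjacency,
mean intra-module correlation, eigengene variance explained, mean |kME|)
and three connectivity statistics (reference-vs-test correlations of
intramodular connectivity kIM, of kME, and of the gene–gene correlation
pattern). Each is standardized against `n_permutations = 100` random
same-size gene sets drawn uniformly from the shared gene universe
excluding the module under test; `Zdensity` and `Zconnectivity` are the
medians of their groups and `Zsummary` their mean, classified by the
conventional 2/10 thresholds. Results are bit-reproducible given the seed.

Two honest consequences of permuting against the whole gene universe: when
the universe contains other strong modules, the null already carries
preserved co-expression, so connectivity Z-scores are modest even for
genuinely preserved modules (density carries the signal); and a "random"
gene set is only calibrated (|Z| < 2) when it is drawn from the same
universe the null uses — a set drawn from background genes alone scores
*negative* Z in structured data, because the null is richer than it is.

## Elastic-net marker panels

Panels minimise

```
(1/n) Σ log(1 + exp(−y_i x_i'β)) + λ(α‖β‖₁ + (1−α)/2‖β‖₂²)
```

with predictors standardized internally and coefficients reported on the
input scale. λ descends a 50-point log grid from `λ_max` (the smallest
penalty zeroing all coefficients, `max|X'(y−ȳ)|/(n·max(α, 10⁻³))`) over
three decades; the grid is fit warm-started per CV fold and λ chosen by
stratified cross-validation maximising the average-precision PRAUC, ties
going to the larger (sparser) penalty. The numerical solver is saga
(scikit-learn); a full-gradient proximal oracle in the test suite verifies
the objective to 1e-4.

PRAUC uses the average-precision estimator (precision at each positive's
rank, averaged; tied scores handled as blocks with the block-end
precision, so constant scores give the prevalence). Permutation
significance shuffles the training labels and reruns the *entire* fitting
procedure, including the CV penalty choice — refitting at the observed λ
would break exchangeability and is measurably anticonservative. Against a
held-out evaluation set the evaluation labels stay fixed; for training-set
evaluation the permuted statistic is each null model's PRAUC on its own
permuted labels, mirroring the observed statistic's overfitting.
`p = (1 + #{null ≥ observed}) / (1 + B)` with `B = 100` by default (floor
1/101; with B = 19 the floor is 0.05). When several panels are compared
their permutation p-values are BH-adjusted.

## Synthetic study conditions

The generator is the factor model that eigengene analysis estimates:
module m has per-sample scores `ME_m ~ N(0,1)`; member gene g with loading
`ρ_g` is `ρ_g·ME_m + √(1−ρ_g²)·ε`, so members correlate as `ρ_i ρ_j`;
background genes are pure noise; a gene-specific baseline (N(8, 1.5²))
mimics log-intensity levels without affecting correlations. Default
conditions: 2 cohorts × 2000 genes × 120 samples; shared modules of 300,
200, 150, 120 and 80 genes plus one 60-gene module present only in cohort
2; loadings U(0.3, 0.9).

Traits: `phenotype ~ Bernoulli(logistic(Σ w_m ME_m))` with w = +3 for the
up-module (300 genes) and −3 for the down-module (200 genes);
`FVC, DL_CO = Σ w ME + ε` with w = ∓1.2 and unit noise, measured in cohort
1 only (emulating a validation cohort without lung-function records). The
two disease modules' eigengene scores are drawn with correlation −0.5.
This reflects how opposed disease programs behave in real cohorts, and it
is also what makes the binary phenotype attainable as a candidate trait:
dichotomization caps the point-biserial correlation of an eigengene with
the label at `0.798·cov(ME, logit)/sd(logit)`, which for two *independent*
antagonistic modules is ≈ 0.56 no matter how large w is — too close to the
0.5 candidate threshold to be a stable truth. With the −0.5 coupling each
disease eigengene correlates with the label at ≈ 0.65 and with the
lung-function traits at ≈ 0.78.

Mock annotation sets (secretome, known-disease, lung-function GWA,
per-cell-type markers) are drawn with a configurable fraction of their
genes from the top-loading decile of the disease modules, so the triage
arithmetic (novel = hubs − known; biomarkers = hubs ∩ secretome) and
enrichment tests have a controllable ground truth.

What passing on this benchmark shows: the estimators recover the
generative structure they assume, at realistic sample sizes and noise.
What it does not show: robustness to platform/batch effects, probe-level
artifacts, non-Gaussian counts, outlier samples, or modules that violate
the single-factor form — none of which the generator emulates.

## Problem sizes and determinism

Default analysis sizes (2000 genes, 120 samples, 100 permutations, 100
label permutations) run the full pipeline in about a minute on one CPU;
the test suite uses smaller replicas of the same conditions where a
property does not require full scale. All randomness flows from explicit
seeds (`numpy.random.default_rng` via `SeedSequence`), so pipeline reruns
reproduce identical artifact digests, and the acceptance script is a pure
function of its `--seed`.

## Known limitations

* No block-wise TOM approximation: memory is O(n²) in genes (fine to
  ~20,000 genes, not beyond).
* The simplified tree cut does not reproduce the reference dynamic-hybrid
  implementation's branch-splitting decisions; on data whose modules are
  only separable by within-branch structure it will under-split.
* Preservation offers the permutation Z battery only (no medianRank or
  cross-tabulation statistics).
* Elastic-net α is user-specified, not searched; class weights are uniform.
* GEO series-matrix parsing covers the standard table block, not the full
  metadata header dialect.
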