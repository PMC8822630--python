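# Methods

`otubench` benchmarks preprocessing pipelines for sparse 16S rRNA-gene count
tables.  This note documents the models and procedures it implements, the
parameters that matter, and the choices made where the underlying methods
leave room.

## The problem

An OTU/ASV count table records, per sample, how many sequencing reads mapped
to each bacterial feature.  These tables are highly sparse (typically 70–95%
zeros) and compositional: each column's total is an instrument artifact, not
a biological quantity.  A zero can be *biological* (the species is genuinely
absent) or *technical* (the species was present but its reads were lost to
the finite sequencing budget).  Standard workflows only normalize library
sizes; they never try to recover technical zeros.  The package quantifies
what a zero-imputation step adds — and what an ill-suited one destroys — by
scoring 35 pipelines (5 normalizations, 5 imputers, and all 25 combinations,
always normalization first) against simulated data whose ground truth is
known.

## Count simulator (`otubench.sim`)

Two-step generative model per sample:

1. **Biological variability.**  Feature `i` in condition `c` has mean
   intensity `phi_i(c) >= 0`; a replicate's abundance is drawn from a gamma
   law with mean `phi_i` and squared coefficient of variation `v_i`
   (shape `1/v_i`, scale `phi_i * v_i`).  `phi_i = 0` marks a structural
   (biological) zero and yields exactly 0.  Features with `phi_i > 0` but
   declared `v_i <= 0` use a floor of `v = 1e-6`, making the draw effectively
   deterministic at the mean rather than raising.
2. **Sequencing.**  The abundance vector is discretized into an integer
   community pool of exactly `P` units (largest-remainder rounding, so
   structural zeros get no pool mass and the total is exact; `P` defaults to
   10× the maximum depth), and `N_j` reads are drawn from the pool *without
   replacement* — a multivariate hypergeometric draw, implemented exactly as
   sequential univariate hypergeometric conditioning.  `N_j` is uniform on
   the preset's depth range.

Consequences the tests rely on: raw columns sum exactly to their depths;
structural zeros can never be sequenced; sampling can only add zeros, so raw
sparsity ≥ ground-truth sparsity; and as `N_j` approaches the pool total the
raw proportions converge to the pooled ground-truth proportions.

Determinism: depths and gamma draws use the dataset seed; each sample's
hypergeometric draw uses a substream derived from `seed + sample index`, so
results do not depend on evaluation order.

**Preset construction.**  `random_preset` builds condition intensity
profiles from a lognormal base intensity (σ controls how heavy the rare-species
tail is, hence how much is lost at sequencing), independent per-condition
presence with probability `1 − structural_zero_frac`, and a mild lognormal
condition effect (σ = 0.4) so conditions are genuinely differentially
abundant.  Three built-in presets mirror the benchmark's scenario contrasts
at desk scale (300–400 features, 8 conditions × 10 replicates):

| preset | character | structural zeros | v | depths | raw sparsity band |
|---|---|---|---|---|---|
| scenario1 | moderate sparsity, low variability | 0.55 | 0.25 | 5k–20k | 60–80% |
| scenario2 | low sparsity, high variability | 0.40 | 4.0 | 3k–10k | — |
| scenario3 | high sparsity, high depth | 0.90 | 1.0 | 30k–100k | 88–96% |

The intensity skew of scenarios 1 and 3 (σ = 2.5 and 3.0) was set so the
sequencing step removes a realistic share of rare species and the raw
sparsity lands in the documented band.

**What the simulator does not model:** phylogenetic structure, species
interaction networks, amplification bias, technical replicates, or
parameter estimation from real experiments.  Passing tests therefore show
that a pipeline behaves correctly under gamma biological noise and
without-replacement sequencing loss — not that it is optimal on any given
real dataset.

## Normalization (`otubench.normalization`)

All five methods rescale each sample by one positive scalar, so none can
create or destroy zeros — the mechanism behind the exact sparsity-invariance
results.

* **TSS** — proportions `c_ij / N_j`.  **CPM** is TSS × 10⁶ and is the common
  scale for all abundance-error metrics.
* **CSS** — cumulative-sum scaling.  Per sample, quantiles of the *positive*
  counts on a grid of `m` levels (`m` = number of features); `s_j^l` is the
  sum of counts at or below the level's quantile.  The shared level `l̂` is
  the smallest one where the median absolute deviation `d_l` of sample
  quantiles around their cross-sample median turns unstable
  (`d_{l+1} − d_l ≥ 0.1 d_l`); the selection operates on the cross-sample
  deviations, so one shared level is used for all samples.  If the rule never
  fires, the median level (0.50) is used and flagged in `CSSStats`.
  Normalized counts are `K · c_ij / s_j^l̂`, `K` = median of the `s_j^l̂`.
* **TMM** — per sample vs a reference (the sample whose 75th percentile of
  positive-count CPM is closest to the mean such percentile), log fold
  changes `M_i` and mean log abundances `A_i` on features nonzero in both;
  rank-trim 30% per tail on `M` and 5% per tail on `A`; factor
  `2^(Σ w_i M_i / Σ w_i)` with delta-method inverse-variance weights
  `w_i = [(N_j−c_ij)/(N_j c_ij) + (N_r−c_ir)/(N_r c_ir)]⁻¹`; factors
  rescaled to geometric mean 1.  Fewer than 10 surviving features → factor 1
  with a warning.
* **DESeq-style median of ratios** — pseudo-reference = per-feature geometric
  mean over samples, restricted to features positive in *every* sample
  (the factor is the median ratio to it).  No pseudo-count alternatives are
  offered; data with no all-positive feature raise.
* **GMPR** — median count ratio `r_jk` over features nonzero in both samples
  of a pair; factor = geometric mean of a sample's usable `r_jk` (pairs with
  no shared feature are skipped and recorded); factors rescaled to median 1.

Scale behavior worth knowing: multiplying one sample's counts by `f` moves
its median-of-ratios factor (relative to the others) by exactly `f`, its
GMPR factor by `f^(n/(n−1))`, and its TMM factor only marginally (M-values
are depth-normalized; the weights feel the raw counts weakly).

## Zero imputation (`otubench.imputation`)

Common contract: same-shape nonnegative output; only zeros are eligible for
replacement; `llsimpute`/`scimpute`/`drimpute` leave non-zero entries
bit-unchanged; imputed values below 1e−9 are snapped to exact zero so
numerical dust never counts as an imputed entry.

* **llsimpute** — local least squares borrowed from the microarray world.
  Per feature with zeros, the K nearest features (Euclidean distance on the
  feature's observed samples) form a regressor block; least-squares
  coefficients fitted on the observed samples predict the missing ones,
  clamped at zero.  Imputes aggressively: it treats every zero as missing.
* **zcomp_sq / zcomp_czm** — Bayesian-multiplicative and rounded-zero
  multiplicative replacement for compositions.  SQ replaces each zero
  proportion with its posterior expectation under a uniform Dirichlet prior
  of total strength `s = √n` (so each zero part gets `(√n/D)/(n+√n)`); CZM
  uses `δ = frac × detection limit` with `frac = 0.65`.  Both multiply the
  non-zero proportions by one minus the replaced mass (ratios preserved) and
  rescale to the original total; both therefore output 0% sparsity by
  construction.  The CZM detection-limit proxy `1/(n+1)` presumes a count
  total; it is capped at the sample's smallest positive proportion, which is
  inactive on integer counts and keeps the replacement on-scale after
  normalization (after TSS a column sums to 1 and the uncapped proxy would
  exceed the whole simplex).
* **scimpute** — dropout-aware imputation in the style of single-cell
  methods.  On log1p-CPM values, each feature's values are modelled as a
  two-component Gamma (dropout) + Normal (expressed) mixture fitted by EM
  (init: split at the 10th percentile; weighted moment estimates for the
  component parameters; ≤200 iterations, tolerance 1e−6; a fit whose
  "expressed" mean does not exceed the dropout mean is discarded and the
  feature skipped).  Zero entries whose posterior dropout probability
  exceeds `t = 0.5` are candidates.  Each sample is then regressed by
  nonnegative least squares on its similar samples — its group members when
  labels are available, otherwise clusters on the top 5 principal
  directions — using its reliable (non-candidate, detected) features, and
  the fitted combination predicts the candidates.  Because donors may have
  dropped the same feature, the prediction uses detected donors only with
  renormalized weights.  A candidate predicted at zero (e.g. a feature
  absent in the whole group) remains zero — this is what gives the method
  its high specificity on biological zeros.
* **drimpute** — consensus clustering.  On log1p-CPM values, for every
  combination of correlation metric (Spearman, Pearson) and cluster count
  `k` in 10..15 (ks outside `2 ≤ k < n` are skipped with a warning), samples
  are clustered by average linkage on `1 − correlation`; correlations are
  computed pairwise over features detected in both samples, so suspected
  dropouts do not drive donor selection.  A zero entry's estimate in one
  combination is the mean of the feature's detected values in the sample's
  cluster; combinations whose cluster holds no detected value contribute no
  estimate, and the final value averages the informative combinations.
  Entries undetected in every combination (condition-wide absences) stay
  zero.

Exact numeric parity with the original R tools is not claimed for the two
model-based imputers; they implement the published procedures with the
documented choices.

## Evaluation (`otubench.evaluation`)

All abundance comparisons are made after CPM, per sample.

* **Total sparsity** — percent of zero entries.
* **Zero classification** — over raw zeros: technical if the ground truth is
  positive, biological otherwise; "imputed" if the processed value is
  positive.  Sensitivity = recovered technical zeros; specificity =
  preserved biological zeros.  Pipelines without imputation score exactly
  0% / 100%.
* **SMAPE** — `100/m · Σ |x_i−y_i| / (|x_i|+|y_i|)` with 0/0 terms counted
  as 0; computed per sample across features and summarized as the median
  across samples.
* **Aitchison distance** — Euclidean distance between clr-transformed
  vectors, which equals the normalized double sum over pairwise log-ratio
  differences (the identity is verified against the literal double loop in
  the tests).  Zeros are replaced beforehand by half the smallest positive
  value across the vector pair (configurable; recorded).
* **Alpha diversity** — observed richness and Pielou evenness
  (`J = H / ln S_obs`, undefined for single-feature samples).  Composite
  indices (Shannon-as-endpoint, inverse Simpson) and sparse-data richness
  estimators (Chao1, jackknife) are deliberately out of scope: the former
  mix richness and evenness effects, the latter require integer counts.
  Pipeline improvement is tested on per-sample relative errors vs raw with a
  one-sided Wilcoxon signed-rank test (the paired analogue of the rank test
  used between groups), BH-corrected across pipelines within an index, with
  Cohen's d and the conventional magnitude labels (Negligible < 0.01 ≤ Very
  small < 0.2 ≤ Small < 0.5 ≤ Medium < 0.8 ≤ Large < 1.2 ≤ Very large < 2.0
  ≤ Huge).  Group–group comparisons use one-sided Mann–Whitney tests in both
  directions (BH within index) and are labelled up/down/ns; pipelines are
  scored by percent disagreement with the ground-truth labels.
* **Beta diversity** — Whittaker's presence/absence ratio
  `S_union / mean(S_a, S_b)` and Bray–Curtis dissimilarity; Bray–Curtis
  matrices are embedded by non-metric MDS (SMACOF with isotonic regression,
  best of several seeded restarts, Kruskal stress-1 reported).  The report
  summarizes each pipeline by the mean absolute deviation of its
  dissimilarity matrices from the ground truth's, plus the NMDS stress.
* **Differential abundance** — per condition pair, a two-sided Mann–Whitney
  U test per feature (features all-zero in both groups excluded), BH across
  features, adjusted p < 0.05.  Concordance with the ground-truth feature
  sets is the Jaccard index; two empty sets count as 1 (both datasets agree
  there is nothing to find).  Improvement over raw is tested with the paired
  one-sided rank test over condition pairs.

Rank tests use scipy's implementations (midranks for ties, exact small-sample
p-values where available); BH adjustment is statsmodels'
step-up procedure.  Degenerate inputs are defined away rather than raised:
all-tied samples give p = 1, identical paired vectors give p = 1, and a
pooled-variance of zero gives Cohen's d = 0 for equal means.

## Problem sizes and determinism

The test-suite and acceptance-script simulations run at desk scale — 300
features, 4–8 conditions, 5–10 replicates, depths in the thousands — which
preserves all the benchmark's qualitative contrasts while keeping a full
35-pipeline evaluation around a minute.  Every stochastic component
(simulator, scImpute clustering fallback, NMDS restarts) is driven by an
explicit seed, and repeated runs are bit-identical.

## Known limitations

* The simulator's conversion of step-one abundances into the finite pool
  (largest-remainder rounding at `P` = 10× max depth) is this package's own
  construction; the two-step model constrains the marginals, not the
  discretization.
* The scImpute-style EM uses weighted moment estimates rather than full
  weighted MLE for the gamma component; at the sample sizes involved the
  difference is well below the decision threshold `t`.
* Non-metric MDS coordinates are defined only up to rotation, reflection and
  monotone distance transforms; only rank structure and stress are
  comparable across runs.
* Alpha group-comparison labels depend on the BH family (here: across group
  pairs within an index); with few groups the correction is mild.
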