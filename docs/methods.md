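# Methods

## Problem setting

The pipeline discriminates adenomatous polyps (AP) from colorectal cancer
(CRC) from 16S OTU count tables collected across three specimen types
(stool, tissue biopsy, saliva). The canonical cohort layout is strongly
imbalanced — 34 AP samples (9 stool / 13 biopsy / 12 saliva) against 114
CRC samples (34 / 40 / 40) — so the analysis first balances the classes
with synthetic records, gates their quality, and only then extracts and
evaluates discriminative taxa.

## Gaussian-copula synthesis

Each (condition, specimen) group is modelled separately: a copula fitted
to pooled specimens would blur the strong site effects (saliva
communities differ qualitatively from gut-derived ones).

**Marginals.** Every feature gets a 1-D Gaussian KDE with Scott's
rule-of-thumb bandwidth; a zero-variance column degenerates to a point
mass. The KDE cdf is the mean of kernel cdfs and is strictly increasing,
so its inverse is computed by bisection to double precision. OTU counts
are not continuous, but the KDE + final rounding reproduces the empirical
count distribution closely while allowing unobserved intermediate values.

**Latent correlation.** Observations map to latent scores
`z = Φ⁻¹(F_j(x))` with the cdf clipped to `(δ, 1−δ)`, `δ = 1/(4n)`, to
keep scores finite at the empirical boundaries. The score correlation
matrix is shrunk toward the identity with
`λ = min(0.5, p / (10 n))` — with tens of samples and hundreds to
thousands of features the raw estimate is singular — and projected to the
nearest positive-semidefinite correlation (eigenvalue clipping +
diagonal rescale).

**Sampling.** Latent normal draws are pushed through `Φ` and each
marginal's inverse cdf; `enforce_min_max` clips to the observed
[min, max] per feature (which also guarantees nonnegativity) and
`enforce_rounding` rounds to the nearest integer, so synthetic tables are
valid count tables.

**Augmentation schedule.** Targets are *post-augmentation totals* per
(condition, specimen): 59 stool / 63 biopsy / 68 saliva, i.e. 190 per
class. Only this reading is arithmetically consistent with an 18-record
extraction subset leaving 172 training samples per class and 53/57/62
per-specimen training groups (59/63/68 minus 6). Synthesis proceeds in
rounds the size of the group's real count (last round truncated). CRC
groups are fitted on a seeded random subset of 20 real samples per
specimen (cost control at full feature dimension); AP groups always use
all their samples to preserve the scarce class's variability.

## Quality gates

**Adversarial validation.** Real and synthetic rows are merged (classes
balanced by seeded subsampling of the larger side), screened to the 500
largest chi-squared features against the real/synthetic label, and
classified by logistic regression (z-scored inputs; raw counts make the
solver ill-conditioned) and a polynomial-kernel SVC under stratified CV.
Good synthesis is *indistinguishable*: the gate passes when the best
accuracy stays at or below 0.75. The ceiling is a package choice —
"low accuracy" has no canonical number — set so that it separates the
positive control (copula output, observed ≈ 0.35–0.6) from the negative
control (column-permuted + mean-shifted tables, observed ≈ 1.0) with wide
margin on fixtures. SVC hyperparameters can be tuned by seeded random
search (100 trials, log-uniform over C ∈ [0.01, 1000], γ ∈ [10⁻⁴, 100],
objective = mean CV accuracy); random search rather than an adaptive
optimizer keeps the search deterministic under a single seed with the
same best-of-100 contract.

**Distributional battery.** Per-feature two-sample Kolmogorov–Smirnov
tests (asymptotic p-values — count columns are tie-heavy, which makes the
exact method unreliable) with Bonferroni correction
`p_adj = min(1, p·n_features)` at α = 0.05. Columns constant and equal in
both tables report statistic 0 / p 1. Sample counts are paired by seeded
subsampling of the larger table; row alignment is by draw order, which
only affects the exploratory Spearman/MSE column diagnostics, not the KS
or mean/STD statistics.

**Hard-example retention.** Synthetic rows the adversary misclassifies as
real, or scores within a margin (default 0.1) of 0.5, can be retained
preferentially; the rule is exposed as configuration because no single
quantitative criterion is canonical.

## LRP-ε feature extraction

The extraction network is Dense(64) → Dense(32) → Dense(1, sigmoid) with
a hidden-activation sweep over ReLU, LeakyReLU(α = 0.01), Softmax and
GeLU (Softmax as a *hidden* activation is unusual but supported as a
listed variant — it is a vector softmax over the layer's units), trained
with adam on binary cross-entropy, batch 32, 45 epochs. The network is
implemented directly in numpy: relevance propagation needs the weights
and cached activations, and single-threaded numpy makes training
bit-reproducible under a seed.

Inputs are z-scored per feature with training-fold statistics before the
network; raw OTU counts span orders of magnitude and make both training
and relevance scales fragile. Relevances are therefore reported in
standardized space (rankings are what downstream stages consume).

The ε-rule backward pass is
`R_j = Σ_k a_j w_jk / (z_k + ε·sign(z_k)) · R_k` per dense layer, with
the output relevance seeded at the pre-sigmoid logit (the probability is
available by configuration; the logit keeps relevance linear in the
network output). The default stabilizer is *relative* — ε = 10⁻² × mean
|z| of the layer, with sign(0) := +1 — so it is scale-free; an absolute ε
can be passed instead. Bias relevance is absorbed rather than
redistributed, the standard ε-rule behaviour, so conservation
(Σ input relevances = output) is exact only in the zero-bias limit; the
test suite verifies it there at ε = 10⁻⁹.

Extraction runs inside stratified 10-fold CV on a specimen-balanced
random subset of 10% of the augmented data (18 per condition, 6 per
specimen; the per-condition quota is the largest multiple of 3 below the
fraction). Per-taxon scores are the mean of |relevance| over validation
samples and folds — the mean-signed variant is available, but absolute
aggregation is robust to the class-symmetric signs relevances take in a
two-class problem — and the top 64 by score (ties toward the smaller
feature index) form the extracted set. An optional reference taxa list is
intersected by whitespace-normalized exact string match.

## Beta diversity

Counts are transformed to `sqrt(100 · x / rowsum)` (squared row sums
100), Bray–Curtis dissimilarities are computed with the convention that
two all-zero rows have distance 0, and PCoA is the eigendecomposition of
the Gower-centered matrix `−½ J D² J`. Bray–Curtis is a semimetric, so
negative eigenvalues occur; they are reported and excluded from the
coordinates, and explained proportions are over the positive spectrum.
Axis signs follow a deterministic convention (largest-magnitude loading
positive) so ordinations reproduce across runs. The ordination stage runs
on the full feature set, the 64 extracted taxa, and the reference
intersection when present.

## Classification and attribution

The post-extraction data (172 per class) are split 80:20 with seeded
per-(condition, specimen) strata (holdout within one sample of the ratio
per stratum). Three classifiers — polynomial-kernel SVC, XGBoost
(300 trees, depth 4, learning rate 0.1: fixed, stated values in place of
unstated settings), random forest (300 trees) — share identical
stratified 10-fold CV folds; the highest mean accuracy wins, ties broken
by the listed order. The winner is refitted on the full training subset
and evaluated once on the holdout; ROC uses CRC as the positive class.

Shapley attributions:

* `tree_exact` — an in-package float64 path-dependent TreeSHAP over the
  dumped XGBoost trees (thresholds and inputs rounded to float32 to
  mirror the booster's routing exactly). Additivity
  `base + Σφ = margin(x)` holds to ~10⁻¹⁴; the booster's own float32
  `pred_contribs` is used as an independent cross-check in the tests.
* `permutation_sampled` — model-agnostic permutation estimator against a
  background sample (default: column means), with antithetic permutation
  pairs for variance reduction. Each permutation telescopes, so
  additivity is exact for any number of draws; the values converge to the
  exact interventional Shapley values (verified against exhaustive
  2^p enumeration at small p in the tests).

Summary (mean |φ| ranking), beeswarm (per-sample value/attribution
pairs) and force (per-sample sequences, all AP samples then all CRC)
tables are exported per specimen; the per-specimen sub-reports partition
the holdout.

## Fixture generator

The generator emulates the study layout (paper-true group sizes by
default) with a hurdle count law: an entry is a structural zero with
probability `zero_inflation` (default 0.3), otherwise `1 + Poisson(λ)`
with `log λ = base_j + specimen_shift + patient_offset + ε`,
`ε ~ N(0, dispersion²)`. The hurdle form pins the expected zero fraction
at exactly the configured sparsity; the log-normal latent supplies the
heavy upper tail. Per-taxon baselines are `N(1.5, 1.2²)` on the log
scale; specimen shifts (stool 0, biopsy −0.4, saliva +0.6) create the
site separation ordinations show in real data; specimens of one synthetic
patient share a `N(0, 0.3²)` offset, exposing the intra-patient
correlation that repeated-specimen designs carry.

Planted differential taxa (default 10, fold change 4, directions
alternating between CRC- and AP-enriched) are drawn from features with
above-median baseline abundance — a fold change on a near-absent taxon
would be an undetectable "ground truth". The dispersion default (0.6) is
calibrated once against the generator's stated signal-strength contract:
at fold change 4 a per-taxon rank-sum test at α = 0.05 flags ≥ 90% of
planted taxa (measured 94%, with 4% at the null), so downstream recovery
tests measure the pipeline, not the generator.

What the fixture does **not** emulate: real taxon co-occurrence networks
(correlations arise only through patient/specimen structure),
phylogenetic relatedness, compositional closure, and sequencing-depth
variation between body sites. Passing tests therefore demonstrate the
pipeline's mechanics and its behaviour under a known signal, not
performance on any particular real cohort.

## Numerical choices and scales

* KDE inverse cdfs by 90-iteration bisection (exact to double precision);
  probit clipping `δ = 1/(4n)`.
* PSD repair tolerance: eigenvalues clipped at 0; PCoA positive-axis
  tolerance `max(|λ|)·10⁻¹²`.
* Chi-squared screening scores undefined (all-zero) features as lowest;
  all ties break toward the smaller feature index everywhere a ranking is
  produced.
* Test and demonstration runs use 40–200 features with the paper-true
  sample layout; the package's data structures are dimension-agnostic and
  the full 10,329-feature scale is supported, just slower.
* Every stochastic stage takes an explicit seed; the pipeline derives
  per-stage seeds from one master seed via `SeedSequence`, and the run
  manifest records them with the artifact hashes.

## Known limitations

* The copula model captures pairwise latent correlation only, and the
  shrinkage needed at p ≫ n weakens even that; synthetic data can
  understate the co-occurrence structure of real communities (visible in
  ordinations as real/synthetic separation at full feature dimension).
* Samples from one patient are treated as independent in splits and CV,
  as in the emulated design; the fixture's shared patient offsets make
  the resulting optimism measurable but the pipeline does not correct it.
* KS pairing uses small per-group sample counts, so the battery has
  limited power against subtle distributional differences (a Type II
  risk inherent to the design, not a software property).
* `tree_exact` attributions use the path-dependent (cover-weighted)
  background; they answer a slightly different question than the
  interventional `permutation_sampled` values and will not match them
  exactly on correlated features.
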