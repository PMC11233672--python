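# Methods

## Model

Let `X` be a gene-by-sample matrix of log-scale RNA-seq abundances or
microarray intensities. The embedding is built in three steps.

**Feature selection.** For each training cohort separately, every gene
gets a coefficient of variation CV = σ/μ (σ with the n−1 denominator;
genes with μ = 0 have undefined CV and are excluded). Candidate genes are
those shared by all cohorts, minus the stable panel; they are ranked by
the unweighted mean of per-cohort CVs and the top `n_variable` (default
1000) are kept, with ties broken by gene identifier so the selection is
invariant to input ordering. The stable housekeeping panel (default 44
genes, supplied as a one-id-per-line file, never hard-coded) is appended,
giving 1044 feature genes at the defaults. Stable genes are excluded from
the variable candidate pool so the feature count is exactly
`n_variable + n_stable`.

**Rank normalization.** Within each sample the feature genes are ranked
from lowest to highest expression (ties receive average ranks — average
ranks keep the stable-gene mean stable under duplicated values) and every
rank is divided by that sample's mean stable-gene rank. Consequences that
the tests assert exactly: the per-sample mean of stable-gene values is 1;
the output is bitwise invariant to strictly monotone per-sample transforms
of the input; all values are strictly positive.

**Uncentered PCA.** The normalized training matrix (samples × features) is
decomposed by SVD with no centering and no scaling; loadings are the
leading right singular vectors (orthonormal within 1e−8), scores the data
projected onto them. K = 4 components are retained by default. An SVD
(never an iterative solver) is used so fits are deterministic. Because
every normalized sample carries the same multiset of rank values up to the
stable divisor, PC1 aligns with the per-gene mean (correlation ≈ 1:
"PC1 is centering") and PC2 with the post-centering per-gene spread, so
PC3/PC4 of the uncentered fit reproduce PC2/PC3 of an ordinary
centered-and-scaled PCA of the same data; `scaled_pca_equivalence`
measures exactly this.

**Signs.** PCA components are defined up to reflection; refits on
resampled training sets can flip axes. Signs are resolved
deterministically: PC1 positive along the mean direction, PC3 positive on
a designated ER-program hub gene (ESR1 in real use; the generator's
synthetic hub in tests), every other component positive on its
largest-|loading| gene. If an anchor loading is exactly zero the component
falls back to its largest-|loading| gene and records the fallback in the
model metadata. `align_signs` applies the same rules to any refit, which
is how the retraining-stability protocol compares embeddings.

**Projection.** A new sample is ranked among whatever feature genes it
has, divided by the mean rank of its available stable genes, and embedded
as loadingsᵀ·v with missing genes contributing 0. Re-ranking among
available genes (rather than keeping full-panel ranks) is a design choice
the sensitivity diagnostic probes; displacement in PC3/PC4 stays small up
to ~30% of top-loading genes removed. Samples sharing no genes with the
model are rejected; >50% missingness is flagged in the projection
metadata.

## ASIS

The absolute scorer refits the same normalization + uncentered PCA on the
full shared gene universe after an expression filter (default: cohort mean
above a configurable floor in every training cohort; the filter must not
remove stable genes). For each sample the batch components (PC1/PC2 by
default) are regressed out of the normalized vector by least squares
without an intercept — the batch span already contains the mean direction,
so an intercept would be redundant; an alternative reading (reconstructing
from training scores instead of per-sample least squares) is algebraically
close but not identical, and the least-squares choice is the recorded one.
Since the loadings are orthonormal the residual is simply
v − B·Bᵀ·v, orthogonal to every batch loading. A gene-set score is the sum
of residuals over the set's genes; coverage (fraction of the set present
in the universe) below 0.75 flags the score (≥ 0.75 passes). Guarantees,
asserted exactly by tests: adding any vector in the batch span changes no
score; scores are additive over disjoint sets; scoring one sample alone
equals scoring it inside a cohort bitwise (the implementation deliberately
routes cohort scoring through the single-sample path rather than a batch
matrix product, which would round differently); the stable-panel score is
≈ 0 on data from the training distribution.

## Neighborhood comparison

A sample's neighborhood is every other sample within Euclidean radius 1 in
(PC3, PC4); the center is excluded from its own neighborhood (the
reference description leaves this open; excluding it keeps the comparison
"sample vs its context"). The neighborhood's mean pathway score gets a
Bayesian posterior under score ~ Normal(μ, σ) with μ ~ Normal(0, 1) and
σ ~ Exponential(1), sampled by Metropolis-within-Gibbs (conjugate normal
update for μ, random-walk Metropolis on log σ), 4 chains × 1000 kept draws
after 500 warmup, seeded and bitwise reproducible; split-chain R̂ is
reported. With no members the prior is returned, flagged. The sample is
called *above* / *below* its neighborhood if it exceeds the 97.5% /
falls under the 2.5% posterior quantile (strict inequalities; boundary
scores are *middle*) — the reference never quantifies "above the
distribution", so the 95% central interval is the recorded choice.

Responder/non-responder pairs are all cross-label pairs at distance
< 0.5 in (PC3, PC4); the strict inequality follows the running-text
convention over the figure caption's ≤, and is configurable. A sample may
belong to several pairs. Pair screening rules: *low-in-nonresponder* fires
iff the non-responder is below and the responder middle-or-above (the
TGF-β pattern); *high-in-nonresponder* is the mirror (the androgen
pattern). The two-group comparison fits score ~ Normal(a + b·group, σ)
with Normal(0, 1) priors on a and b; the reported probability of a
difference is the fraction of b draws sharing the majority sign, and the
posterior-predictive percentile differences are flat at b draw-for-draw
because the model assumes equal variances — one defensible reading of a
percentile-wise predictive comparison, recorded as such.

## Diagnostics

*LISI*: per sample, Gaussian weights over the 3×perplexity nearest
neighbors are bisection-tuned to the target perplexity (default 30, the
metric's customary scale); LISI is the inverse Simpson index of the
weighted label proportions, bounded by 1 (separated) and the number of
categories (mixed). *Jaccard stability*: refit on random training subsets
(default 25 seeds × 1000 samples), re-anchor signs, embed everything, and
compare each probe's k-nearest-neighbor set (k = 50 by default; the
neighborhood size is not specified by the reference and is reported in the
output) in PC3/PC4 against the reference embedding. *Hexbin maps*:
pointy-top hexagonal binning of PC3/PC4 with per-cell mean scores; every
sample lands in exactly one cell so the count-weighted grand mean is
conserved to 1e−10; the default hex size shrinks until the densest cell
holds ≤ 5% of samples; a weighted linear fit of cell means on cell centers
gives the dominant gradient direction. *Missing-gene sensitivity*: remove
the top fraction of genes by max(|PC3|, |PC4| loading), re-rank, zero-fill,
re-project; report mean displacement and neighbor preservation.

## Synthetic study conditions

The generator emulates two cohorts sharing a 2000-gene universe with 600
samples each: five subtype groups (proportions .40/.20/.10/.20/.10)
forming a continuum — program activities are drawn per sample around
subtype means with sd 1.2, not constant per subtype; four gene programs
(ER 150 genes × effect 1.0, proliferation 120 × 0.8, EMT 80 × 0.6, HER2
50 × 0.7) with 20% negatively-loaded genes; per-gene baselines N(6, 1.5)
and per-gene noise sd uniform on (0.2, 0.8); a 44-gene stable panel with
no program loadings and noise sd 0.05, which lands in the lowest CV decile
of every cohort by construction. The microarray-like cohort applies a
per-gene additive probe bias N(0, 1.8) — constant across samples, so it
reorders genes between platforms and survives rank normalization, which is
what puts the cohorts apart on PC1/PC2 — plus a sample-wise strictly
monotone map (offset 1.5, slope 0.85, softplus compression 0.6 emulating
dynamic-range saturation) that rank normalization removes bitwise. These
defaults were chosen so the generated data reproduces the qualitative
geometry the method assumes (platform variance dominating the first two
components, ER as the leading biological axis) and were verified across
independent simulation seeds.

What the generator does *not* emulate: count-level noise (no negative
binomial; log-scale Gaussian only), gene–gene correlation beyond the four
programs, probe effects correlated with expression level, missing-ness
patterns of real arrays, tumor purity, or clinical covariates. Passing
tests therefore demonstrate the algebraic and geometric guarantees of the
construction and its behavior under the assumed generative structure — not
clinical performance on real cohorts, which requires the original data.

## Problem sizes and numerics

Tests and the acceptance script run the default study (2 × 600 samples,
2000 genes, 1044-feature panel, 1000 training samples) for end-to-end
checks and a quarter-scale study (2 × 140 samples, 500 genes, programs
scaled to keep the program/background ratio) for unit-level fixtures; the
retraining-stability protocol uses 25 seeds × 200 probes × k = 50. Rank
ties use average ranks; SVD rank deficiency below the requested component
count is an error; zero-variance genes are dropped (with a note) before
the scaled-PCA comparison; the stable-gene divisor is always positive so
normalization cannot divide by zero. All randomness flows through
`numpy.random.default_rng` seeds carried in configs and function
arguments; MCMC chains derive per-chain seeds from the user seed.

## Known limitations

Only reflections (not general rotations) are handled when aligning refits;
near-degenerate singular values can still swap neighboring components
between refits. The per-sample regression removes a fixed batch subspace —
batch structure outside span(PC1, PC2) is untouched. The Bayesian model
assumes equal variances across groups. CV-based selection on log-scale
data is sensitive to additive shifts (CV is not shift-invariant), which is
inherited from the definition.
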