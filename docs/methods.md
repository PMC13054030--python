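# Methods

This note records the statistical model behind each pipeline stage, the
defaults and why they were chosen, what the synthetic benchmark does and
does not emulate, and the numerical conventions a maintainer needs.

## Differential expression of counts

**Normalization.** Library composition is corrected by TMM: for sample *i*
against a reference *r*, per-gene log-ratios M = log₂((xᵢ/Nᵢ)/(x_r/N_r)) and
abundances A = ½·log₂((xᵢ/Nᵢ)(x_r/N_r)) are computed over genes positive in
both samples; the 30% tails of M and 5% tails of A are trimmed and the
remaining M averaged with inverse-asymptotic-variance weights
(Nᵢ−xᵢ)/(Nᵢxᵢ) + (N_r−x_r)/(N_r x_r). The factor is 2 to that weighted
mean; factors are rescaled to geometric mean 1. The reference is the sample
whose 75th percentile of scaled counts is closest to the cross-sample mean.
A uniform doubling of one sample's counts therefore yields factor 1 — the
library size absorbs global scale, TMM only corrects composition.

**Dispersion.** Counts are modeled NB with variance μ + φμ². φ is a pooled
method-of-moments estimate: counts are rescaled to a common effective
library size, and Σ(v−m) / Σm² is pooled over all genes and both
conditions, floored at 0 (Poisson limit). An optional tagwise mode shrinks
per-gene moment estimates toward the common value with a prior weight of 20
genes. This deliberately replaces likelihood-based dispersion machinery:
the exact test below is defined conditionally, and a pooled moment estimate
is sufficient, transparent, and oracle-testable. Note that shared
sample-level factors (see the generator) inflate this estimate slightly;
that conservatism is intentional.

**Exact test.** Replicate group sums of NB(1/φ) variables are NB(nᵢ/φ).
After rescaling to equal effective library sizes (quantile-to-mean scaling,
sums rounded to integers), the test conditions on the total t = y₁+y₂:
P(Y₁=k | t) ∝ C(k+r₁−1,k)·C(t−k+r₂−1,t−k) with rᵢ = nᵢ/φ, a binomial when
φ = 0. The two-sided p sums all outcomes whose conditional probability does
not exceed the observed one (min-likelihood convention; a tail-doubling
convention is available — the choice matters only for asymmetric designs).
Probabilities are computed in log space with a 1+1e−12 tie guard.
log₂ fold changes use normalized group means with a prior count of 0.125
per sample so zero counts stay finite. Genes with zero total are flagged
untestable (p = 1, FC = 0).

## Differential abundance of intensities

Reporter intensities are log₂-transformed (non-positive values become
missing) and median-centered per sample; an optional cyclic-loess pass
straightens intensity-dependent trends against the mean profile. No
imputation is performed: missing values reduce per-feature degrees of
freedom, and features with fewer than two observations in either group are
flagged untestable. Per-feature pooled variances s²_g with d_g df are
shrunk toward a scaled inverse-χ² prior (d₀, s₀²) obtained by matching the
mean and variance of log s²_g to their theoretical values (digamma/trigamma
moments; the trigamma equation is inverted by Newton iteration). The
moderated statistic (mean difference over shrunken standard error) is
referred to t with d₀ + d_g df. Setting the prior df to 0 recovers the
ordinary equal-variance t-test exactly; infinite prior df pools all
variances. Zero-variance features are floored at 1e−8 with a logged
warning rather than dropped.

Both feature classes end in Benjamini–Hochberg adjustment and a strict
significance gate: |FC| strictly greater than the threshold (1.5 for mRNA,
1.2 for protein) *and* FDR strictly below 0.05. Boundary values are never
significant.

## O2PLS integration

With preprocessed blocks (column-centered by default; unit-variance scaling
available but off, since per-feature variance carries the differential
signal):

1. initial joint loadings W, C = leading singular vectors of XᵀY, computed
   through thin QR of each block so the p×q product is never formed;
2. block-specific ("orthogonal") components are extracted sequentially: with
   T = X_d W and E = X_d − T Wᵀ, the loading is the leading left singular
   vector of EᵀT; its score is removed from X_d. Each loading is orthonormal
   and orthogonal to W, and at most n such components exist per block (the
   span of (I−WWᵀ)XᵀXW is n-dimensional and each deflation consumes one
   direction) — requesting more raises an error reporting the attainable
   maximum;
3. W, C, T = X_d W, U = Y_d C are re-estimated on the deflated blocks, and
   the inner relations B_t, B_u are least-squares maps between score spaces.

Because every orthogonal loading is orthogonal to the (re-estimated) joint
loadings, the reconstruction X = TWᵀ + T_yosc P_yoscᵀ + E and the Frobenius
energy partition ‖X‖² = ‖joint‖² + ‖orthogonal‖² + ‖E‖² are exact
identities of the fit, and the test suite holds them to 1e−8 relative.
Score cross-products T_yoscᵀT vanish exactly only in noiseless planted
data; on noise fits they are small but nonzero (the construction
orthogonalizes loadings, not scores).

Sign convention: each loading column is flipped so its largest-magnitude
entry is positive; scores flip with their loadings, and the inner relations
are computed afterwards, so results are reproducible across linear-algebra
backends.

**Sample pairing.** The two blocks must share samples row-for-row. When
replicate counts differ (6+6 RNA vs 5+5 protein in the reference design),
the default policy drops unpaired samples by id; the dropped ids are
logged. Condition-mean collapse was considered and rejected as the default
because it reduces a 10-row decomposition to 2 rows.

**Component numbers.** Defaults are n = 3 joint, 2 + 2 orthogonal — the
upper end of what 10 paired samples support. The choice is deliberate: the
per-feature correlation step below acts on systematic parts, and very
low-rank reconstructions concentrate even a null mRNA's variance onto the
condition/latent axes, inflating spurious correlations; richer systematic
parts dilute that artifact. For prediction-oriented use,
`cross_validate` searches n ∈ 1..3, n_orth ∈ 0..2 (points with
n_orth > n are infeasible and skipped) by row-wise k-fold CV of the
symmetric cross-block prediction error, with near-ties (below 1e−12 of the
total data energy) resolved toward the smaller triple.

## Target classification

Only DEPs passing the |FC| > 1.2 gate enter the table; the bait is
excluded. For each protein with a detected mRNA, the Pearson correlation
across samples between its column of the proteome systematic part and its
mRNA's column of the transcriptome systematic part is tested one-sided for
positivity and BH-adjusted across the table: significant → transcriptional,
otherwise → post-transcriptional. Proteins without a detected mRNA cannot
exhibit a positive correlation and default to post-transcriptional
eligibility (logged). A second, two-sided correlation against the bait's
systematic column assigns positive/negative direction where its BH-adjusted
p < 0.05, else none. Correlating systematic parts rather than raw data
follows the integration model (`use_systematic=False` provides the raw
sensitivity analysis). Degenerate (zero-variance) columns yield r = NaN,
p = 1.

## Substrate filtering

Candidates are the conjunction: post-transcriptional ∧ bait-direction
negative ∧ surface-annotated. Surface annotation is a case-insensitive
substring match of configurable keywords ("cell membrane", "cell surface")
against the UniProt-style location string; multi-location strings count as
surface if any keyword matches (logged for audit), which keeps e.g.
"Mitochondrion inner membrane" out while admitting
"Cell membrane; Nucleus". Topology strings parse to
{single-pass I–IV/unknown, multi-pass, GPI-anchor, none}; GPI anchoring is
read from the location string when the topology field is empty, matching
how UniProt records it. Ranking: type I > type II > other single-pass >
GPI > multi-pass > untyped (configurable), then descending |log₂FC|, then
id for determinism.

## Enrichment and overlap

The expressed background is the gene set with summed raw control counts
≥ 10 (inclusive). Query and library sets are intersected with the
background; each set is tested one-sided by the hypergeometric upper tail
P[K ≥ k] (identical to Fisher's exact test with the "greater"
alternative), BH-adjusted across sets. Two-list overlap reports the
representation factor k·G/(n₁n₂) and P[K ≥ k] on a G = 20,000 universe
(protein-coding genome); "≥" rather than ">" is used for the observed
overlap, so k = 0 gives p = 1 exactly.

## Synthetic benchmark

The generator emulates the reference design: 2,000 genes / 1,500 proteins
(1,200 gene-paired), 6+6 RNA and 5+5 protein replicates with shared sample
ids for pairing, one bait knocked down at −2 log₂ units in both blocks.
Planted classes (5% transcriptional, 4% post-transcriptional, 2%
substrates of the proteome) draw |log₂FC| ~ N(1.0, 0.2) with random signs
— except substrates, which are positive (they accumulate when the protease
falls) and surface-annotated with realistic topology frequencies; 10% of
the remaining proteins get surface annotations as decoys, and some
intracellular proteins carry membrane-but-not-surface locations to
exercise the distinction.

Counts are NB (gamma–Poisson) with dispersion 0.05 (biological CV ≈ 22%,
typical of cell-line RNA-seq) around log-normal library sizes
(σ = 0.15 around 3×10⁵ — desk scale); protein log₂ intensities have
Gaussian noise sd 0.25 (≈ 19% CV, typical TMT). A shared per-sample latent
factor g_s ~ N(0,1) loads on every feature of both blocks with N(0, 0.25)
log₂ loadings, modeling sample-level covariation (harvest density, input
amount) and giving the blocks genuine joint structure beyond the condition
contrast. Transcriptionally driven proteins (and the bait) inherit their
mRNA's latent loading — a protein that follows its mRNA follows all of its
mRNA's variation — while post-transcriptional and null proteins load
independently.

What passing tests therefore show: the pipeline separates the planted
classes and recovers planted substrates under realistic noise,
library-size, and sample-covariation conditions at the reference design's
sample sizes. What they do not show: robustness to TMT ratio compression,
batch structure beyond one latent factor, missing-value mechanisms that
correlate with abundance, isoform-level mRNA–protein mapping ambiguity, or
annotation errors — real-data phenomena the generator does not model.

## Numerical conventions and limitations

- All randomness flows through a single integer seed
  (`numpy.random.default_rng`); reruns are byte-identical, and the model
  archive is written with fixed zip metadata so even its hash reproduces.
- Expression tables round-trip exactly (17 significant digits on write);
  result tables print 12 significant digits.
- BH adjustment delegates to statsmodels and is NaN-transparent
  (untestable features never consume multiple-testing budget).
- The exact test caches the conditional distribution per (total,
  dispersion), and rounds scaled group sums to the nearest integer; for
  very shallow libraries this rounding is the dominant approximation.
- With 10 paired samples, correlation tests at N−2 df are short on power;
  the class boundary (transcriptional vs post-transcriptional) is a
  significance call, not an effect-size call, so weakly coupled
  transcriptional targets will land in the post-transcriptional class.
- The O2PLS orthogonal-component cap (n_orth ≤ n_joint) is a property of
  the sequential extraction; designs needing more block-specific structure
  should raise n_joint.
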