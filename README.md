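# sheddetect

Integrative proteotranscriptomics for sheddase substrate discovery.

Cell-surface proteases ("sheddases", e.g. ADAM9) release the ectodomains of
membrane proteins. Knocking a sheddase down changes the proteome in two very
different ways: *transcriptional* targets change because their mRNA changes,
while *post-transcriptional* targets change at the protein level only — and
direct cleavage substrates are the special case that accumulates at the cell
surface when the protease falls. Secretomics alone cannot separate these
classes. `sheddetect` implements the integrative route: paired RNA-seq and
TMT proteome profiling of knockdown vs control, joint decomposition of the
two blocks, and correlation-based target classification, ending in a ranked
list of cell-surface substrate candidates.

It is aimed at computational biologists analyzing a paired
knockdown-vs-control experiment (counts matrix + reporter-intensity matrix +
protein annotation), and ships a synthetic paired-omics generator with
planted ground truth so the whole pipeline is testable without any data
download.

## Method

Given counts `X` (samples × genes) and intensities `Y` (samples × proteins):

1. **Differential mRNAs** — TMM normalization (trimmed mean of M-values,
   30% M-trim / 5% A-trim, precision weights), pooled method-of-moments NB
   dispersion φ, and a conditional exact test: for each gene the group sums
   (y₁, y₂) are referred to the conditional law
   P(Y₁ = k | Y₁+Y₂ = t) ∝ C(k+r₁−1, k)·C(t−k+r₂−1, t−k), rᵢ = nᵢ/φ
   (binomial when φ = 0), with the two-sided p summing all outcomes no more
   probable than the observed split. DEGs: |FC| > 1.5, BH FDR < 0.05.
2. **Differential proteins** — log₂, per-sample median centering, two-group
   linear model with empirical-Bayes variance shrinkage: residual variances
   s²_g are squeezed toward a scaled inverse-χ² prior (s₀², d₀) fitted by
   moment-matching of log s², and the moderated t is referred to t with
   d₀ + d_g df. DEPs: |FC| > 1.2, BH FDR < 0.05.
3. **O2PLS integration** — the sample-paired blocks decompose as
   `X = T Wᵀ + T_yosc P_yoscᵀ + E`, `Y = U Cᵀ + U_xosc P_xoscᵀ + F`:
   a joint part shared by both blocks (from the SVD of XᵀY), block-specific
   orthogonal parts, and residuals, with inner relations U ≈ T·B_t. The
   *systematic part* of a block is its joint + orthogonal reconstruction.
4. **Target classification** — each DEP passing the |FC| > 1.2 gate is
   correlated (Pearson, across samples) between its protein systematic
   profile and its mRNA's systematic profile: a significant positive
   correlation (one-sided test, BH < 0.05) makes it *transcriptional*,
   otherwise *post-transcriptional*. A second, two-sided test against the
   bait protease's systematic profile signs each target positive/negative.
5. **Substrate candidates** — post-transcriptional ∧ negatively
   bait-correlated ∧ cell-surface (UniProt-style location keywords), ranked
   by membrane topology (single-pass type I first) then effect size.
6. **Enrichment & overlap** — one-sided Fisher exact tests of a query list
   against a GMT library on an expressed-gene background (summed control
   counts ≥ 10), and two-list overlap via the representation factor
   RF = k·G/(n₁·n₂) with hypergeometric upper-tail P[K ≥ k] on a
   G = 20,000-gene universe.

## Worked example

```python
from sheddetect import (
    SimConfig, generate_paired_omics, tmm_factors, estimate_common_dispersion,
    nb_exact_test, moderated_t, call_differential, O2PLS, pair_features,
    classify_targets, filter_candidates, topology_summary,
)
from sheddetect.diffexpr import normalize_intensities
from sheddetect.pipeline import log2_cpm, pair_samples

cfg = SimConfig(seed=1)   # 2,000 genes, 1,500 proteins, 6+6 / 5+5 replicates
counts, intensities, design, annotation, truth = generate_paired_omics(cfg)

factors = tmm_factors(counts)
dispersion = estimate_common_dispersion(counts, design, factors)
deg = call_differential(nb_exact_test(counts, design, factors, dispersion), 1.5, 0.05)
dep = call_differential(moderated_t(intensities, design), 1.2, 0.05)

common = pair_samples(counts, intensities)          # drop unpaired samples
x = log2_cpm(counts, factors).subset_samples(common)
y = normalize_intensities(intensities).subset_samples(common)
model = O2PLS(n_joint=3, n_orth_x=2, n_orth_y=2).fit(x.values, y.values)

pairs = pair_features(x, y, annotation)
table = classify_targets(model, x, y, dep, pairs, "ADAM9")
candidates = filter_candidates(table, annotation)
```

which prints, via the obvious `print` statements:

```
common NB dispersion: 0.062
DEGs (|FC|>1.5, FDR<0.05): 61 / 2000
DEPs (|FC|>1.2, FDR<0.05): 160 / 1500
O2PLS joint variance (proteome): 0.67
regulation_class
post_transcriptional    82
transcriptional         77
substrate candidates: 29
{'single_pass_I': 17, 'single_pass_II': 4, 'single_pass_IV': 2,
 'single_pass_unknown': 2, 'multi_pass': 4, 'total': 29}
protein_id      topology  protein_log2fc  bait_cor
    P00928 single_pass_I        1.156617 -0.949203
    P00376 single_pass_I        1.136769 -0.679755
    P00492 single_pass_I        1.091123 -0.982118
```

Reading: of 160 differential proteins, 77 track their mRNA (transcriptional
targets of the knockdown) and 82 do not; 29 of the post-transcriptional,
negatively bait-correlated targets are surface-annotated and survive the
substrate gate — type I single-pass proteins such as `P00928` (protein up
1.16 log₂ units on knockdown, r = −0.95 against the bait) rank first. On
this synthetic dataset the planted truth confirms the calls (see
`evaluate_recovery`).

The same flow is available from the shell:

```sh
sheddetect simulate --seed 1 --out data/
sheddetect run --config run.yaml        # deg → dep → integrate → classify →
                                        # substrates → enrich → overlap
```

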