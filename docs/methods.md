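# Methods

## Overview

`polyti` analyses gene-level count matrices from polysome-profiling RNA-seq:
for each condition (non-treated, NT; treated, T) two mRNA pools are
sequenced — total cytoplasmic mRNA and mRNA co-sedimenting with polysomes on
a sucrose gradient. The polysomal/cytoplasmic abundance ratio of a gene
reads out how efficiently its mRNA is recruited into translation, and the
treatment-induced change in that ratio is the quantity of interest. Around
this core the package provides transcriptional cross-classification, 5′TOP
motif analysis of 5′UTRs, Loewe-additivity synergy scoring for drug
combinations, small assay metrics, and a synthetic-data generator that makes
every stage testable without external data.

## The translational index

For each gene, on size-factor-normalized counts,

```
x1 = mean(poly, T)  / mean(cyto, T)
x2 = mean(poly, NT) / mean(cyto, NT)
TI = x1 / x2
```

`log2 TI > 0` means the mRNA is more efficiently loaded onto polysomes
under treatment. Because TI is a ratio of ratios, any per-sample scale
(library size, polysome-loading efficiency) cancels in expectation; the
test suite verifies invariance to rescaling a single library.

**Normalization.** Median-of-ratios size factors: each sample's factor is
the median over genes of `count / geometric-mean-across-samples`, computed
over genes with no zero count, then rescaled so the factors' geometric mean
is 1. No pseudo-reference fallback is applied — a dataset with no
all-positive gene is rejected rather than silently imputed.

**Expression filter.** A gene counts as expressed when its normalized mean
reaches `expression_min_mean` (default 10) in all four
(fraction × condition) groups; the bound is inclusive. This guarantees
positive group means, so `log2 TI` is finite for every tested gene; a gene
with a zero group mean outside the filter is flagged NaN, never ±∞.

**Significance.** A two-sided permutation test of the
fraction × condition interaction. Condition labels are permuted
independently within each gradient fraction, and the full `log2 TI`
statistic is recomputed for every relabelling. The two within-fraction
label assignments combine as a cross-product: a 3+3 design per fraction
yields C(6,3)² = 400 distinct relabellings. When that number is at most
`n_permutations` (default 10 000) the null distribution is enumerated
exhaustively and `p = #{|stat_perm| ≥ |stat_obs|} / n_distinct` — the
identity relabelling is part of the enumeration, so p is never 0. Larger
designs fall back to Monte-Carlo sampling with an explicit seed and
`p = (1 + #extreme) / (1 + B)`.

Two numerical facts about this test are worth stating explicitly because
they bound what small designs can show:

- The statistic is odd under the full label swap, so relabellings tie in
  ± pairs and the smallest attainable two-sided p for a 3+3 design is
  2/400 = 0.005.
- That minimum is attainable only by genes whose condition signal appears
  in *both* fractions (e.g. a translational shift riding on a
  transcriptional shift). A pure translational-efficiency shift leaves the
  cytoplasmic fraction flat, its relabellings contribute nothing, and the
  effective granularity collapses to the single-fraction C(6,3) = 20
  (minimum p = 0.1). With Benjamini–Hochberg control at α = 0.05 across
  thousands of genes this makes significant calls at 3 replicates/group
  sparse by construction; designs with ≥ 4–5 replicates per group remove
  the limitation. This is a property of assumption-light permutation
  inference at small n, chosen deliberately over a parametric
  negative-binomial model to keep the test self-contained.

**FDR and classification.** Benjamini–Hochberg step-up adjustment
(delegated to `statsmodels`, cross-checked in tests against an independent
hand-rolled implementation). A gene is translationally `up` when
`log2 TI ≥ log2(fold_cutoff)` and `FDR < α`, `down` for the mirrored bound,
else `stable`. The fold cut-off (default 1.5) is interpreted on the linear
scale — `|log2 TI| ≥ log2 1.5 ≈ 0.585` — because published TI values in
this assay family are printed on a log2 scale (a value of −0.99
corresponds to a ~2-fold repression and must be callable at cut-off 1.5).

## Transcriptional cross-classification

Transcriptional regulation is measured on the cytoplasmic fractions alone:
per gene `log2FC = log2(mean_cyto_T / mean_cyto_NT)`, a condition-label
permutation test within the cytoplasmic samples, BH-FDR, and the same
fold/α thresholds (kept independently configurable). `cross_classify`
tabulates translational (rows) × transcriptional (columns) classes,
reporting counts and row percentages to 1 decimal; rows with zero total
report not-available. All three transcriptional columns are always
reported, so row percentages sum to 100.

## 5′TOP motif calling

A 5′-terminal oligopyrimidine mRNA starts with a cap-adjacent C followed by
a pyrimidine tract, often trailed by a G-rich region. With position 1
defined as the transcription start site (first base of the FASTA record),
the scanner calls `is_top` when position 1 is C **and** the maximal C/T run
starting there is ≥ 5 nt (the C plus ≥ 4 more). Design choices:

- The textbook upper bound of ~15 pyrimidines is *not* enforced — longer
  tracts remain TOP; the bound is soft in the literature.
- Downstream G-richness (≥ 50% G in the 10 nt after the run) is reported
  as a flag but never gates the call ("often followed by" is optional).
- An N at position 1 yields a negative call with an explicit reason.

The scanner is equivalent to the regular expression `^C[CT]{4,}`, which the
test suite uses as an independent oracle. Overlap with a reference TOP
catalogue is summarized as four disjoint Venn counts over a gene universe,
and over-representation is tested with the exact hypergeometric upper tail
(two-sided available via Fisher's exact test).

## Loewe synergy scoring

Monotherapy dose–response margins are fitted with a four-parameter Hill
curve `E(d) = einf + (e0 − einf) / (1 + (d/ec50)^h)` by bounded
least-squares (`e0 ∈ [0.8, 1.2]`, `einf ∈ [0, 1.2]`, `h ∈ [0.1, 10]`),
multi-started over log-spaced EC50 seeds; flat margins are flagged
degenerate and refuse downstream inversion. Effects are fractions of
untreated control (1 = no effect). The Loewe-additive expected effect at a
dose pair (a, b) solves

```
a / D_A(E) + b / D_B(E) = 1
```

with `D_X(E)` the closed-form Hill inverse, by bisection on E to 1e-9.
When E is deeper than one drug's asymptote, that drug's equivalent dose is
infinite and its term is 0; if the equation has no root above the deeper
asymptote the expectation saturates there. Zero-dose margins reduce exactly
to the fitted monotherapy curves, and a sham combination (a drug with
itself) satisfies `E(d, d) = monotherapy(2d)` — both verified numerically
in tests.

The synergy score is `100 × (expected − observed)` percentage points of
control: positive when the combination inhibits more deeply than additivity
predicts (synergy), 0 additive, negative antagonism — matching the sign
convention of the Combenefit-style analyses this emulates. The exact scale
of published Combenefit scores is not documented, so this linear score is
an approximation that preserves sign and additivity, not a reconstruction.
The per-cell verdict threshold (default 5 points) is a reporting
convenience; with replicate surfaces a one-sample t-test per cell with
BH-FDR across cells is available instead.

## Synthetic-data generator

The generator emulates the study design, not any particular dataset:

- Per-gene truth: transcriptional and translational classes drawn from
  3-way (up/down/stable) mixtures. Defaults echo a translatome in which
  ~6% of genes are translationally deregulated with a ~3:1 down:up split
  (te proportions 0.015/0.047/0.938) and a comparable transcriptional
  rate; effect magnitudes |log2FC| uniform on [0.7, 2.5], matching the
  observed TI range of roughly −2 to +2.5.
- Counts: negative binomial with variance `μ + α μ²` (dispersion α uniform
  on [0.05, 0.2] by default; α < 1e-8 falls back to Poisson), expected
  count `base_mean · sizefactor · 2^(txn·[T]) · ρ(fraction) ·
  2^(te·[T ∧ poly])`. Base means are log-normal (log-mean 6 ≈ 400 counts);
  library-size factors uniform on [0.7, 1.3]; the polysome-loading factor
  ρ (default 0.8, cytoplasmic = 1) cancels in TI and exists to prove that
  invariance.
- 5′UTRs: TOP genes get `C + 4–15 pyrimidines + G-rich decamer`; non-TOP
  genes start with a purine or carry a sub-minimal pyrimidine run, so the
  generator and scanner agree by construction — a cross-module property
  the tests assert at 100%. TOP prevalence defaults to 0.25 among
  translationally up-regulated genes and 0.02 elsewhere, echoing the
  concentration of TOP mRNAs among treatment-resistant translation.
- Dose surfaces: margins follow exact Hill curves; interior cells are the
  Loewe expectation plus an optional additive `synergy_offset` (negative =
  deeper inhibition = injected synergy) plus Gaussian noise.

What the generator does **not** emulate: batch effects, GC/length biases,
isoform structure, UTR secondary structure, count correlation between
fractions beyond the shared mean structure, or dose-plate edge effects.
Passing tests therefore demonstrate correctness of the estimators under
the stated generative model, not robustness to those real-data artifacts.

All stages derive independent random streams from a single mandatory seed
(`numpy` SeedSequence spawning), so every output is bit-reproducible.

## Problem sizes and numerical choices

Simulation-based tests use 150–2,000 genes at 3–6 replicates per group —
sizes at which the exhaustive permutation enumeration (≤ 10⁴ relabellings)
is vectorized over genes and runs in seconds while keeping Monte-Carlo
error well inside the asserted tolerances. Tail comparisons use an
absolute slack of 1e-12 to make float ties (the identity relabelling)
deterministic. Bisection tolerance is 1e-9 in effect units; the Loewe
equation residual is verified < 1e-6. Percentages are reported to 1
decimal (cross-table rows) or 2 decimals (class splits), with zero totals
reported as not-available rather than 0.

## Known limitations

- The permutation test's granularity bounds attainable significance at
  small replicate numbers (see above); it replaces, and does not
  reconstruct, a negative-binomial GLM analysis.
- TI uses group means only; gene-level dispersion does not inform the
  point estimate.
- The TOP scanner assumes the FASTA records start exactly at the TSS; it
  performs no TSS inference.
- Loewe scoring assumes monotone inhibitory margins; non-monotone
  (hormetic) responses are rejected with diagnostics rather than scored.
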