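# Methods

This note documents the statistical procedures the package implements, the
defaults it ships, and the numerical conventions behind them. It states no
empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## Census

**Model.** Each genome or transcriptome library either does or does not
yield a validated homologue of each subunit in a panel. Because absence in
an incomplete assembly is uninformative, libraries are gated on a positive
control: the AP1 adaptor complex is near-universal in eukaryotes, so a
library with fewer than two distinct validated AP1 subunits
(`min_control_subunits = 2`) is excluded from every count. Only validated
detections — those that survived downstream phylogenetic curation — count;
`include_unvalidated=True` folds raw hits back in for sensitivity analysis.

**Statistics.** Per taxon group and subunit the census reports the count of
AP1-positive libraries with a validated detection, the integer percentage,
and a sector class: `absent` (count 0), `single` (count 1), `majority`
(count/total ≥ 0.5 and count > 1), `minority` otherwise. A single detection
out of a single library is classified `single`, not `majority`: one dataset
is treated as anecdotal evidence regardless of the denominator.
`complete_complex_count` counts eligible libraries carrying every panel
subunit.

**Rounding.** All percentages are round-half-up to integer, computed in
exact integer arithmetic as `(200*count + total) // (2*total)`. This
reproduces ratios such as 266/330 → 81 and 30/47 → 64.
`verify_printed_percentage` recomputes a quoted percentage from its counts
and flags a mismatch rather than propagating it; 33/329 recomputes to 10%.

**Denominators.** Group-level percentages use the group's AP1-positive
library count; multiple libraries of one species count separately, because
the unit of observation is the library, not the species.

## Coregulation

**Rank fusion.** Raw values from different platforms (RNA-seq relative
abundances; microarray fold-changes) are not comparable, but within-sample
orderings are. Each sample is independently transformed to percentile
ranks: average (fractional) ranks 1..n over the non-missing genes, rescaled
as `100*(rank-1)/(n-1)`, so 100 is the sample's most highly expressed gene
and 0 its lowest. An all-tied sample maps to 50 everywhere; a sample with a
single evaluated gene is defined as 50 (the all-tied convention's natural
limit). Genes not evaluated on a platform stay missing (NaN) for all of its
samples; both platforms are rank-transformed identically with no platform
weighting. The whole downstream analysis is therefore invariant under any
per-sample strictly increasing transform of the raw values — a property the
suite asserts bit-exactly.

**Correlation.** `pairwise_corr` is the Pearson correlation of two genes'
rank profiles over the samples where both are observed (a Spearman-type
statistic). It is computed with the symmetric estimator
`cov/sqrt(varx*vary)` so that `pairwise_corr(a,b)` and `pairwise_corr(b,a)`
are bit-identical. A correlation is *undefined* (NaN, never 0) when the
overlap has fewer than `min_overlap` samples or either profile is constant
on the overlap. `min_overlap` defaults to 10: below roughly ten paired
samples a rank correlation's sampling error spans most of [−1, 1], so the
value would be noise presented as signal.

**Ranking orientation.** The default `per_sample` mode ranks genes within
each sample and correlates across samples, matching how meta-datasets of
this kind are assembled; `per_gene` mode is textbook Spearman (each gene's
profile re-ranked across the shared samples) and is provided for
comparison. The two agree in sign on planted-module genes but are not
numerically identical; neither is asserted against full-scale published
coefficients, which would require the original meta-dataset.

**Core score and selection.** A gene's score is the arithmetic mean of its
defined correlations to the core set (default: the four central TSET
subunit genes Phatr3_J43047/TCUP, Phatr3_J54511/TPLATE, Phatr3_J54718/TSPOON,
Phatr3_J46356/TTRAY; the paralogues Phatr3_J43761 and Phatr3_J14536 are
excluded as weakly coregulated). Undefined member correlations are skipped,
not zero-imputed — zero-imputation would systematically penalize
platform-restricted genes, the exact bias the missing-value masking exists
to avoid. A gene with no defined member correlation gets an undefined score
and a zero member count, never a silent drop. Selection takes genes with
mean score strictly above the threshold (default 0.5).

## Pathway completeness

Completeness of a category is `100 * |category ∩ selected| / |category|`,
round-half-up, computed per category so genes in several categories are
counted in each without double-counting artifacts. Categories with fewer
than 5 genes (strict: size 4 dropped, size 5 kept) and the "Enzymes"
catch-all are excluded before ranking. Ranking is by descending percent
with a deterministic tie-break (larger category first, then name), so
output order is stable under input permutation. Selected genes absent from
the reference universe are ignored with a warning, guarding against
annotation-version drift. No enrichment p-values are computed: the
statistic is descriptive.

## Ocean stage

**Normalization.** Per sample (station × depth layer × size fraction), each
transcript's fraction-of-total-reads is divided by the summed fraction of
all transcripts of the target taxon (default Bacillariophyta) in that
sample. This removes the taxon's own ecological abundance signal and makes
values comparable across stations; it is exactly scale-invariant, and the
per-sample sum of normalized panel abundances equals the panel's raw sum
over the group total — an identity the tests check to machine precision.
Size fractions are never pooled.

**Station summaries.** A station's value is the mean of its available depth
layers (surface and deep chlorophyll maximum); a station with one layer
uses that layer rather than being dropped. Presence of a subunit is any
detected transcript, with no minimum-abundance floor. The per-station
subunit ratio (default TCUP : AP2mu) uses the same layer-averaged values
and is undefined (NaN) where the denominator is absent or zero.

**Environmental correlation.** Textbook Spearman per (subunit, covariate),
pairwise-complete over missing covariate values, via `scipy.stats.spearmanr`
on the paired subset. Cells with fewer than `min_overlap` pairs (default 5
— environmental tables pair far fewer samples than an expression meta-set,
and a sign estimate stabilizes quickly) or a constant variable are left
blank; a never-detected subunit therefore yields an entirely blank column.
In this stage samples where a subunit was not detected contribute zero
abundance, since absence of reads is informative here (unlike the
expression meta-set, where absence means "not measured").

**Imputation + PCA.** Variables (covariates plus the panel's total
normalized abundance, one row per sample) are centered and scaled to unit
variance on their observed values. Missing entries start at the column mean
and are refilled iteratively from a truncated SVD reconstruction
(default 2 components) whose singular values are shrunk by the mean
residual eigenvalue — a regularized EM-PCA in the style of the missMDA
family of methods — until the imputed values change by less than `1e-8` or
200 iterations. A complete table passes through unchanged. PCA
(scikit-learn) of the completed matrix returns loadings, scores and
explained-variance fractions; entirely missing and constant columns are
dropped with warnings. Rows are station × depth × fraction samples, not
station aggregates.

## Synthetic data

The generators define the package's test conditions; all are deterministic
given a seed (`numpy.random.default_rng`).

* **Census block.** Groups of libraries with per-subunit Bernoulli
  detection probabilities (defaults span absent, single, minority and
  majority sectors) and an AP1 dropout rate (default 0.10–0.15) that leaves
  a library with fewer than two control subunits. All emitted detections
  are validated.
* **Expression block.** Defaults: 200 genes, a 20-gene planted module
  containing the four core genes, latent loading 0.9, noise sd 0.3, two
  platforms of 30 samples each (identity and cube-root distortions), 10%
  missingness. With these values two module genes correlate at about
  0.81/0.90 ≈ 0.9, far above the 0.5 threshold, while a background gene's
  null correlation has a standard error near 0.14 — so selection separates
  module from background with a wide margin, which is the regime the
  published protocol operates in. One shared latent factor is the simplest
  structure consistent with a coregulated module; multi-factor programs are
  out of scope.
* **Pathway block.** Ten categories with sizes 5–30; one category draws 80%
  of its members from the planted module (capped so the module can supply
  its share), all others sample background genes uniformly.
* **Ocean block.** 60 stations × 2 layers. Normalized subunit abundance is
  `softplus(intercept + offset − slope·temperature + ε)`, with intercept
  −8.2 (placing per-station panel totals around 10⁻³, the order reported
  for wild diatom populations), slope 0.05, noise sd 0.3, temperature
  N(15, 8²) °C. AP2mu carries offset +1.4 so it outexpresses TCUP;
  TSAUCER's detection floor is infinite, so it is never emitted and its
  correlation column is blank. Raw abundances are the normalized values
  multiplied by sampled per-sample group totals, so normalization recovers
  the planted values exactly. Environmental covariates are Gaussian with
  oceanographically plausible means and are masked at 10% to exercise
  imputation. The generator plants only the temperature gradient; other
  covariates are independent noise.

## What the simulations do and do not show

Passing recovery tests on this synthetic substrate demonstrates that the
implementations are correct for the structures the analyses assume — a
shared expression program, monotone platform distortions, a monotone
environmental gradient, missingness at random. Real meta-datasets add
correlated missingness, batch structure, non-monotone platform effects and
taxonomic misannotation, none of which the generator emulates; the
full-scale published figures (e.g. a genome-wide count of coregulated
genes) additionally depend on the original data files and are not
reproduced here.

## Problem sizes and tolerances

The default test suite and the acceptance script use the generator defaults
above (200-gene expression matrices, 60-station ocean tables, 100-seed
repetition for frequency claims); these sizes give Monte-Carlo error well
inside the asserted margins while keeping a full run in the tens of
seconds. Exact-arithmetic claims (rounding, normalization conservation,
correlation symmetry, rank invariance) are asserted bit-exactly or at
1e-12; statistical claims use the margins stated in the tests (e.g.
recovery ≥ 90%, contamination ≤ 5%, rank-1 frequency ≥ 95/100, PC1
explained-variance gap < 5 points).
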