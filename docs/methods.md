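# Methods

This note records the models, parameter choices and numerical decisions
behind each stage, including the places where the design was genuinely
open and what the synthetic validation does and does not establish.

## Coordinate conventions

All internal coordinates are 0-based half-open on the reference + strand.
Conversions to 1-based conventions (GFF3 inclusive, fixedStep wiggle)
happen only in `io.py`. Orthology maps between the toy genomes are
coordinate-identity on mappable windows: translation therefore only
filters reads (a read needs ≥ 50% of its bases in mappable intervals, the
same match criterion used for interval lift-over), it never rewrites
coordinates. Real chain-based maps would permute coordinates as well; the
classification model is agnostic to that difference because it only sees
reference-coordinate densities.

## Peak calling

Compiled density profiles use a Gaussian kernel (bandwidth 30 bp) over
read starts shifted toward the fragment center by half the fragment size
(default shift 75 bp for 150-bp fragments; strand-aware when strand is
known). The exact kernel of the original density-profile software is not
prescribed anywhere, so both bandwidth and shift are parameters; the
acceptance checks avoid depending on kernel specifics. Depth
normalization scales every track to the minimum depth of the compared set
— the natural reading of "normalize by sequencing depth" that keeps all
values in reads-equivalent units.

The permutation threshold permutes ChIP/input labels across all six
tracks, samples 10,000 coordinates per permutation, repeats 100 times and
takes the 99th percentile of the positive null values. Sampling is with
replacement and the identity permutation is not excluded (its inclusion
only makes the threshold conservative). Degenerate data in which the null
has no positive values (all tracks identical) raises rather than
returning 0.

Segmentation: runs > threshold of length ≥ 50 bp, merge gaps < 100 bp,
summit = leftmost argmax of enrichment in the merged region, summit fold
≥ 2 (fold denominator floored at 0.5 reads-equivalent so zero-coverage
input cannot produce infinite fold), Poisson upper-tail q < 0.001 on raw
counts with the input rate scaled by the depth ratio and floored at 1
read. Genomic categories: exon beats intron for overlapping transcripts
(exon evidence is positional, intron is complementary); otherwise
promoter within 1 kb of the nearest TSS, else intergenic.

## The linear categorical model

At each coordinate the twelve normalized density values of a species pair
(2 species × ChIP/input × 3 replicates) enter a 2×2 factorial OLS with
interaction. The design is balanced, so the fit reduces to cell-mean
contrasts; the interaction coefficient is identically the difference of
the two species' ChIP−input enrichments (tested as an algebraic
invariant).

Coefficient p-values use the large-sample normal approximation
(z = estimate/SE) rather than the t reference distribution. With eight
residual degrees of freedom a t-based −log10 p can never reach the
classification cutoff of 20 (it would need |t| ≈ 300); the conventional
cutoff is only attainable with normal tails, which is therefore what the
significance tracks report, capped at 350 where the residual variance is
exactly zero. Both the enrichment and the −log10 p tracks are smoothed
with a 100-bp sliding window (step 1 bp), the window shrinking at
chromosome ends to the available coordinates.

Pair normalization scales every sample's total density mass to the pair
minimum. The original normalization formula is not legible in the source
material; mass-to-minimum is the choice most consistent with the
depth-ratio language and is idempotent, which the tests assert.

Candidate regions are the union of the two species' own peak
segmentations (each species' permutation threshold applied to its own
replicates, the non-reference one after translation). Classification at a
region's summit: *shared* needs both species' smoothed enrichment above
the threshold and both ChIP/input contrasts significant;
*reference-specific* needs reference above, other below, the reference
ChIP/input contrast significant and the interaction significant
(symmetrically for *other-specific*); anything else stays unclassified.
The default enrichment threshold is the empirically derived permutation
threshold ("auto"); the fixed thresholds 0.35/0.4/0.5/1.0 are accepted
for sensitivity analyses on data normalized to that scale.

## Error-rate accounting

`estimate_error_rates` reports FPR = truly shared sites called specific
to either species, FNR = truly diverged sites called shared, total =
FPR + FNR, with the unclassified fraction given separately. The
self-validation scores these rates over truth sites whose 201-bp window
is mappable in the pair's orthology map: a site inside an unmappable gap
loses its non-reference reads to translation, so its status is
structurally unknowable there rather than misclassified (this mirrors the
two-way-orthologous filter that separates non-orthologous DNA throughout
the analysis). The unfiltered rate is reported alongside; at the default
gap rates the two differ by at most a few sites per 200.

## Parsimony dating

Occupancy vectors are dated by exhaustive Fitch parsimony: all eight
assignments of presence/absence to the three internal nodes are scored
and the minimal-change reconstructions kept. The origin branch is the
most recent gain on the root→mel path; origin branches map to age classes
<2.5, 2.5–6, 6–25 and >25 Myr. Ties between reconstructions — either in
events or in the implied origin — set an ambiguity flag; ambiguous sites
are excluded from per-branch gain/loss headlines and counted separately,
because any silent tie-break would bias the gain/loss asymmetry the
counts are meant to measure.

## Motif scanning

PWMs are column-normalized frequency matrices with an additive
pseudocount; log-odds scores are in bits against a uniform background
(configurable to sequence composition). Exact p-values come from the full
score distribution computed by dynamic programming over per-column score
convolutions with scores discretized to 0.001-bit bins; at width 9 the
binned DP distribution matches full enumeration of all 4^9 words to
floating-point precision (asserted in the tests). Zero-probability
letters score −100 bits, which is unreachable by any threshold in use.
Windows containing non-ACGT letters are skipped; the reverse strand is
scanned with the reverse-complemented matrix so hit offsets always refer
to forward-strand window starts. A site has a "conserved motif" when each
orthologous sequence contains at least one hit of its own species' PWM at
the configured p cutoff (0.005 for the conservation contrast, 0.01 for
motif-site definition).

## Population-genetic statistics

Tajima's D uses the standard constants with π from clean alignment
columns (any masked or ambiguous base removes the column for all
statistics; masking replaces bases under Phred 30 with N). D is an
explicit error when no site segregates — an undefined statistic should
not silently become 0. MK counting: a segregating site is polymorphic
regardless of the outgroup state; a fixed difference is monomorphic in
the panel and different from the outgroup. The 2×2 test is chi-square
without continuity correction, replaced by Fisher's exact test (flagged)
when a marginal is zero.

Shared α is a reimplementation of the shared-adaptation estimand as an
explicit likelihood: locus i contributes
Bin(P_sel | P_tot, f_i/(1+f_i)) · Bin(D_sel | D_tot, g_i/(1+g_i)) with
g_i = f_i/(1−α); f_i absorbs the locus's mutational target and
constraint, α is shared. For a single locus the MLE reduces exactly to
the classical α = 1 − (D_neu·P_sel)/(D_sel·P_neu). The 95% CI is the
profile-likelihood interval (χ²₁ cutoff), with an optional bootstrap
cross-check over loci. The α grid spans (−4, 0.98]; strongly negative α
is meaningful (segregating deleterious excess) and occurs in real data.

The multilocus HKA test fits per-locus θ and a common divergence time by
the standard moment equations (E[S_i] = θ_i·a1(n_i), E[D_i] = θ_i(T+1)),
sums squared standardized deviations of S and D, and calibrates the
p-value with coalescent simulations (msprime; haploid samples, unit
population size, split at the fitted T, locus rate θ_i/2) in which the
parameters are re-estimated per simulated dataset — so the p-value
inherits none of the variance-formula approximations.

## Expression divergence

Counts are upper-quartile normalized (factor = geometric-mean UQ divided
by the sample's UQ, computed over expressed genes); genes with fewer than
5 reads in total are NA. Divergence is a per-gene likelihood-ratio test
of the species effect in a count GLM — negative binomial with a pooled
method-of-moments dispersion, falling back to Poisson when underdispersed
(n = 3 per species makes per-gene tail estimation of dispersion
unstable) — with BH correction; *diverged* requires adjusted p < 0.01 and
|log2 FC| > 2, i.e. more than four-fold. Nearest genes are assigned by
summit-to-TSS distance with a lexicographic gene-id tie-break; a gene
linked to several sites of a class counts once in the Fisher tables.
Association tests are one-sided (enrichment of diverged expression near
diverged binding); the TE and motif contrasts are two-sided.

The congruence analysis compares, for new versus old essential genes, the
distance to the nearest binding site whose occupancy pattern matches the
gene's origination pattern exactly; old genes are summarized by the mean
cumulative curve over 1,000 resamples of 42 genes, and the new/old
difference is tested with a two-sample KS test on the distance
distributions.

## The synthetic generator

The generator reproduces the study design — 4 species on
(((mel,sim),yak),pse) with splits at 2.5/6/25 Myr, 3 ChIP + 3 input
replicates, 36-bp reads, 37-strain panels — at desk scale (defaults:
200-kb genome, 200 sites, 200k reads per sample). Specific choices:

* **Binding histories** follow a two-state gain/loss Markov process
  simulated event-by-event along branches (root state at the stationary
  frequency); sites absent from all four leaves are resampled. Defaults
  gain 0.02 / loss 0.04 per site per Myr give pairwise divergences in the
  observed 15–75% range across the three splits. Empirical pattern
  frequencies are tested against the matrix-exponential distribution.
* **Reads**: input samples are homogeneous background; ChIP samples mix
  background with peak reads whose fragment centers are Gaussian
  (sd 60 bp) around the summit, read starts offset by half a fragment on
  the sequenced strand. Every sample emits exactly its configured depth,
  so peak reads displace background: the per-site read allocation is
  solved self-consistently so that summit density ≈ enrichment × the
  sample's own background. Consequences: the ChIP background sits below
  the input background after mass normalization, as in real ChIP-seq.
* **Orthology**: window identity decays as exp(−0.0239·t) with Gaussian
  scatter (sd 0.08), putting ~27% of 25-Myr windows under the 50%
  identity cutoff; the unmappable fraction rises linearly with split time
  to 5% at 25 Myr.
* **Polymorphism**: panels are drawn from a parameterized site-frequency
  spectrum (mass ∝ 1/i^skew) rather than a coalescent — fast,
  deterministic, and sufficient for statistic recovery; the coalescent
  backend (msprime) is used where the null distribution itself is the
  object (HKA). Purifying classes use constraint 0.35 and skew 1.8;
  positive classes inflate fixed differences by 1/(1−α_true) with
  α_true = 0.4 by default.
* **Expression**: negative-binomial counts (dispersion 0.1) around
  lognormal baselines; genes nearest a diverged site receive a true
  16-fold change with probability 0.5, versus 0.1 for background genes.

What the synthetic validation does **not** establish: the generator has no
sequencing error, duplicate reads, mappability structure beyond the
orthology gaps, coverage heterogeneity, or linked selection; real-data
error rates therefore need not equal the synthetic ones. The original
study validated its null by pooling and re-splitting *real* reads — the
synthetic analogue replaces the pool with simulated reads, and the
equivalence of the two constructions is assumed, not established.

## Problem sizes

Validation experiments run on a 200-kb genome with 200 sites and 200k
reads per sample; property tests use 10k-site histories, 100-panel
Tajima comparisons, 10-replicate α-recovery runs and 200-simulation HKA
nulls. These sizes were chosen so the full suite exercises every stage
end-to-end in about a minute while keeping Monte-Carlo error well inside
the asserted tolerances.
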