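# bindturnover

Comparative ChIP-seq analysis of insulator-protein (CTCF) binding-site
evolution across four *Drosophila* species — *D. melanogaster*,
*D. simulans*, *D. yakuba* and *D. pseudoobscura*, which split from
*D. melanogaster* roughly 2.5, 6 and 25 Myr ago. The package is written
for regulatory-genomics researchers who want to quantify how fast
transcription-factor binding turns over between close species, date the
birth of individual binding sites, and test whether that turnover is
shaped by natural selection.

## What it computes

**Peak calling on compiled density profiles (CDP).** Replicate read sets
are kernel-smoothed into per-coordinate densities, depth-normalized, and
combined into a mean enrichment track `mean(ChIP) − mean(input)` and a fold
track `mean(ChIP)/mean(input)`. The enrichment threshold is empirical: the
ChIP/input labels are permuted, 10,000 random coordinates are sampled per
permutation, and the 99th percentile of the positive null values bounds the
FDR below 1%. Runs ≥ 50 bp above threshold are merged across gaps < 100 bp
and kept when the summit fold is ≥ 2 and the Poisson q-value < 0.001.

**Reference-centric divergence classification.** Reads from the
non-reference species are translated into reference coordinates through an
orthology map (reads with < 50% of bases mappable are dropped), all twelve
samples of a pair are normalized to a common density mass, and at every
coordinate an ANOVA-like linear categorical model is fitted:

    Y = B0 + B_E·Experiment + B_S·Species + B_I·(Experiment × Species) + ε

where `Experiment` indicates ChIP vs input and `Species` the reference vs
other species, so `B_I` is the species-specific ChIP effect. Smoothed
(100-bp sliding window) enrichment and −log10 p tracks classify each
candidate region as shared, reference-specific, other-specific, or —
conservatively — unclassified.

**Evolutionary analysis.** Each reference site carries a 4-bit occupancy
vector over (mel, sim, yak, pse); the 15 possible non-empty patterns form
the evolutionary categories. Fitch small-parsimony on the fixed tree
(((mel,sim),yak),pse) assigns each site an origin branch and an age class
(<2.5, 2.5–6, 6–25, >25 Myr), per-branch gain/loss counts, and the
regression of pairwise divergence on split time yields the turnover rate
in % per Myr.

**Selection and function.** Position-weight-matrix scanning with exact
p-values (dynamic programming over the full score distribution), Tajima's D
and McDonald–Kreitman tables on 37-strain polymorphism panels, a shared
maximum-likelihood adaptive fraction α with profile-likelihood CIs, the
multilocus HKA test with an msprime-simulated coalescent null, RNA-seq
expression-divergence calls (count GLM, BH-adjusted p < 0.01 and
|log2 FC| > 2) and Fisher association tests against binding-site classes,
gene–site phylogenetic-congruence curves and TE-overlap contrasts.

**Synthetic data.** `bindturnover.synthetic` generates every input at toy
scale with recorded ground truth — annotation, gain/loss binding histories
on the phylogeny, replicate ChIP/input reads, orthology maps with
unmappable gaps, strain panels with class-specific frequency spectra, and
expression counts coupled to binding divergence — so every stage has a
parameter-recovery test.

## Worked example

```python
import numpy as np
from bindturnover import evolution, validation

fit = evolution.divergence_rate_regression([17.34, 28.05, 68.37], [2.5, 6.0, 25.0])
print(f"binding divergence rate: {fit['slope']:.2f}% per Myr "
      f"(R^2 = {fit['r_squared']:.3f}, p = {fit['p_value']:.3f})")
rate, headline = evolution.per_myr_rate(89, 2.5)
print(f"mel-branch gains: 89 sites / 2.5 Myr = {rate:.1f} -> ~{headline} per Myr")
res = evolution.parsimony_age((1, 1, 0, 0))
print(f"occupancy (1,1,0,0): origin {res.origin_branch}, age {res.age_class} Myr, "
      f"{res.n_events} event(s)")
errors = validation.classification_validation(seed=1)
print(f"pipeline validation: FPR+FNR = {100*errors['total']:.2f}% "
      f"over {errors['n_orthologous']} orthologous truth sites")
```

prints

```
binding divergence rate: 2.22% per Myr (R^2 = 0.997, p = 0.035)
mel-branch gains: 89 sites / 2.5 Myr = 35.6 -> ~36 per Myr
occupancy (1,1,0,0): origin anc_ms, age 2.5-6 Myr, 1 event(s)
pipeline validation: FPR+FNR = 0.00% over 199 orthologous truth sites
```

The first line regresses the two-way-orthologous binding divergence
percentages of the three species pairs on their split times: binding
diverges at about 2.22% per Myr, almost perfectly linearly. The second
converts a branch gain count into the headline gains-per-Myr figure. The
third dates a site bound in mel and sim but absent elsewhere to the
mel+sim ancestral branch (one gain, 2.5–6 Myr old). The last line runs the
full synthetic self-validation: on a designed 200-site landscape the
classification chain makes no errors among sites with orthologous
sequence.

A shell interface wraps the same stages
(`bindturnover simulate|pipeline|callpeaks|evolve|motif|popgen|express`);
`bindturnover pipeline --outdir out --seed 1` runs
simulate → callpeaks → divergence → evolve end to end and writes a
checksum manifest, so identical configurations are verifiably
bit-identical.

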