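# Methods

This note documents the models, conventions and numerical choices behind
each pipeline stage, and what the synthetic generator does and does not
emulate.

## Detection model and preprocessing

A gene is called present ("positive calling") in a sample when its
hybridization intensity reaches 1000 fluorescence units **and** its
signal-to-noise ratio reaches 2.  The two cutoffs are applied
conjunctively — the standard practice for this chip family, and the only
combination under which a low-intensity/high-SNR probe is (correctly)
rejected.  Genes detected in zero samples are dropped before all
downstream analysis, so "the gene pool" always means genes detected at
least once.

Normalization is per-sample total-sum scaling of the detected
intensities: detected entries are divided by the sample's detected
intensity sum and undetected entries are zero, so every sample column
sums to one.  This is the simplest mass-conserving choice; it makes the
normalized values directly usable as the relative-abundance vector p for
diversity indices.

The core/non-core partition is exact set logic: core = detected in every
sample, non-core = detected somewhere but missing in at least one
sample.  Core genes are carried forward as normalized abundances,
non-core genes as 0/1 presence profiles; this split drives everything
downstream (networks, biomarkers).

## Diversity and group comparison

Shannon diversity is computed in nats (−Σ p ln p over nonzero p) and
"Simpson" is reported as inverse Simpson 1/Σ p², the effective number of
equally abundant genes.  For a sample of ~2,500 genes these conventions
put Shannon near 7.5 (upper bound ln 2500 ≈ 7.82) and inverse Simpson in
the hundreds-to-thousands range; a classical Simpson index (≤ 1) could
not produce values of that magnitude.

Group comparisons are permutation t-tests: the observed statistic is
Welch's unequal-variance t (a robust default; the pooled variant is a
one-line change), and the null distribution comes from relabeling the
samples.  When the number of label assignments C(n, n₁) is at most
20,000 the enumeration is exhaustive and the p-value is the exact
proportion of |t| at least as extreme; otherwise a seeded Monte Carlo
with the +1 correction, p = (#{|t_perm| ≥ |t_obs|} + 1)/(N + 1), which
can never return zero.  Significance tiers use strict inequalities:
NS, * (p < 0.1), ** (p < 0.05), *** (p < 0.01) — so p = 0.05 earns a
single asterisk.  A Benjamini–Hochberg adjusted column accompanies
row-wise (gene- and category-level) tests for reference; tiering follows
the raw p.

Degenerate input (both groups constant with equal means) is assigned
t = 0 and hence p = 1 rather than NaN.

## Gene sharing and the saturation curve

Pairwise sharing between two samples defaults to the union convention,
100·|A∩B|/|A∪B|, with mean- and min-denominator options (the choice
matters by several percentage points and the union is the only
convention consistent with pairing a shared count with a
"total detected in the subset" denominator).  The group-core fraction is
100·(genes in all subset samples)/(genes in any subset sample), rounded
to one decimal.

The saturation curve draws, per iteration, one random ordering of the
host pool and counts the genes common to the first k hosts for every k.
A prefix of a uniform random ordering is a uniform random k-subset, so
the per-k mean estimates the subset average, while the nesting makes
every iteration — and therefore the mean curve — monotone
non-increasing, and pins the k = n point exactly at the pool's core size
with zero variance.  Default 100 iterations.

## Co-presence networks

The association measure, threshold and module algorithm are deliberately
simple and fully specified: Pearson correlation of normalized
intensities (core networks) or of 0/1 profiles, i.e. the phi coefficient
(non-core networks); an edge requires a positive association at or above
the threshold (default 0.8); modules are connected components of the
thresholded graph, with greedy modularity communities available as an
option.  Only positive associations become edges — a co-*presence*
network links genes that rise and fall together.  Genes with constant
profiles in the group (all-present or all-absent non-core genes,
constant-intensity core genes) have undefined correlations and stay
isolated.

Non-core sub-networks are scoped to metabolic pathway groups:
Carbon-associated (Complex Carbohydrates, Feeder Pathways to Glycolysis,
Respiration), AA-associated (Amino acid transport and metabolism, Amino
acid synthesis) and Nitrogen-associated (Nitrogen Metabolism).

Module ids are ordered by decreasing size with ties broken by the
lexicographically smallest member gene, so labeling is invariant to gene
order.  Module counts and sizes are strongly data- and
threshold-dependent; they are reported as descriptive summaries, not
matched against any external count.

## Ordination and MRPP

Correspondence analysis decomposes the chi-square standardized residuals
S = D_r^{-1/2}(P − rcᵀ)D_c^{-1/2} by SVD; eigenvalues are squared
singular values (each in [0, 1]) and scores are principal coordinates.
DCA is implemented as detrending by segments: axis 1 is kept unchanged,
and axis-2 scores are centered within each of 26 (default) equal-width
bins of axis 1.  Hill's nonlinear rescaling is deliberately omitted: it
is under-determined from available descriptions, and the quantity of
interest here — whether host groups separate in the ordination plane —
does not depend on it.

MRPP reports the observed delta (the n_i/N-weighted mean of within-group
mean pairwise distances; classical group-size weighting), the
chance-corrected effect size A = 1 − δ_obs/δ_exp with δ_exp the mean of
the permuted deltas, and p = (#{δ_perm ≤ δ_obs} + 1)/(n_perm + 1).  The
default distance is Bray-Curtis on the normalized intensities; any scipy
pdist metric or a precomputed matrix is accepted.  The unit tests
cross-check delta and A against R vegan's `mrpp` and the CA eigenvalues
against vegan's `cca` on small matrices.

## Triplet biomarkers

The discriminative unit is an ordered-free set of three non-core genes.
Each group's samples are split into training/testing subsets in every
possible way (10 samples split 7/3 → 120 groupings per group; the same
7/3 scheme is applied to both groups).  A bootstrap loop (default 50
iterations) draws one split per group uniformly from the 120 × 120 grid
and applies two steps:

1. *Feature selection*: genes are ranked by the absolute difference of
   their presence frequencies between the two groups' training samples;
   the top `n_top_genes` (default 25) seed the candidate set.  All
   C(25, 3) = 2,300 triplets among them are evaluated (capped at
   `n_candidates_per_split`, with uniform sub-sampling beyond the cap).
   A uniform random draw over all ≈10⁹ possible triplets was rejected:
   it almost never revisits any specific strong triplet, so selection
   frequencies carry no signal.
2. *Classification*: each group's consensus pattern is the per-gene
   majority over its training samples (an exact tie yields an ambiguous
   bit encoded as 0.5, equidistant from both states — ties then count
   against the triplet).  The training score is the fraction of the 14
   training samples strictly closer in Hamming distance to their own
   group's consensus; each of the 6 test samples is assigned to the
   nearer consensus, ties counted incorrect.

Per-triplet accuracies are averaged over every split in which the
triplet was evaluated, and triplets with mean held-out accuracy ≥ 80%
(default) are selected.  A triplet is attributed to the group whose
consensus pattern is predominantly "present".  Equally accurate triplets
are ranked by the mean per-gene frequency gap, then by how many of the
three genes are present in the assigned group's consensus, then by gene
ids — deterministic, data-driven tie-breaks; without them the top rank
among observationally identical features would be decided by gene
naming.

*Exclusive-pattern* genes are genes occurring in the selected triplets
of exactly one group.  Over a very large selection this is computed on
each group's shortlist of top-ranked markers (`top_n`), since with tens
of thousands of passing triplets every frequent gene eventually appears
in both lists.

## Synthetic data generator

The generator emulates the structure of a two-group chip experiment at
the scale of the emulated study population: 10 + 10 samples and a 5,400
probe pool of which ~3,700 genes are detectable somewhere, per-sample
richness ~2,600, a ~37% group functional core and ~73% mean pairwise
sharing, Shannon ~7.45 and inverse Simpson ~1,100.

Presence model: a core fraction (default 0.205) of genes is present in
all samples.  Each remaining gene draws a baseline presence probability
from a Beta distribution with mean 0.42 and concentration 0.3 — strongly
U-shaped, mixing near-ubiquitous and rare genes, which is what keeps the
ever-detected pool finite while group cores stay large.  A per-gene
group effect shifts the probability by ±group_effect/2 (default ±0.5) on
the logit scale with a random direction.  Planted structure: a few
exclusive genes (presence 0.9 in one group, exactly 0 in the other) and
discriminative triplets (0.95 vs 0.05).

Signal model: present genes draw intensity from lognormal(log-mean 8,
log-sd 1) — chosen so the inverse Simpson of a ~2,500-gene sample lands
in the high hundreds-to-low thousands — and SNR from lognormal(ln 10,
0.8).  No mechanistic noise model is claimed for these choices; they are
the generator's own convention.  A present gene can still fall below a
cutoff (≈16% joint thinning), so the positive-calling filter does real
work; core and planted-marker genes are exempt (their present entries
are drawn from the cutoff-truncated distributions) so the planted
partition is exactly recoverable.  Absent genes receive background
intensity (lognormal, mean 200) and an SNR clipped below the calling
cutoff, never omitted values.

With the default group effect the generator reproduces the emulated
study's qualitative contrast: diversity indices do not differ between
groups (permutation t-tests NS) while community structure does (MRPP
p < 0.01).

What the generator does **not** emulate: probe-level hybridization and
probe-to-gene summarization, dye/array spatial artifacts, intensity
correlation between genes of the same organism, category-specific
abundance distributions, or any real phylogenetic structure.  Passing
tests therefore demonstrate that the pipeline's logic is correct and its
statistics calibrated on data of realistic shape — not that the
biological conclusions transfer to any particular real cohort.

## Determinism and problem sizes

All randomness flows from explicit seeds; the pipeline derives one seed
per stage from the root seed and records them in the run manifest, and
two runs with the same root seed produce byte-identical TSV artifacts.
The test suite uses down-scaled problem instances (hundreds of genes,
5–10 samples per group, a few thousand permutations) chosen so each
statistical check retains its power — e.g. type-I error of the
permutation t-test is estimated from 1,000 null simulations at 499
permutations each, and Monte-Carlo MRPP p-values are compared with
exhaustive 20-split enumerations on 6-sample toys.

## Known limitations

- The non-core phi networks inherit phi's dependence on marginal
  frequencies: genes with very unbalanced presence cannot reach |phi| = 1,
  so rare genes are structurally under-connected.
- DCA omits nonlinear rescaling; axis-2 scales are not comparable to
  implementations that apply it.
- The triplet search is a guided heuristic, not exhaustive; the count of
  selected triplets grows with search breadth (`n_top_genes`,
  `n_bootstrap`) and is meaningful only relative to those settings.
- MRPP's expected delta is estimated from the permutation sample, so the
  A statistic carries Monte-Carlo noise of order 1/√n_perm.
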