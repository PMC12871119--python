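# Methods

## Raw divergence metrics

**Sequence.** The built-in estimator is the Nei–Gojobori counting method
(NG86). Codon columns with a gap or ambiguity character in either
sequence, or a stop codon, are removed pairwise. Each codon position
contributes a synonymous site fraction equal to the share of its three
possible single-nucleotide changes that preserve the amino acid; changes
to stop codons count as nonsynonymous, so N + S = 3 × (codons compared)
exactly. Site counts are averaged across the two sequences. For codons
differing at d ∈ {2, 3} positions, synonymous/nonsynonymous difference
counts are averaged with equal weights over the d! substitution orderings
that avoid stop-codon intermediates; if every ordering is blocked (rare),
all orderings are used. Proportions pn = Nd/N and ps = Sd/S are corrected
with the Jukes–Cantor formula K = −(3/4)·ln(1 − (4/3)·p); when the
logarithm argument is nonpositive the estimate is reported as undefined
and the gene is dropped during table assembly. The estimator agrees with
Biopython's independent NG86 implementation to 1e-9 on every codon pair
without stop-adjacent substitution paths; on the remaining pairs the two
differ by convention (Biopython keeps stop-passing paths). Maximum
likelihood codon models are deliberately out of scope — codeml pairwise
output can be parsed and used in place of the built-in estimator, and a
config switch selects Ks instead of Ka as the sequence-level metric.

**Expression.** A gene is dropped if TPM < 1 in all tissues in either
species — the filter is applied per species because a gene unexpressed
in one species has no comparable profile. Surviving values are
transformed log2(TPM + 1); the pseudocount is needed because TPM = 0
occurs in individual tissues after the all-tissues filter, and base 2 is
the transcriptomics convention. "Relativizing" divides each gene's
log-profile by its sum across tissues so that profiles sum to one and
compare shape rather than magnitude; divergence is the Euclidean distance
between the two relativized profiles over matched tissues. Relativization
happens per species before tissue matching. Quantile normalization of the
TPM tables is upstream of this package.

**Structure.** Divergence is 100 − s for a similarity score s ∈ [0, 100]
from flexible structural alignment; the package parses FATCAT text output
with a tolerant token scanner (formats vary across versions and only the
similarity, p-value, RMSD, and twist count are needed).

## Standardization

Box-Cox requires strictly positive input, but divergence data contain
exact zeros — identical proteins have Ka = 0 and identical structures
s = 100 — so when zeros are present a data-driven shift (half the
smallest positive value) is added first. λ is fitted by maximizing the
profile log-likelihood over [−5, 5] (bounded scalar minimization,
absolute tolerance 1e-6); divergence data are mildly skewed, and optima
outside this interval indicate degenerate input. z-scores use the sample
(n−1) standard deviation; at the gene counts involved the choice is
immaterial, but one convention must be fixed for exact tests.

**Fitting granularity.** By default one λ is fitted per pooled
standardization dataset: per taxon for the taxon-specific z-scores
(all three levels pooled) and per level for the level-specific z-scores
(all taxa pooled). This keeps every z-score pool on a single common
transformed scale. The alternative — one λ per (taxon, level) dataset,
with both z-score variants pooling the per-dataset transforms — is
available as `granularity="per-dataset"`; it normalizes each dataset
more closely but pools values transformed with different λ, i.e. in
different effective units, which is statistically delicate. Because the
pooled default uses different transforms for the two z-score variants,
the standardized table carries a (λ, shift, transformed) column triple
for each variant; in per-dataset mode the two triples coincide.

**What the orderings mean.** Group means of pooled z-scores are
constrained: within each pooling the per-group means average to zero, so
no taxon can have the highest *mean* z at every level and no level can
have the highest *mean* z in every taxon. The orderings reported by the
comparison stage are therefore medians — the statistic a boxplot
displays — and they carry information precisely because the transformed
groups remain asymmetric to different degrees. The dominant source of
that asymmetry in real divergence data is the saturation mass at zero
(conserved genes), which no power transform can symmetrize away: a group
with more zeros has its pool dragged down relative to its median. Median
orderings should be read as statements about typical genes, not about
group averages.

## Synthetic data

The generator draws, for each gene, a 3-dimensional Gaussian vector with
a per-taxon correlation matrix (default off-diagonal 0.30, matching the
small positive cross-level correlations the analysis expects), maps it
through the standard normal CDF, and inverts a zero-inflated gamma
marginal per (taxon, level): with probability `zero_inflation` the raw
divergence is exactly zero (saturation), otherwise it is a gamma draw.
Everything is reproducible from a single integer seed.

The default parameter table encodes the qualitative ordering structure
the pipeline is expected to reveal, via three mechanisms:

* saturation mass increases from sequence to expression to structure in
  every taxon, so each level pool's mean is dragged down in proportion
  and the median level-specific z rises in that order for every taxon;
* the Drosophila row carries the most total saturation and the primates
  row the least, which uniformly raises (respectively lowers) a taxon's
  medians within its own taxon-specific pool, making Drosophila highest
  at every level;
* the primates sequence scale is reduced relative to its other levels,
  placing primates lowest at the sequence level.

Scale parameters are matched to the saturation masses so that group
medians stay aligned and the atoms act through pool means rather than
group positions; the numerical values were calibrated by simulation at
design time and validated on seeds disjoint from the calibration set
(100/100 runs at 2000 genes/taxon reproduce all orderings, mean worst
margin ≈ 0.10 standard units).

What the generator does **not** emulate: phylogenies, indels, alignment
error, tissue-specific expression programs, realistic protein geometry,
the order-of-magnitude unit differences between raw levels (defaults use
stylized units of roughly 0.1 / 0.3 / 0.5), or realistic zero fractions —
the default saturation masses (up to 0.42) are chosen to make the median
mechanisms robust at the default sample size, not to match any organism.
Passing tests therefore demonstrate that the pipeline's machinery
recovers known structure from data of the assumed form; they say nothing
about whether real divergence data have that form.

The codon simulator draws the ancestor uniformly over sense codons and
applies Poisson numbers of synonymous/nonsynonymous single-nucleotide
events (means t·sites from the ancestor's NG86 site counts) in random
interleaved order, choosing uniformly among currently available changes
of the requested class and rejecting stops — a uniform-proposal scheme,
not a full codon rate matrix, which suffices for approximate rate
targets. NG86 recovery of the targets is within ±0.02 for loads ≤ 0.3
when both classes are present; under extreme asymmetry (one class zero,
the other at 0.3) pathway averaging of multi-hit codons leaks ~0.02
between classes, an inherent property of counting estimators.

## Statistical machinery

Mann–Whitney U uses the exact null distribution (full enumeration) when
max(n1, n2) ≤ 8 and the pooled sample is tie-free, otherwise the normal
approximation with tie and continuity corrections; the reported U is
min(U1, U2) and the two-tailed p doubles the one-tailed p, capped at 1.
The approximation deviates from the exact p by at most ~0.011 at
n1 = n2 = 8; group sizes in practice are in the thousands. Correlations
are Pearson and Spearman (average ranks for ties) with two-sided p-values
from the t transform with n − 2 degrees of freedom. The per-taxon linear
models are OLS with intercept, one rotation per response level; a
rank-deficient design raises rather than silently producing coefficients.

Tail extraction ranks genes within each (taxon, level) and takes
k = max(1, floor(fraction · n)) from each end (default fraction 0.025);
because the standardization is strictly monotone, ranking on raw values,
transformed values, or z-scores yields identical sets, and boundary ties
are broken lexicographically by gene id. The overlap baseline draws three
independent uniform k-subsets per replicate (default 101 replicates,
medians reported — a single draw would be noise-dominated) and records
the triple intersection; its expectation is k³/n². Enrichment uses the
standard upper-tail hypergeometric test against a user-supplied
genome-wide background with Benjamini–Hochberg control (terms with zero
study hits report p = 1); it replaces the DAVID web service's
modified-Fisher EASE score, and GO hierarchy propagation is the user's
responsibility upstream.

## Numerical choices and degenerate inputs

The Box-Cox transform is computed as expm1(λ·log x)/λ to avoid
catastrophic cancellation for |λ| near zero. Constant-valued groups,
groups with fewer than three values, zero-variance pools, empty gene
intersections, and study genes outside the background all raise typed
errors instead of propagating NaN. Copula correlation matrices are
validated for symmetry, unit diagonal, and positive semidefiniteness
(with an eigenvalue-clipping square root for numerically semidefinite
inputs). The pipeline fans a single seed out to stage seeds through a
fixed SeedSequence derivation, and identical (config, seed) runs produce
byte-identical output trees, recorded in a manifest with a configuration
hash and per-file digests.

## Known limitations

* NG86 is a counting estimator: no transition/transversion weighting, no
  codon frequencies, and saturation (p ≥ 3/4) is reported as undefined
  rather than extrapolated. For distant pairs a likelihood method
  (codeml, parsed by this package) is preferable.
* Comparisons between distributions that share genes (e.g. two levels of
  the same taxon) are performed unpaired, as in the figure conventions
  they mirror, although the samples are not independent.
* No multiple-testing correction is applied across the figure-level
  Mann–Whitney comparisons; BH control applies within each enrichment
  table only.
* The median-based ordering statements depend on residual asymmetry of
  the transformed groups; on data without saturation zeros (or after a
  transform that fully symmetrizes every group) all such orderings
  collapse toward ties, and that is a property of the standardization
  itself, not of this implementation.
* Problem sizes in the test suite and acceptance script (2000 genes per
  taxon, 100 replicate runs, 500-codon alignments, 50 replicates per
  recovery setting) were chosen as the smallest sizes at which the
  checked properties are stable; all scale linearly if increased.
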