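# Methods

## Genome distance estimation

Each genome (one or more contigs) is reduced to the set of its canonical
k-mers: for every window of k consecutive bases, the lexicographic minimum
of the k-mer and its reverse complement. Windows containing any non-ACGT
symbol are skipped and contigs shorter than k contribute nothing. K-mers
are packed into 64-bit integers at 2 bits per base (A=0, C=1, G=2, T=3),
which limits k to 32 — the same ceiling Mash uses — and makes the integer
order coincide with lexicographic order, so canonicalization is an integer
minimum. Hashing applies a seeded splitmix64 finalizer to the packed code;
with a fixed `hash_seed` (default 42) sketches are bit-reproducible across
platforms and runs, which is required for sketches to be comparable at all.

A sketch keeps the s smallest distinct hash values (bottom-s MinHash,
default s = 10 000). The Jaccard index of two genomes is estimated with the
merged estimator: let U be the s smallest values of the union of the two
hash sets; the estimate is |U ∩ A ∩ B| / |U|. Whenever s is at least the
size of the union of the two k-mer sets, the estimate equals the exact
Jaccard to machine precision (the test suite checks this equality, not
approximate agreement). The estimate is converted to a distance with the
Mash formula D = −(1/k)·ln(2j/(1+j)); j = 0 is mapped to D = 1 rather than
infinity so distance matrices stay bounded for clustering, and D is capped
at 1. Under the Poisson substitution model behind this formula, a pair of
sequences diverged at per-site rate r gives D ≈ −ln(1−r) ≈ r, and the
distance–divergence tests require |D − r| ≤ 0.005 for r up to 0.05 at
k = 21, s = 10 000, 100 kb.

Defaults: k = 21 (the standard genome-sketching k-mer size; small enough to
keep k-mer sharing high at 5% divergence, large enough that random 21-mer
collisions are negligible at genome scale), s = 10 000.

## SGB clustering

Species-level genome bins (SGBs) are flat clusters of an agglomerative
average-linkage (UPGMA) hierarchy over the Mash distance matrix, cut so
that every merge whose average inter-cluster distance is ≤ 0.05 is applied
and none above it. Two conventions are fixed deliberately because they are
otherwise underdetermined:

- **Inclusive cut.** A merge at exactly the threshold is applied ("spanning
  5% genetic diversity" reads as a closed bound). At 1% within- and ~35%
  between-species divergence nothing sits near the boundary, so the choice
  only matters for adversarial inputs.
- **Tie-breaking.** When two candidate merges share a height, the pair
  whose lexicographically smallest member id is smallest merges first.
  This makes the partition invariant to genome input order; the test suite
  permutes inputs and requires identical partitions.

UPGMA is monotone (no inversions), so merge heights are non-decreasing and
the flat cut is well defined. The implementation uses the Lance–Williams
average update; correctness is pinned against two independent oracles: a
brute-force clusterer that recomputes every average from the raw matrix at
each step, and scipy's hierarchical clustering on random matrices.

SGB ids are assigned by descending member count, ties by smallest member
id. Classification: an SGB is a *kSGB* if it contains at least one
reference genome or at least one human MAG (a stricter reference-only
definition sits behind `ksgb_requires_reference`), an *fSGB* if all its
members are food MAGs, and *other* otherwise. Before clustering, genomes
are screened with the medium-quality MAG filter completeness > 50% and
contamination < 5% (both strict).

Ordination uses classical (Torgerson) MDS: double-center the squared
distance matrix, eigendecompose, scale eigenvectors by the square roots of
the positive eigenvalues. Eigenvalues below a relative floor of 1e−9 of
the leading eigenvalue (absolute floor 1e−12) are treated as zero;
negative eigenvalues (non-Euclidean inputs) are truncated, and if fewer
positive eigenvalues than requested dimensions exist the output is reduced
with a warning. Coordinates are reproducible up to sign.

## Prevalence profiling

Tables are MetaPhlAn-style: rows are lineage strings
(`k__...|g__Genus|s__Genus_species`), columns are samples, values are
relative abundances in percent. Detection is *strictly* greater than
0.01%; the prevalence gate for retaining species is *strictly* greater
than 0.1% prevalence in the gut (stool) stratum. Prevalence per stratum is
n_positive/n_total with NA-valued samples excluded from that grouping's
denominator; mean abundance is computed over positive samples only and is
undefined (NaN) when none exist. The LAB set is the genera *Lactobacillus*,
*Lactococcus*, *Leuconostoc*, *Weissella* plus *S. thermophilus*; merged
taxa (e.g. *Lb. casei/paracasei*) are handled by a configurable species
alias map applied before any computation.

Contrasts between two named strata build, per species, the 2×2 table of
(positive, negative) × (group A, group B) and use the two-sided Fisher
exact test with the minimum-likelihood rule: p is the sum of
hypergeometric probabilities of all tables with the observed margins whose
probability is ≤ that of the observed table, with a relative tolerance of
1e−7 on the comparison to absorb floating-point ties between symmetric
support points. Degenerate margins give p = 1. The implementation is
verified against exhaustive enumeration in exact rational arithmetic on
every table with total ≤ 40 (agreement to 1e−12) and against scipy's
`fisher_exact`. Multiple testing uses Benjamini–Hochberg step-up
(statsmodels), applied across the species within one contrast; the FDR
family is per-contrast by design, since each contrast is reported as a
unit.

## Pangenome enrichment

Gene matrices are genome × gene boolean presence/absence (Roary-style CSV
or binary TSV are read; the gene clustering itself is consumed, never
recomputed). Genomes with completeness ≤ 80% (strict) are removed first;
then genes present in fewer than 5% (exclusive via the inclusive lower
bound ≥ 5%) or in ≥ 95% of the retained genomes are removed — core and
near-absent genes carry no signal for a prevalence contrast. Genomes
labelled `other`/`NA` are excluded from testing and, by default, from the
band denominator as well. Each retained gene is tested with the shared
Fisher implementation and BH-corrected across retained genes; `enriched_in`
is the group with the higher prevalence.

Power and calibration are pinned on planted designs: with 50+50 genomes
and 20 of 500 genes planted at 80% vs 20% prevalence, all 20 planted genes
must reach q < 0.05 and at most 5% of null genes may; under a pure null
the fraction of genes with p < 0.05 must lie in [0.03, 0.07]. The null
band is asymmetric around 0.05 because Fisher's test is conservative on
discrete tables: an exact design calculation (summing binomial
probabilities of all 2×50 tables) gives a true size of 0.035 at background
prevalence 0.5, which is also why 0.5 is the generator's background
default — it maximizes the achievable size at this sample size.

## Synthetic data

The generators define the study conditions for all tests.

- **Genomes.** Alphabet A/C/G/T only; substitutions replace a base with one
  of the three alternatives uniformly, so expected identity is exactly
  1 − rate. Each species draws a centroid from a shared random ancestor by
  i.i.d. substitutions at the between rate (default 0.2, giving ~35%
  pairwise centroid divergence), or independently in "unrelated" mode
  (expected shared 21-mers ≈ 0, exercising the saturated j = 0 → D = 1
  branch). Each strain is its centroid with substitutions at the within
  rate (default 0.01), so strain–strain divergence is ≈ 2% — with the 5%
  threshold bracketed from both sides. MAG incompleteness is emulated by
  cutting the genome into ~5 kb fragments and keeping a random fraction,
  with the recorded completeness set to 100 × keep_fraction.
- **Abundance tables.** Per (species, stratum): presence is Bernoulli with
  the planted probability; abundance on presence is lognormal in percent
  (a standard heavy-tailed model for relative abundances — a modelling
  choice, since no generative model is implied by the prevalence
  definitions themselves). Default log-scale location −0.5 to 0 and scale
  1 put draws well clear of the 0.01% detection floor (P(draw < floor)
  ≈ 5e−5), so empirical prevalence converges to the planted probability.
- **Gene matrices.** Independent Bernoulli presence per gene and genome;
  planted differential genes use per-group probabilities, background genes
  share one probability across groups.

One global seed fans out to per-component substreams via numpy
`SeedSequence` spawning; identical arguments and seed reproduce outputs
byte-for-byte.

What the generators do **not** emulate: indels, rearrangements, horizontal
transfer, chimerism or contamination in MAGs; compositional coupling
between species in a sample (abundances are drawn independently and are
not renormalized to 100%); marker-gene profiling noise (tables are treated
as exact draws from the planted model); linkage between genes in the
pangenome. Passing tests therefore demonstrate correctness of the
*machinery* (distances, clustering, counting, testing) under a clean
generative model, not robustness to assembly artefacts or profiling bias
in real data.

## Problem sizes and numerical choices

The test and acceptance workloads use desk-scale sizes chosen to make each
statistical check sharp at small cost: 100 kb genomes for
distance–divergence (binomial noise on the k-mer survival fraction is then
well inside the ±0.005 band), 5 species × 4 strains for partition
recovery, 2000 samples per stratum for prevalence recovery (99% binomial
intervals of ±3 percentage points), 500 random matrices of size ≤ 8 for
the clustering oracle, all 2×2 tables with total ≤ 40 for Fisher, and 2000
null genes for type-I calibration.

Other fixed conventions: empty sketches (no valid k-mer) are flagged and
excluded from distance matrices with a warning; distance matrices are
validated for symmetry, zero diagonal, and range on construction;
odds ratios report inf for a zero denominator with non-zero numerator and
NaN for 0/0; all tables on disk are tab-separated UTF-8 with a header row
and `NA` for missing values.

## Known limitations

- Mash distance saturates near j = 0; between-species distances above
  ~0.3 true divergence are reported at or near the cap of 1 and are not
  meaningful beyond "far apart" — which is all the 5% cut needs.
- The O(n³) in-house UPGMA targets desk-scale catalogues (hundreds of
  genomes), not the hundreds of thousands of a full survey; the clustering
  semantics, not throughput, are the point here.
- Fisher + BH on strata with very unequal sizes is conservative; no
  continuity-corrected or mid-p variants are offered.
- The prevalence machinery assumes percent-unit tables; proportions in
  [0, 1] must be scaled by the caller.
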