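# Methods

This note documents the models, conventions and design choices behind
`mirnapop`, in the order the pipeline applies them.

## Hairpin regions

Internal coordinates are 0-based half-open; GFF3/VCF 1-based input is
converted at the boundary. The seed is transcript positions 2–8 of a mature
(7 nt, inclusive); the mature's position 1 nucleotide is counted in `mat`,
not in the seed. On the minus strand transcript order runs from the high
genomic coordinate downward, so the seed of a mature `[s, e)` is
`[e−8, e−1)`. Flanks abut the hairpin span on each side and have the span's
length; `flank5` is on the transcript 5′ side. When only one mature is
annotated the loop cannot be delimited, so the whole stretch from the end of
the given mature to the start of the opposite flank is labelled `pre` and no
loop is emitted. Intervals shared by two or more hairpin spans are labelled
`ovlp`; SNPs inside them are flagged and excluded from region-specific
diversity, but the hairpins themselves are kept.

Cluster detection chains hairpins on the same chromosome and strand whose
inter-span gap (end-to-start distance; 0 for overlapping spans) is at most
10 kb, by single linkage; groups of ≥ 2 are clusters, the rest are isolated.
Genomic context uses a ≥ 1 bp overlap with protein-coding, lncRNA and
transposable-element interval sets; `Intg` means neither gene class
overlaps. Evolutionary age groups are consumed as a two-column table — they
are curated data, not something this package re-derives.

## Variants and haplotypes

Only biallelic SNPs with a known ancestral allele matching REF or ALT are
kept; genotypes are re-polarized so 1 always means the derived allele
(an involution — applying it twice restores the input). Lowercase ancestral
calls (the low-confidence convention of large callsets) are accepted by
default; a flag requires uppercase. Missing genotypes are rejected outright
when haplotype statistics are requested, because EHH is undefined with
missing data. The minor-allele-frequency rules are implemented as: the
global threshold (default 0.5%) gates the dataset, the per-population
threshold (default 1%) additionally gates population-level statistics. The
order of the two gates does not matter under this reading.

## Diversity

Per-site diversity uses the unbiased pairwise-mismatch form
π = 2p(1−p)·n/(n−1); this equals the exact fraction of mismatching
haplotype pairs, and region diversity is Π = Σπ/L over the region's SNPs
and length. π is symmetric in p ↔ 1−p, so Π does not depend on the
polarization, and Π·L is additive over disjoint sub-regions.

Per-position profiles support two anchorings, because hairpins differ in
length and no canonical alignment of precursors exists: mature-anchored
indexing (offset from each region's transcript-5′ end, the default, since
the positions of interest sit inside the matures) and relative-length
binning (each precursor scaled onto a fixed number of bins,
`bin = floor(n_bins·offset/length)`). Both are approximations of
cross-hairpin homology and are labelled as such; positions with zero
coverage are reported as missing, never as zero diversity.

Group comparisons use Kruskal–Wallis and pairwise two-sided Wilcoxon
rank-sum tests with Bonferroni correction (p multiplied by the number of
pairs, capped at 1). The Wilcoxon null is exact when both groups have fewer
than 50 tie-free observations and asymptotic otherwise, mirroring the
convention of R's `wilcox.test`, the tool such analyses conventionally run
through. The joint model of diversity on age, clustering and context is
ordinary least squares with one-hot categorical encoding (first sorted
level as reference); collinear designs raise an error naming the aliased
column rather than silently dropping it.

## Differentiation

The per-SNP Hudson estimator is used because it is insensitive to sample
size: N = (p₁−p₂)² − p₁(1−p₁)/(n₁−1) − p₂(1−p₂)/(n₂−1),
D = p₁(1−p₂) + p₂(1−p₁), F̂ = N/D. Sites monomorphic in both populations
(D = 0) are undefined, flagged, and dropped before aggregation. The
estimator is symmetric in the two populations, gives exactly 1 for fixed
differences, and is slightly negative for identical frequencies (finite-
sample bias of order 1/(n−1)).

Two multi-locus combinations are provided. The ratio of means (ΣN/ΣD) is
the consistent estimator of the differentiation parameter and is what the
parameter-recovery experiment uses; the mean of per-SNP ratios is biased
low (≈ 0.08 at a true F = 0.1 with 200 haplotypes) but matches the
"mean F_st per region" convention used for per-unit summaries, so region
and mature aggregation defaults to the mean of ratios with the ratio of
means behind a flag.

Frequency normalization regresses F̂ on global MAF and keeps the residual.
The regression is fitted per population pair by default — the MAF–F_st
relationship varies with pair divergence — with a pooled mode available;
fewer than three records, or an all-equal MAF design, degrade to
mean-centering with a warning. Top-SNP extraction takes scores strictly
above the pooled quantile (ties at the cut are excluded; all-equal scores
give an empty set).

## Haplotype statistics

EHH at an offset is the probability that two random carriers of the core
allele are identical at every site from the core to that offset, computed
by refining the carrier partition site by site
(EHH = Σ_g C(|g|,2)/C(n,2)). The curve starts at 1 and is non-increasing;
it is truncated when EHH < 0.05 (the cutoff convention of the standard
scan software, exposed as config), when the gap to the next site exceeds
20 kb (flagged `gap-truncated`), or at the matrix edge (flagged
`edge-truncated` and kept — small synthetic matrices would otherwise lose
every core). iHH is the trapezoid integral of the curve, clipped at the
cutoff crossing; unstandardized iHS = ln(iHH_A/iHH_D). nSL is identical
except distances count segregating sites (1 per step), which makes it
invariant to monotone distortions of physical positions; the 20-kb gap
rule still bounds its scan. Cores need MAF > 5% and at least two carriers
per allele.

Scores are standardized to mean 0 / variance 1 within equal-width
derived-allele-frequency bins (default 50 — the bin count is not dictated
by anything, so it is exposed), separately per population. The bin
statistics are estimated from a reference score set, by default the scores
themselves, which is the whole-genome-scan convention where sweeps are a
negligible fraction of sites. On short simulated segments where a planted
sweep spans a large share of the sites this convention breaks down — the
swept block floods its frequency bin and absorbs its own signal — so the
calibration experiments fit the bins on the sites outside the block, which
restores the neutral-dominated reference a genome-wide scan provides.
Extreme scores are |z| ≥ 2 (inclusive, both tails; a one-tailed flag is
available since published candidate tables list positive maxima).

## Enrichment

Enrichment of a focal SNP set in an annotation is a Pearson chi-square on
the 2×2 table. The background excludes the focal set by default (an
overlapping background dilutes the contrast); an inclusive mode reproduces
whole-dataset comparisons literally. No continuity correction by default,
Yates available; expected counts below 5 are flagged. CADD PHRED scores
are compared across regions with the same rank tests, and the fraction at
or above 10 (the conventional top-1%-deleterious cut) is reported.

## Target prediction

Canonical sites for a 7-mer seed (mature positions 2–8) in a UTR scanned
5′→3′: the reverse complement of positions 2–7 is the 6mer core; a
preceding match to position 8 upgrades to 7mer-m8, a following A (opposite
mature position 1, regardless of the miRNA's position 1 nucleotide)
upgrades to 7mer-A1, both to 8mer. Each occurrence is reported once with
the strongest applicable type. U and T are interchangeable at the matching
boundary. Only the longest 3′UTR isoform per gene is scanned when isoforms
are present.

Site scoring is a pluggable interface. The full trained context-feature
regression and cross-species conservation scoring of the established
target-prediction pipelines are deliberately out of scope; the default
scorer assigns fixed negative constants ordered by canonical site strength
(8mer −0.31 < 7mer-m8 −0.16 < 7mer-A1 −0.10 < 6mer −0.02), which preserves
the semantics the filter depends on (more negative = stronger repression).
The filter keeps only negative scores and, of those, the sites at or below
the per-miRNA-allele median — inclusive, keeping the stronger half; the
inclusivity is configurable. Per-gene scores accumulate over retained
sites. The allele shift summary is the cosine similarity
|A∩B|/√(|A|·|B|), defined as 0 when either target set is empty. Two
published target-count rows (hsa-miR-4472 and hsa-miR-4741) do not
round-trip to their printed cosine at 2 decimals (0.195 vs 0.19, 0.236 vs
0.23, plausibly truncation); they are excluded from the reproduction
checks.

## Synthetic data

The generators define the conditions every statistical claim is tested
under.

*Structured haplotypes.* Balding–Nichols: per site a global frequency
p ~ Uniform(0.05, 0.95); per population a frequency
~ Beta(p(1−F)/F, (1−p)(1−F)/F), whose expected F_st equals F; alleles
i.i.d. Bernoulli given the population frequency. Defaults are two
populations of 100 phased diploids, 2000 sites at 100 bp spacing, F = 0.1
(the magnitude of human continental pairs). A closed-form simulator was
chosen over a coalescent so that parameter recovery has an exact target;
the cost is no linkage disequilibrium in the neutral background and no
recombination gradient in EHH decay, so test results quantify estimator
correctness, not performance on realistic LD structure.

*Sweeps.* A hard sweep is a copy of one template haplotype's block
(default 20 kb) around the core into a chosen fraction of haplotypes
(default 0.7), which also receive the derived core allele. This guarantees
the long shared haplotype the statistics must detect, with controlled
carrier frequency — a construction, not a forward simulation, so sweep age
and recombination breakdown are outside its vocabulary.

*Annotations and UTR pools.* The annotation fixture enumerates every
partition edge case (both-mature on both strands, 5p-only, 3p-only,
overlapping pair, 8-kb-gap triplet) with a hand-derived truth table that
partitioning must reproduce exactly. UTR pools plant 8mer sites per the
requested (ancestral-only, derived-only, shared) design and
rejection-sample the background so neither seed has an accidental 6mer
core match, making the expected target counts and cosine exact. Seeds
sharing their 6mer core (a SNP at seed position 7) are rejected, since
allele-exclusive sites then cannot exist.

All generators are deterministic given their seed.

## Problem sizes and calibration experiments

The parameter-recovery experiment (F = 0.1, 2 × 200 haplotypes, 2000
sites) bounds the multi-locus estimate within ±0.01 of F. The sweep-power
experiment uses 100 replicates of 200 haplotypes × 500 sites with carrier
fraction 0.7 and asks whether the core's |standardized iHS| exceeds the
95th percentile of the replicate's outside-block |z|; detection holds in
≥ 80% of replicates (observed ≈ 0.85–0.90 across seeds). Under the neutral
model the extreme-score rate at |z| ≥ 2 stays near the Gaussian 4.6%.
These sizes keep the full suite and the acceptance script to a few minutes
on one CPU while leaving the Monte Carlo margins comfortably away from
their thresholds.

## Known limitations

- No linkage disequilibrium or recombination in the neutral simulator;
  EHH decay rates in synthetic data are not calibrated to any genetic map.
- The default site scorer ranks site types only; it does not reproduce
  trained context scores, so absolute accumulated scores are comparative,
  not predictive.
- Per-position profiles approximate cross-hairpin homology by anchoring or
  scaling; neither is a true alignment.
- Haplotype statistics use physical distance only (no cM coordinates), and
  cross-population haplotype statistics (e.g. XP-EHH) are not implemented.
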