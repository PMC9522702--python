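# mirnapop

Population-genomic analysis of human microRNA variation: who carries which
miRNA alleles, how strongly the functional regions of a hairpin differ in
diversity and between populations, and what a seed variant does to the
miRNA's target repertoire.

miRNAs repress their targets through a near-perfect match between the
**seed** (mature positions 2–8) and sites in 3′UTRs, so even a single SNP in
the seed can rewire hundreds of target genes. `mirnapop` implements the full
chain of analyses needed to characterise such variants from standard files
(miRBase-dialect GFF3, phased VCF with ancestral-allele tags, BED context
intervals, 3′UTR FASTA):

- **annotation** — partition each hairpin into seed / mat / loop / pre plus
  equally sized 5′/3′ flanks, handle incomplete (single-mature) annotation,
  mark overlaps between hairpins, assign genomic context (protein-coding,
  lncRNA, transposable-element, intergenic; ≥ 1 bp overlap rule) and detect
  miRNA clusters (inter-hairpin gap ≤ 10 kb, same strand and chromosome).
- **variation** — biallelic SNPs polarized by ancestral state (1 = derived),
  MAF gates (≥ 0.5% global, ≥ 1% per population), per-population haplotype
  matrices, SNP-to-region assignment.
- **diversity** — per-SNP expected pairwise mismatches
  π = 2p(1−p)·n/(n−1), region diversity Π = Σπ/L, per-position profiles,
  Kruskal–Wallis / pairwise Wilcoxon (Bonferroni) comparisons, and an OLS
  model of Π on age, clustering and context.
- **differentiation** — per-SNP Hudson F_st,
  N = (p₁−p₂)² − p₁(1−p₁)/(n₁−1) − p₂(1−p₂)/(n₂−1), D = p₁(1−p₂) + p₂(1−p₁),
  F̂ = N/D, normalized by regressing on global MAF (residual scores),
  aggregated to regions/matures, top-1%/5% candidate tiers.
- **selection** — EHH decay around core alleles, iHS = ln(iHH_A/iHH_D)
  (trapezoid-integrated over bp) and nSL (distance in segregating sites),
  standardized to mean 0 / variance 1 within derived-allele-frequency bins
  per population; |z| ≥ 2 flags extremes; 20-kb gap and MAF > 5% rules.
- **enrichment** — 2×2 chi-square tests of top-F_st SNPs against
  selection-extreme / eQTL / GWAS sets; CADD PHRED comparisons across
  regions (≥ 10 = top 1% most deleterious convention).
- **targeting** — allele-specific seeds, canonical site detection (8mer,
  7mer-m8, 7mer-A1, 6mer), pluggable site scoring with the
  negative-score / per-miRNA median filter, and the target-set similarity
  cosine = |A∩B| / √(|A|·|B|).
- **synthetic** — Balding–Nichols structured haplotypes with tunable F_st,
  plantable hard sweeps, annotation fixtures covering every partition edge
  case, and 3′UTR pools with planted sites and exact truth counts.

## Worked example

```python
from mirnapop import MirnaHairpin, partition_regions, hudson_fst
from mirnapop.evaluation import fst_recovery
from mirnapop.targeting import extract_allele_seeds, allele_target_shift
from mirnapop.synthetic import simulate_utr_pool

h = MirnaHairpin("hsa-mir-example", "chr1", "+", (1000, 1080),
                 mature5p=(1010, 1032), mature3p=(1048, 1070))
for r in sorted(partition_regions(h).regions, key=lambda r: r.interval):
    print(f"{r.label:7s} [{r.interval[0]}, {r.interval[1]})  arm={r.arm}")

print("per-SNP Hudson Fst (p1=0.9, p2=0.1, n=200 each):",
      round(hudson_fst(0.9, 200, 0.1, 200), 4))
print("multi-locus Fst on Balding-Nichols cohort (F=0.1):",
      round(fst_recovery(F=0.1, seed=1), 4))

sv = extract_allele_seeds("UAGCUUAUCAGACUGAUGUUGA", 3, "G", "C",
                          mature_id="mir-ex")
pool, _ = simulate_utr_pool((sv.seed_ancestral, sv.seed_derived),
                            (30, 30, 40), seed=4)
anc, der, cos = allele_target_shift(sv, pool)
print(f"targets(AA)={len(anc)} targets(DA)={len(der)} "
      f"overlap={len(anc.genes & der.genes)} cosine={cos:.4f}")
```

prints

```
flank5  [920, 1000)  arm=na
pre     [1000, 1010)  arm=na
mat     [1010, 1011)  arm=5p
seed    [1011, 1018)  arm=5p
mat     [1018, 1032)  arm=5p
loop    [1032, 1048)  arm=na
mat     [1048, 1049)  arm=3p
seed    [1049, 1056)  arm=3p
mat     [1056, 1070)  arm=3p
pre     [1070, 1080)  arm=na
flank3  [1080, 1160)  arm=na

per-SNP Hudson Fst (p1=0.9, p2=0.1, n=200 each): 0.7794
multi-locus Fst on Balding-Nichols cohort (F=0.1): 0.0997
targets(AA)=70 targets(DA)=70 overlap=40 cosine=0.5714
```

The partition shows the seed occupying transcript positions 2–8 of each
mature (position 1 stays in `mat`), the loop between the two arms and flanks
sized like the hairpin. The multi-locus Hudson F_st over a synthetic
two-population cohort recovers the generating differentiation parameter
F = 0.1, and a seed SNP whose two alleles share 40 of 70 predicted targets
each yields a cosine similarity of 0.57 — the summary the target-shift
analysis reports per candidate miRNA.

## Command line

```bash
mirnapop run --config config.yaml --outdir results/
```

`config.yaml` selects inputs (file paths or `synthetic`), stage toggles, and
all analysis thresholds (MAF gates, cluster gap, EHH cutoff, DAF bins,
top-F_st quantile) in one place. Every output TSV carries the tool version,
config hash and seed; the log reports the counts surviving each filter.

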