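"""Allele-specific miRNA target prediction and target-set similarity.

A SNP in the seed region (mature positions 2-8) yields two seed variants,
one per allele.  Canonical target sites are the UTR occurrences (5'->3') of
the reverse complement of the seed, graded by site type:

    8mer     reverse complement of positions 2-8, followed by an A
             (the nucleotide opposite mature position 1)
    7mer-m8  reverse complement of positions 2-8
    7mer-A1  reverse complement of positions 2-7, followed by an A
    6mer     reverse complement of positions 2-7

Overlapping occurrences are each reported once with the strongest applicable
type.  Sites are scored by a pluggable scorer (more negative = stronger
predicted repression); per miRNA allele, sites with non-negative scores are
discarded and of the remainder only those at or below the allele's median
(the stronger half) are retained.  Per-gene scores accumulate over retained
sites, and the similarity of the two alleles' target-gene sets is

    cosine = |A n B| / sqrt(|A| * |B|)

(0 when either set is empty).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Dict, List, Optional, Sequence, Tuple

import numpy as np
from Bio.Seq import Seq

SITE_TYPES = ("8mer", "7mer-m8", "7mer-A1", "6mer")

# Default per-site scores by type: fixed constants ordered by canonical site
# strength, all negative (stronger repression = more negative).
DEFAULT_SITE_SCORES = {
    "8mer": -0.31,
    "7mer-m8": -0.16,
    "7mer-A1": -0.10,
    "6mer": -0.02,
}


@dataclass
class SeedVariantMirna:
    """A mature miRNA with a seed SNP: the two 7-mer seeds (mature positions
    2-8) for the ancestral and derived alleles."""

    mature_id: str
    mature_seq: str
    snp_id: str
    offset: int  # 1-based position of the SNP in the mature
    seed_ancestral: str
    seed_derived: str

    def __post_init__(self) -> None:
        if len(self.seed_ancestral) != 7 or len(self.seed_derived) != 7:
            raise ValueError("seeds must be 7-mers")
        diffs = [i for i, (a, b) in
                 enumerate(zip(self.seed_ancestral, self.seed_derived)) if a != b]
        # identical seeds are tolerated as a degenerate input (no shift)
        if diffs not in ([], [self.offset - 2]):
            raise ValueError("seeds must differ exactly at the SNP offset")


@dataclass
class TargetSite:
    gene_id: str
    position: int  # 0-based start of the matched pattern in the UTR
    site_type: str
    score: Optional[float] = None

    def __post_init__(self) -> None:
        if self.site_type not in SITE_TYPES:
            raise ValueError(f"unknown site type {self.site_type!r}")


@dataclass
class TargetSet:
    """Filtered predicted targets of one miRNA allele with per-gene
    accumulated scores (sum of retained per-site scores)."""

    mature_id: str
    allele: str  # {ancestral, derived}
    gene_scores: Dict[str, float] = field(default_factory=dict)

    @property
    def genes(self) -> set:
        return set(self.gene_scores)

    def __len__(self) -> int:
        return len(self.gene_scores)


def _rna(seq: str) -> str:
    return seq.upper().replace("T", "U")


def _dna(seq: str) -> str:
    return seq.upper().replace("U", "T")


def extract_allele_seeds(mature_seq: str, offset: int, ancestral: str,
                         derived: str, mature_id: str = "",
                         snp_id: str = "") -> SeedVariantMirna:
    """Build the two allele-specific seeds of a mature with a seed SNP.

    ``offset`` is the 1-based SNP position in the mature and must fall in
    the seed (positions 2-8).  DNA input is transcribed to the RNA alphabet.
    """
    seq = _rna(mature_seq)
    anc, der = _rna(ancestral), _rna(derived)
    if not 2 <= offset <= 8:
        raise ValueError(f"offset {offset} outside the seed (mature positions 2-8)")
    if len(seq) < 8:
        raise ValueError("mature shorter than 8 nt")
    seed_ref = seq[1:8]
    i = offset - 2
    if seq[offset - 1] not in (anc, der):
        raise ValueError(f"mature position {offset} is {seq[offset - 1]}, "
                         f"matching neither allele")
    return SeedVariantMirna(
        mature_id=mature_id, mature_seq=seq, snp_id=snp_id, offset=offset,
        seed_ancestral=seed_ref[:i] + anc + seed_ref[i + 1:],
        seed_derived=seed_ref[:i] + der + seed_ref[i + 1:])


def find_sites(seed: str, utr: str) -> List[TargetSite]:
    """Canonical seed-match sites of a 7-mer seed in one UTR (gene id left
    empty; the caller fills it in).

    The UTR is scanned 5'->3' for the reverse complement of seed positions
    2-7 (mature 2-7); each occurrence is graded up by the match opposite
    mature position 8 (preceding nucleotide) and the A opposite position 1
    (following nucleotide).  U/T are equivalent.
    """
    if len(seed) != 7:
        raise ValueError("seed must be a 7-mer (mature positions 2-8)")
    seed_dna = _dna(seed)
    utr_dna = _dna(utr)
    core6 = str(Seq(seed_dna[:6]).reverse_complement())  # rc of mature 2-7
    m8 = str(Seq(seed_dna[6]).complement())              # nt pairing mature 8
    sites: List[TargetSite] = []
    start = 0
    while True:
        j = utr_dna.find(core6, start)
        if j == -1:
            break
        start = j + 1
        has_m8 = j >= 1 and utr_dna[j - 1] == m8
        has_a1 = j + 6 < len(utr_dna) and utr_dna[j + 6] == "A"
        if has_m8 and has_a1:
            stype, pos = "8mer", j - 1
        elif has_m8:
            stype, pos = "7mer-m8", j - 1
        elif has_a1:
            stype, pos = "7mer-A1", j
        else:
            stype, pos = "6mer", j
        sites.append(TargetSite(gene_id="", position=pos, site_type=stype))
    return sites


def score_sites(sites: Sequence[TargetSite],
                scorer: Optional[Callable[[TargetSite], float]] = None
                ) -> List[TargetSite]:
    """Attach a score to each site (default: fixed per-type constants)."""
    for s in sites:
        s.score = scorer(s) if scorer else DEFAULT_SITE_SCORES[s.site_type]
    return list(sites)


def filter_sites(sites: Sequence[TargetSite]) -> List[TargetSite]:
    """Retain the stronger half of the repressive sites of one miRNA allele.

    Sites with score >= 0 are discarded; among the negative-scoring sites
    the per-allele median is the threshold and sites with score <= median
    (inclusive) are retained.  No negative scores means an empty result.
    """
    neg = [s for s in sites if s.score is not None and s.score < 0]
    if not neg:
        return []
    cut = float(np.median([s.score for s in neg]))
    return [s for s in neg if s.score <= cut]


def cosine_similarity(set_a: TargetSet, set_b: TargetSet) -> float:
    """|A n B| / sqrt(|A| |B|); 0 when either set is empty."""
    return cosine_from_counts(len(set_a), len(set_b),
                              len(set_a.genes & set_b.genes))


def cosine_from_counts(n_a: int, n_b: int, n_overlap: int) -> float:
    """Cosine similarity from set sizes and overlap count."""
    if n_a == 0 or n_b == 0:
        return 0.0
    if n_overlap > min(n_a, n_b):
        raise ValueError("overlap exceeds a set size")
    return n_overlap / math.sqrt(n_a * n_b)


def longest_isoform(utrs: Dict[str, Dict[str, str]]) -> Dict[str, str]:
    """Keep only the longest 3'UTR isoform per gene.

    ``utrs`` maps gene -> {transcript: sequence}; returns gene -> sequence.
    Ties break on transcript id for determinism.
    """
    out = {}
    for gene, iso in utrs.items():
        tx = max(sorted(iso), key=lambda t: len(iso[t]))
        out[gene] = iso[tx]
    return out


def targets_for_seed(seed: str, utr_pool: Dict[str, str],
                     mature_id: str, allele: str,
                     scorer: Optional[Callable[[TargetSite], float]] = None
                     ) -> TargetSet:
    """Find, score and filter sites for one seed over a gene -> UTR pool,
    accumulating retained per-site scores per gene."""
    all_sites: List[TargetSite] = []
    for gene, utr in utr_pool.items():
        for s in find_sites(seed, utr):
            s.gene_id = gene
            all_sites.append(s)
    score_sites(all_sites, scorer)
    retained = filter_sites(all_sites)
    ts = TargetSet(mature_id=mature_id, allele=allele)
    for s in retained:
        ts.gene_scores[s.gene_id] = ts.gene_scores.get(s.gene_id, 0.0) + s.score
    return ts


def allele_target_shift(mirna: SeedVariantMirna, utr_pool: Dict[str, str],
                        scorer: Optional[Callable[[TargetSite], float]] = None
                        ) -> Tuple[TargetSet, TargetSet, float]:
    """Predicted target sets of the ancestral and derived alleles over a UTR
    pool, and the cosine similarity quantifying how much of the target
    repertoire the seed SNP shifts."""
    anc = targets_for_seed(mirna.seed_ancestral, utr_pool, mirna.mature_id,
                           "ancestral", scorer)
    der = targets_for_seed(mirna.seed_derived, utr_pool, mirna.mature_id,
                           "derived", scorer)
    return anc, der, cosine_similarity(anc, der)
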