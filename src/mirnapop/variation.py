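"""Phased variant input, ancestral polarization and haplotype matrices.

Variants are read from a VCF with phased genotypes and an ancestral-allele
INFO tag.  Only biallelic SNPs whose ancestral state is known and matches the
REF or ALT allele are kept; genotypes are re-polarized so that 1 always means
the derived allele.  Per-population haplotype matrices feed the haplotype
statistics (EHH/iHS/nSL); per-population derived-allele frequencies feed
diversity and differentiation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from cyvcf2 import VCF

from .annotation import Interval, RegionSet, region_tree

logger = logging.getLogger(__name__)

VALID_BASES = {"A", "C", "G", "T"}


@dataclass
class SnpRecord:
    """A polarized biallelic SNP with per-population derived-allele
    frequencies and (later) miRNA region assignments.

    ``pos`` is 0-based.  ``region_hits`` holds (hairpin_id, region, arm)
    triples; ``in_ovlp`` marks SNPs inside hairpin-overlap intervals, which
    region-specific diversity excludes.
    """

    id: str
    chrom: str
    pos: int
    ref: str
    alt: str
    ancestral: str
    derived: str
    global_maf: float
    global_daf: float
    pop_freq: Dict[str, float]
    pop_n: Dict[str, int]
    region_hits: List[Tuple[str, str, str]] = field(default_factory=list)
    in_ovlp: bool = False
    include_global: bool = True
    include_pop: Dict[str, bool] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.ancestral not in (self.ref, self.alt):
            raise ValueError(f"{self.id}: ancestral {self.ancestral} not in (ref, alt)")
        if self.derived == self.ancestral:
            raise ValueError(f"{self.id}: derived equals ancestral")
        for f in (self.global_maf, self.global_daf, *self.pop_freq.values()):
            if not 0.0 <= f <= 1.0:
                raise ValueError(f"{self.id}: frequency {f} outside [0, 1]")


@dataclass
class HaplotypeMatrix:
    """Phased binary haplotypes (rows) x sites (columns) for one population;
    1 = derived allele.  Positions are 0-based and strictly increasing."""

    population: str
    haplotypes: np.ndarray
    positions: np.ndarray
    site_ids: List[str]

    def __post_init__(self) -> None:
        self.haplotypes = np.asarray(self.haplotypes, dtype=np.int8)
        self.positions = np.asarray(self.positions, dtype=np.int64)
        if self.haplotypes.ndim != 2:
            raise ValueError("haplotypes must be 2-D")
        if self.haplotypes.shape[1] != len(self.positions):
            raise ValueError("positions do not match site count")
        if len(self.site_ids) != len(self.positions):
            raise ValueError("site_ids do not match site count")
        if not np.isin(self.haplotypes, (0, 1)).all():
            raise ValueError("haplotype entries must be 0/1")
        if np.any(np.diff(self.positions) <= 0):
            raise ValueError("positions must be strictly increasing")
        if self.haplotypes.shape[0] % 2:
            raise ValueError("odd haplotype count; phased diploids expected")

    @property
    def n_hap(self) -> int:
        return self.haplotypes.shape[0]

    @property
    def n_sites(self) -> int:
        return self.haplotypes.shape[1]

    def derived_freq(self) -> np.ndarray:
        return self.haplotypes.mean(axis=0)

    def site_index(self, site_id: str) -> int:
        return self.site_ids.index(site_id)


def read_popmap(path: str) -> Dict[str, str]:
    """TSV of sample -> population."""
    popmap: Dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            sample, pop = line.split("\t")[:2]
            popmap[sample] = pop
    return popmap


def read_variants(vcf_path: str, popmap: Dict[str, str],
                  aa_field: str = "AA",
                  require_uppercase_aa: bool = False,
                  ) -> Tuple[List[SnpRecord], Dict[str, HaplotypeMatrix]]:
    """Read phased biallelic SNPs, polarize by the ancestral allele and build
    per-population haplotype matrices.

    SNPs whose ancestral allele is missing or matches neither REF nor ALT are
    removed; multiallelic and non-SNP records are removed.  Unnamed variants
    get the id ``rs_<pos>`` (1-based position, matching the VCF column).
    Lowercase ancestral calls (the low-confidence convention) are accepted
    unless ``require_uppercase_aa`` is set.

    Returns the SNP records (polarized: ``pop_freq`` is the derived-allele
    fraction) and one :class:`HaplotypeMatrix` per population.
    """
    vcf = VCF(vcf_path)
    samples = list(vcf.samples)
    missing = [s for s in samples if s not in popmap]
    if missing:
        raise ValueError(f"samples missing from popmap: {missing}")

    pops = sorted(set(popmap[s] for s in samples))
    # haplotype column indices (2 per sample) per population
    hap_cols: Dict[str, List[int]] = {p: [] for p in pops}
    for i, s in enumerate(samples):
        hap_cols[popmap[s]].extend((2 * i, 2 * i + 1))

    snps: List[SnpRecord] = []
    pop_rows: Dict[str, List[np.ndarray]] = {p: [] for p in pops}
    positions: List[int] = []
    site_ids: List[str] = []

    for var in vcf:
        if len(var.ALT) != 1:
            continue  # biallelic SNPs only
        ref, alt = var.REF.upper(), var.ALT[0].upper()
        if ref not in VALID_BASES or alt not in VALID_BASES:
            continue
        aa_raw = var.INFO.get(aa_field)
        if aa_raw is None:
            continue
        aa = str(aa_raw).split("|")[0].strip()
        if require_uppercase_aa and aa != aa.upper():
            continue
        aa = aa.upper()
        if aa not in (ref, alt):
            continue

        gts = np.array(var.genotypes)  # (n_samples, 3): allele, allele, phased
        alleles = gts[:, :2]
        if np.any(alleles < 0):
            raise ValueError(f"missing genotype at {var.CHROM}:{var.POS}; "
                             "haplotype statistics require complete phased data")
        if not np.all(gts[:, 2] == 1):
            raise ValueError(f"unphased genotype at {var.CHROM}:{var.POS}")
        hap = alleles.reshape(-1).astype(np.int8)  # 1 = ALT
        if aa == alt:
            hap = (1 - hap).astype(np.int8)  # re-polarize: 1 = derived = REF
            ancestral, derived = alt, ref
        else:
            ancestral, derived = ref, alt

        daf = float(hap.mean())
        maf = min(daf, 1.0 - daf)
        pop_freq = {p: float(hap[hap_cols[p]].mean()) for p in pops}
        pop_n = {p: len(hap_cols[p]) for p in pops}
        vid = var.ID if var.ID else f"rs_{var.POS}"
        snps.append(SnpRecord(id=vid, chrom=var.CHROM, pos=var.POS - 1,
                              ref=ref, alt=alt, ancestral=ancestral,
                              derived=derived, global_maf=maf, global_daf=daf,
                              pop_freq=pop_freq, pop_n=pop_n))
        positions.append(var.POS - 1)
        site_ids.append(vid)
        for p in pops:
            pop_rows[p].append(hap[hap_cols[p]])

    matrices: Dict[str, HaplotypeMatrix] = {}
    for p in pops:
        if positions:
            mat = np.column_stack(pop_rows[p])
        else:
            mat = np.zeros((len(hap_cols[p]), 0), dtype=np.int8)
        matrices[p] = HaplotypeMatrix(population=p, haplotypes=mat,
                                      positions=np.array(positions),
                                      site_ids=list(site_ids))
    return snps, matrices


def polarize(hap: np.ndarray, swap: bool) -> np.ndarray:
    """Flip 0/1 coding when ``swap`` (an involution: applying twice is a
    no-op)."""
    hap = np.asarray(hap)
    return (1 - hap).astype(hap.dtype) if swap else hap


def filter_by_frequency(snps: Sequence[SnpRecord],
                        min_global_maf: float = 0.005,
                        min_pop_maf: float = 0.01) -> List[SnpRecord]:
    """Set per-analysis inclusion flags from the minor-allele-frequency rules.

    A SNP enters global analyses iff its global MAF >= ``min_global_maf``;
    it enters a population-level analysis iff that population's MAF >=
    ``min_pop_maf`` (and it passed the global gate).  Flags are set in place
    and the SNPs passing the global gate are returned.
    """
    kept = []
    for s in snps:
        s.include_global = s.global_maf >= min_global_maf
        for p, f in s.pop_freq.items():
            pop_maf = min(f, 1.0 - f)
            s.include_pop[p] = s.include_global and pop_maf >= min_pop_maf
        if s.include_global:
            kept.append(s)
    return kept


def assign_snps_to_regions(snps: Sequence[SnpRecord],
                           regionsets: Sequence[RegionSet],
                           ovlp: Optional[Dict[str, List[Interval]]] = None
                           ) -> List[SnpRecord]:
    """Annotate each SNP with every (hairpin, region, arm) containing its
    position; SNPs inside hairpin-overlap intervals get ``in_ovlp`` set and
    are excluded from region-specific diversity downstream."""
    trees = region_tree(regionsets, ovlp)
    for s in snps:
        s.region_hits = []
        s.in_ovlp = False
        tree = trees.get(s.chrom)
        if tree is None:
            continue
        for hit in sorted(tree[s.pos], key=lambda h: (h.begin, h.end, h.data)):
            hid, label, arm = hit.data
            if label == "ovlp":
                s.in_ovlp = True
            else:
                s.region_hits.append((hid, label, arm))
    return list(snps)
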