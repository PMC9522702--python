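"""Synthetic inputs with the statistical structure the analysis assumes.

Structured haplotypes follow the Balding-Nichols model: each site draws a
global derived-allele frequency p ~ Uniform(0.05, 0.95) and each population
an own frequency ~ Beta(p(1-F)/F, (1-p)(1-F)/F), so that the expected
Hudson F_st between populations equals the differentiation parameter F.
Hard sweeps are planted by copying one template haplotype's block around a
core site into a chosen fraction of haplotypes, which also receive the
derived core allele - guaranteeing the long shared haplotype that EHH-based
statistics must detect.  Annotation and 3'UTR generators write standard GFF3
/ BED / VCF / FASTA text together with truth tables from which the expected
output of every downstream stage can be computed without re-running the
generator.  All generators are deterministic given their seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .annotation import MirnaHairpin
from .variation import HaplotypeMatrix

BASES = np.array(list("ACGT"))


@dataclass
class SweepConfig:
    core_index: int          # site index of the sweeping core
    carrier_fraction: float  # fraction of haplotypes carrying the sweep
    block_bp: int            # physical length of the copied block

    def __post_init__(self) -> None:
        if not 0.0 < self.carrier_fraction < 1.0:
            raise ValueError("carrier fraction must lie in (0, 1)")


@dataclass
class SimConfig:
    """Study conditions for the synthetic cohort.

    Defaults mirror the analysed design: two populations of 100 phased
    diploids (200 haplotypes) each, 2000 segregating sites spaced ~100 bp
    apart, and a Balding-Nichols differentiation of F = 0.1 (the magnitude
    of continental human pairs).
    """

    seed: int = 0
    n_pops: int = 2
    n_hap: int = 200
    n_sites: int = 2000
    spacing_bp: int = 100
    F: float = 0.1
    sweep: Optional[SweepConfig] = None
    utr_n_background: int = 50
    utr_length: int = 300
    mutation_density: float = 0.02  # SNPs per bp for annotation windows

    def __post_init__(self) -> None:
        if not 0.0 < self.F < 1.0:
            raise ValueError("F must lie in (0, 1)")
        for name in ("n_pops", "n_hap", "n_sites", "spacing_bp"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class HaplotypeTruth:
    """Generator-side truth: global and per-population allele frequencies."""

    global_freq: np.ndarray
    pop_freq: Dict[str, np.ndarray]
    positions: np.ndarray
    F: float


def simulate_structured_haplotypes(cfg: SimConfig
                                   ) -> Tuple[Dict[str, HaplotypeMatrix], HaplotypeTruth]:
    """Balding-Nichols haplotypes for ``cfg.n_pops`` populations.

    Alleles are i.i.d. Bernoulli given the population frequency; positions
    increase by ``spacing_bp``.  Returns the matrices and the truth record.
    """
    rng = np.random.default_rng(cfg.seed)
    p = rng.uniform(0.05, 0.95, cfg.n_sites)
    a = p * (1 - cfg.F) / cfg.F
    b = (1 - p) * (1 - cfg.F) / cfg.F
    positions = np.arange(1, cfg.n_sites + 1) * cfg.spacing_bp
    site_ids = [f"rs_{pos}" for pos in positions]

    pops = [f"POP{i + 1}" for i in range(cfg.n_pops)]
    matrices: Dict[str, HaplotypeMatrix] = {}
    pop_freq: Dict[str, np.ndarray] = {}
    for pop in pops:
        f = rng.beta(a, b)
        hap = (rng.random((cfg.n_hap, cfg.n_sites)) < f).astype(np.int8)
        matrices[pop] = HaplotypeMatrix(population=pop, haplotypes=hap,
                                        positions=positions.copy(),
                                        site_ids=list(site_ids))
        pop_freq[pop] = f
    truth = HaplotypeTruth(global_freq=p, pop_freq=pop_freq,
                           positions=positions, F=cfg.F)
    if cfg.sweep is not None:
        first = pops[0]
        matrices[first] = plant_sweep(matrices[first], cfg.sweep.core_index,
                                      cfg.sweep.carrier_fraction,
                                      cfg.sweep.block_bp,
                                      seed=cfg.seed + 1)
    return matrices, truth


def plant_sweep(hapmat: HaplotypeMatrix, core: int, carrier_fraction: float,
                block_bp: int, seed: int = 0) -> HaplotypeMatrix:
    """Plant a hard sweep: copy a template haplotype's block around the core
    into ``carrier_fraction`` of the haplotypes and set their core allele to
    derived.  A block exceeding the matrix span is truncated with a warning.
    """
    import logging
    logger = logging.getLogger(__name__)
    if not 0 <= core < hapmat.n_sites:
        raise ValueError("core outside site range")
    if not 0.0 < carrier_fraction <= 1.0:
        raise ValueError("carrier fraction must lie in (0, 1]")
    rng = np.random.default_rng(seed)
    pos = hapmat.positions
    lo_bp = pos[core] - block_bp // 2
    hi_bp = pos[core] + block_bp // 2
    if lo_bp < pos[0] or hi_bp > pos[-1]:
        logger.warning("sweep block exceeds matrix span; truncated")
    in_block = (pos >= lo_bp) & (pos <= hi_bp)

    hap = hapmat.haplotypes.copy()
    n = hap.shape[0]
    n_carriers = max(2, int(round(carrier_fraction * n)))
    order = rng.permutation(n)
    template = order[0]
    carriers = order[:n_carriers]
    hap[np.ix_(carriers, np.flatnonzero(in_block))] = hap[template, in_block]
    hap[carriers, core] = 1
    return HaplotypeMatrix(population=hapmat.population, haplotypes=hap,
                           positions=hapmat.positions.copy(),
                           site_ids=list(hapmat.site_ids))


# ---------------------------------------------------------------------------
# Annotation fixtures
# ---------------------------------------------------------------------------

@dataclass
class AnnotationTruth:
    hairpins: List[MirnaHairpin]
    regions: Dict[str, List[Tuple[str, int, int, str]]]  # id -> (label, s, e, arm)
    overlap_pairs: List[Tuple[str, str]]
    cluster_members: List[List[str]]


def simulate_annotations(outdir: Optional[str] = None, seed: int = 0
                         ) -> AnnotationTruth:
    """A hairpin set covering every region-partition edge case with its truth
    table: complete (both matures, both strands), single-mature (5p-only and
    3p-only), an overlapping pair, and a clustered triplet at 8-kb gaps.
    When ``outdir`` is given, writes ``mirna.gff3`` plus PC/LNC/TE BED files.
    """
    hairpins = [
        # complete annotation, + strand (spans 80 bp, matures 22 bp)
        MirnaHairpin("syn-mir-1", "chr1", "+", (1000, 1080),
                     mature5p=(1010, 1032), mature3p=(1048, 1070)),
        # complete annotation, - strand (mirror of syn-mir-1)
        MirnaHairpin("syn-mir-2", "chr1", "-", (5000, 5080),
                     mature5p=(5048, 5070), mature3p=(5010, 5032)),
        # 5p-only annotation, + strand
        MirnaHairpin("syn-mir-3", "chr1", "+", (30000, 30080),
                     mature5p=(30010, 30032)),
        # 3p-only annotation, - strand
        MirnaHairpin("syn-mir-4", "chr1", "-", (60000, 60080),
                     mature3p=(60010, 60032)),
        # overlapping pair
        MirnaHairpin("syn-mir-5", "chr2", "+", (2000, 2100),
                     mature5p=(2010, 2032)),
        MirnaHairpin("syn-mir-6", "chr2", "+", (2050, 2150),
                     mature5p=(2060, 2082)),
        # clustered triplet at 8-kb inter-span gaps, same strand
        MirnaHairpin("syn-mir-7", "chr3", "+", (10000, 10080),
                     mature5p=(10010, 10032)),
        MirnaHairpin("syn-mir-8", "chr3", "+", (18080, 18160),
                     mature5p=(18090, 18112)),
        MirnaHairpin("syn-mir-9", "chr3", "+", (26160, 26240),
                     mature5p=(26170, 26192)),
    ]

    regions = {
        "syn-mir-1": [
            ("pre", 1000, 1010, "na"), ("mat", 1010, 1011, "5p"),
            ("seed", 1011, 1018, "5p"), ("mat", 1018, 1032, "5p"),
            ("loop", 1032, 1048, "na"), ("mat", 1048, 1049, "3p"),
            ("seed", 1049, 1056, "3p"), ("mat", 1056, 1070, "3p"),
            ("pre", 1070, 1080, "na"),
            ("flank5", 920, 1000, "na"), ("flank3", 1080, 1160, "na"),
        ],
        # mirror of syn-mir-1: transcript runs high -> low
        "syn-mir-2": [
            ("pre", 5070, 5080, "na"), ("mat", 5069, 5070, "5p"),
            ("seed", 5062, 5069, "5p"), ("mat", 5048, 5062, "5p"),
            ("loop", 5032, 5048, "na"), ("mat", 5031, 5032, "3p"),
            ("seed", 5024, 5031, "3p"), ("mat", 5010, 5024, "3p"),
            ("pre", 5000, 5010, "na"),
            ("flank5", 5080, 5160, "na"), ("flank3", 4920, 5000, "na"),
        ],
        # single mature: pre runs from the mature end to the opposite flank
        "syn-mir-3": [
            ("pre", 30000, 30010, "na"), ("mat", 30010, 30011, "5p"),
            ("seed", 30011, 30018, "5p"), ("mat", 30018, 30032, "5p"),
            ("pre", 30032, 30080, "na"),
            ("flank5", 29920, 30000, "na"), ("flank3", 30080, 30160, "na"),
        ],
        "syn-mir-4": [
            ("pre", 60032, 60080, "na"), ("mat", 60031, 60032, "3p"),
            ("seed", 60024, 60031, "3p"), ("mat", 60010, 60024, "3p"),
            ("pre", 60000, 60010, "na"),
            ("flank5", 60080, 60160, "na"), ("flank3", 59920, 60000, "na"),
        ],
    }

    truth = AnnotationTruth(
        hairpins=hairpins,
        regions=regions,
        overlap_pairs=[("syn-mir-5", "syn-mir-6")],
        # the overlapping pair is itself a cluster: overlapping spans have
        # inter-span gap 0
        cluster_members=[["syn-mir-5", "syn-mir-6"],
                         ["syn-mir-7", "syn-mir-8", "syn-mir-9"]],
    )
    if outdir is not None:
        _write_annotation_files(outdir, truth)
    return truth


def _write_annotation_files(outdir: str, truth: AnnotationTruth) -> None:
    import os
    os.makedirs(outdir, exist_ok=True)
    with open(os.path.join(outdir, "mirna.gff3"), "w") as fh:
        fh.write("##gff-version 3\n")
        for i, h in enumerate(truth.hairpins):
            hid = f"MI{i:07d}"
            fh.write(f"{h.chrom}\t.\tmiRNA_primary_transcript\t{h.span[0] + 1}\t"
                     f"{h.span[1]}\t.\t{h.strand}\t.\tID={hid};Name={h.id}\n")
            for arm, iv in h.matures.items():
                fh.write(f"{h.chrom}\t.\tmiRNA\t{iv[0] + 1}\t{iv[1]}\t.\t"
                         f"{h.strand}\t.\tID={hid}_{arm};Name={h.id}-{arm};"
                         f"Derives_from={hid}\n")
    # context intervals: the first hairpin in a PC intron, the second in a TE
    with open(os.path.join(outdir, "pc.bed"), "w") as fh:
        fh.write("chr1\t500\t2000\thostgene1\n")
    with open(os.path.join(outdir, "lnc.bed"), "w") as fh:
        fh.write("chr2\t1900\t2200\tlnc1\n")
    with open(os.path.join(outdir, "te.bed"), "w") as fh:
        fh.write("chr1\t4950\t5100\tAlu/SINE\n")


# ---------------------------------------------------------------------------
# Variant fixtures (VCF text)
# ---------------------------------------------------------------------------

def write_vcf(path: str, matrices: Dict[str, HaplotypeMatrix],
              chrom: str = "chr1", ancestral_is_ref: bool = True) -> List[str]:
    """Write per-population haplotype matrices as one phased VCF with an AA
    INFO tag; returns the sample names (``<pop>_<i>``).  All matrices must
    share positions and site ids."""
    pops = sorted(matrices)
    ref_mat = matrices[pops[0]]
    samples: List[str] = []
    for pop in pops:
        n = matrices[pop].n_hap
        if n % 2:
            raise ValueError("haplotype count must be even (phased diploids)")
        samples.extend(f"{pop}_{i}" for i in range(n // 2))

    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##contig=<ID={chrom}>\n")
        fh.write('##INFO=<ID=AA,Number=1,Type=String,Description="Ancestral allele">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(samples) + "\n")
        ref, alt = ("A", "G") if ancestral_is_ref else ("G", "A")
        aa = "A"
        for j, pos in enumerate(ref_mat.positions):
            gts = []
            for pop in pops:
                col = matrices[pop].haplotypes[:, j]
                if not ancestral_is_ref:
                    col = 1 - col  # ALT is ancestral: derived carriers show REF
                for i in range(0, len(col), 2):
                    gts.append(f"{col[i]}|{col[i + 1]}")
            fh.write(f"{chrom}\t{pos + 1}\t{ref_mat.site_ids[j]}\t{ref}\t{alt}"
                     f"\t.\tPASS\tAA={aa}\tGT\t" + "\t".join(gts) + "\n")
    return samples


def write_popmap(path: str, matrices: Dict[str, HaplotypeMatrix]) -> None:
    with open(path, "w") as fh:
        for pop in sorted(matrices):
            for i in range(matrices[pop].n_hap // 2):
                fh.write(f"{pop}_{i}\t{pop}\n")


# ---------------------------------------------------------------------------
# UTR pools with planted target sites
# ---------------------------------------------------------------------------

@dataclass
class UtrTruth:
    n_ancestral_only: int
    n_derived_only: int
    n_shared: int

    @property
    def expected_cosine(self) -> float:
        a = self.n_ancestral_only + self.n_shared
        b = self.n_derived_only + self.n_shared
        if a == 0 or b == 0:
            return 0.0
        return self.n_shared / math.sqrt(a * b)


def _site_8mer(seed: str) -> str:
    """The 8mer site sequence (DNA, 5'->3') matched by a 7-mer seed."""
    from Bio.Seq import Seq
    return str(Seq(seed.upper().replace("U", "T")).reverse_complement()) + "A"


def _contains_core(seq: str, seed: str) -> bool:
    from Bio.Seq import Seq
    core6 = str(Seq(seed.upper().replace("U", "T")[:6]).reverse_complement())
    return core6 in seq


def simulate_utr_pool(seeds: Tuple[str, str], design: Tuple[int, int, int],
                      cfg: Optional[SimConfig] = None, seed: int = 0,
                      fasta_path: Optional[str] = None
                      ) -> Tuple[Dict[str, str], UtrTruth]:
    """Random UTR pool with planted 8mer sites for two seed alleles.

    ``design`` = (ancestral-only, derived-only, shared) gene counts; further
    ``cfg.utr_n_background`` genes carry no site for either allele.
    Backgrounds are rejection-sampled so no accidental 6mer core match for
    either seed exists anywhere, making the truth counts exact.
    """
    cfg = cfg or SimConfig(seed=seed)
    rng = np.random.default_rng(seed)
    seed_a, seed_d = seeds
    if seed_a.upper().replace("U", "T")[:6] == seed_d.upper().replace("U", "T")[:6]:
        # a SNP at seed position 7 leaves the 6mer core shared, so any site
        # for one allele is at least a 6mer for the other: exclusive genes
        # cannot be planted
        raise ValueError("seeds share their 6mer core; allele-exclusive sites "
                         "cannot be planted")
    site_a, site_d = _site_8mer(seed_a), _site_8mer(seed_d)
    n_a, n_d, n_s = design

    def background(length: int) -> str:
        while True:
            s = "".join(rng.choice(BASES, size=length))
            if not (_contains_core(s, seed_a) or _contains_core(s, seed_d)):
                return s

    def gene_with(sites: Sequence[str]) -> str:
        while True:
            total = cfg.utr_length - sum(len(s) for s in sites)
            chunks = []
            per = total // (len(sites) + 1)
            for st in sites:
                chunks.append(background(per))
                chunks.append(st)
            chunks.append(background(total - per * len(sites)))
            seq = "".join(chunks)
            # the junctions may create an accidental core for the other seed;
            # verify the planted design holds exactly, else resample
            ok_a = _contains_core(seq, seed_a) == (site_a in sites)
            ok_d = _contains_core(seq, seed_d) == (site_d in sites)
            if ok_a and ok_d:
                return seq

    pool: Dict[str, str] = {}
    idx = 0
    for _ in range(n_a):
        pool[f"gene{idx:04d}_A"] = gene_with([site_a]); idx += 1
    for _ in range(n_d):
        pool[f"gene{idx:04d}_D"] = gene_with([site_d]); idx += 1
    for _ in range(n_s):
        pool[f"gene{idx:04d}_S"] = gene_with([site_a, site_d]); idx += 1
    for _ in range(cfg.utr_n_background):
        pool[f"gene{idx:04d}_N"] = background(cfg.utr_length); idx += 1

    if fasta_path is not None:
        with open(fasta_path, "w") as fh:
            for gene, seq in pool.items():
                fh.write(f">{gene}\n{seq}\n")
    return pool, UtrTruth(n_ancestral_only=n_a, n_derived_only=n_d, n_shared=n_s)
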