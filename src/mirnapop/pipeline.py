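"""End-to-end orchestration of the analysis stages from one YAML config.

Stages run in order annotation -> variation -> diversity -> differentiation
-> selection -> enrichment -> targeting, each toggleable.  Inputs are either
file paths (GFF3/BED/VCF/TSV/FASTA) or ``synthetic``, in which case the
generators produce a full self-consistent cohort.  The config is validated
before any stage runs, every output TSV carries a provenance header (tool
version, config hash, seed), and the log records the counts surviving each
filter step.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import yaml

from . import __version__
from . import annotation as ann
from . import variation as var
from . import diversity as div
from . import differentiation as diff
from . import selection as sel
from . import enrichment as enr
from . import targeting as tgt
from . import synthetic as syn

logger = logging.getLogger(__name__)

STAGES = ("annotation", "variation", "diversity", "differentiation",
          "selection", "enrichment", "targeting")

DEFAULT_THRESHOLDS = {
    "min_global_maf": 0.005,   # global MAF gate on the dataset
    "min_pop_maf": 0.01,       # per-population MAF gate
    "cluster_gap": 10_000,     # max inter-hairpin gap within a cluster (bp)
    "ehh_cutoff": 0.05,        # EHH truncation level
    "max_gap_bp": 20_000,      # max inter-site gap in the haplotype scan
    "min_scan_maf": 0.05,      # core MAF floor for iHS/nSL
    "n_daf_bins": 50,          # DAF bins for score standardization
    "top_quantile": 0.99,      # top-Fst SNP tier
    "extreme_z": 2.0,          # |z| cut for extreme selection scores
}


def load_config(path: str) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    cfg.setdefault("seed", 0)
    cfg.setdefault("stages", {})
    for s in STAGES:
        cfg["stages"].setdefault(s, True)
    thr = dict(DEFAULT_THRESHOLDS)
    thr.update(cfg.get("thresholds") or {})
    cfg["thresholds"] = thr
    cfg.setdefault("inputs", "synthetic")
    return cfg


def _config_hash(cfg: dict) -> str:
    return hashlib.sha256(json.dumps(cfg, sort_keys=True, default=str)
                          .encode()).hexdigest()[:12]


def validate_config(cfg: dict) -> None:
    """Validate-first: raise before any stage runs if an enabled stage lacks
    its inputs or depends on a disabled stage."""
    stages = cfg["stages"]
    deps = {"variation": ["annotation"], "diversity": ["variation"],
            "differentiation": ["variation"], "selection": ["variation"],
            "enrichment": ["differentiation", "selection"]}
    for stage, needs in deps.items():
        if stages.get(stage):
            for need in needs:
                if not stages.get(need):
                    raise ValueError(f"stage {stage!r} requires disabled stage {need!r}")
    if cfg["inputs"] == "synthetic":
        return
    paths = cfg["inputs"]
    required = {"annotation": ["gff3"], "variation": ["vcf", "popmap"],
                "targeting": ["utr_fasta", "variant_table"]}
    for stage, keys in required.items():
        if stages.get(stage):
            for key in keys:
                p = paths.get(key)
                if not p or not os.path.exists(p):
                    raise ValueError(f"stage {stage!r} needs input {key!r} "
                                     f"({p!r} not found)")


def _write_tsv(df: pd.DataFrame, path: str, cfg: dict) -> None:
    with open(path, "w") as fh:
        fh.write(f"# mirnapop {__version__}; config_hash={_config_hash(cfg)}; "
                 f"seed={cfg['seed']}\n")
        df.to_csv(fh, sep="\t", index=False)


def run_pipeline(config_path: str, outdir: Optional[str] = None) -> str:
    """Run the enabled stages; returns the result directory."""
    cfg = load_config(config_path)
    validate_config(cfg)
    outdir = outdir or cfg.get("outdir", "mirnapop_results")
    seed = int(cfg["seed"])
    thr = cfg["thresholds"]
    stages = cfg["stages"]
    synthetic = cfg["inputs"] == "synthetic"
    os.makedirs(outdir, exist_ok=True)

    hairpins: List[ann.MirnaHairpin] = []
    regionsets: List[ann.RegionSet] = []
    ovlp: Dict[str, list] = {}

    if stages["annotation"]:
        if synthetic:
            truth = syn.simulate_annotations(outdir=os.path.join(outdir, "inputs"),
                                             seed=seed)
            hairpins = truth.hairpins
        else:
            age = (ann.read_age_table(cfg["inputs"]["age_table"])
                   if cfg["inputs"].get("age_table") else None)
            hairpins = ann.read_mirna_annotation(cfg["inputs"]["gff3"], age)
        logger.info("annotation: %d hairpins", len(hairpins))
        regionsets = [ann.partition_regions(h) for h in hairpins if h.matures]
        ovlp = ann.mark_overlaps(hairpins)
        clusters = ann.detect_clusters(hairpins, thr["cluster_gap"])
        logger.info("annotation: %d hairpins with ovlp regions, %d clusters",
                    len(ovlp), len(clusters))
        rows = [{"hairpin": rs.hairpin_id, "chrom": rs.chrom, "strand": rs.strand,
                 "region": r.label, "start": r.interval[0], "end": r.interval[1],
                 "arm": r.arm}
                for rs in regionsets for r in rs.regions]
        _write_tsv(pd.DataFrame(rows), os.path.join(outdir, "regions.tsv"), cfg)
        _write_tsv(pd.DataFrame([{"cluster": c.cluster_id, "chrom": c.chrom,
                                  "strand": c.strand,
                                  "members": ",".join(c.member_ids)}
                                 for c in clusters]),
                   os.path.join(outdir, "clusters.tsv"), cfg)

    snps: List[var.SnpRecord] = []
    matrices: Dict[str, var.HaplotypeMatrix] = {}
    if stages["variation"]:
        if synthetic:
            sim = syn.SimConfig(seed=seed, **(cfg.get("synthetic") or {}))
            matrices, _truth = syn.simulate_structured_haplotypes(sim)
            vcf_path = os.path.join(outdir, "inputs", "variants.vcf")
            pop_path = os.path.join(outdir, "inputs", "popmap.tsv")
            os.makedirs(os.path.dirname(vcf_path), exist_ok=True)
            syn.write_vcf(vcf_path, matrices)
            syn.write_popmap(pop_path, matrices)
        else:
            vcf_path = cfg["inputs"]["vcf"]
            pop_path = cfg["inputs"]["popmap"]
        popmap = var.read_popmap(pop_path)
        snps, matrices = var.read_variants(vcf_path, popmap)
        logger.info("variation: %d polarized biallelic SNPs", len(snps))
        snps = var.filter_by_frequency(snps, thr["min_global_maf"],
                                       thr["min_pop_maf"])
        logger.info("variation: %d SNPs pass the global MAF gate", len(snps))
        var.assign_snps_to_regions(snps, regionsets, ovlp)
        n_hit = sum(1 for s in snps if s.region_hits)
        logger.info("variation: %d SNPs fall in miRNA regions", n_hit)
        _write_tsv(pd.DataFrame([{
            "snp": s.id, "chrom": s.chrom, "pos": s.pos, "ancestral": s.ancestral,
            "derived": s.derived, "global_maf": s.global_maf,
            "global_daf": s.global_daf, "in_ovlp": s.in_ovlp,
            "regions": ";".join(f"{h}:{r}:{a}" for h, r, a in s.region_hits)}
            for s in snps]), os.path.join(outdir, "snps.tsv"), cfg)

    if stages["diversity"] and snps:
        rows = []
        for rs in regionsets:
            for label in ("seed", "mat", "loop", "pre", "flank5", "flank3"):
                ivs = rs.intervals(label)
                L = sum(e - s for s, e in ivs)
                if L == 0:
                    continue
                in_region = [s for s in snps
                             if any(h == rs.hairpin_id and r == label
                                    for h, r, _ in s.region_hits)]
                res = div.region_pi(in_region, L,
                                    unit_id=f"{rs.hairpin_id}:{label}")
                rows.append({"unit": res.unit_id, "scope": res.scope, "L": res.L,
                             "n_snps": res.n_snps, "Pi": res.Pi})
        _write_tsv(pd.DataFrame(rows), os.path.join(outdir, "diversity.tsv"), cfg)
        logger.info("diversity: %d (hairpin, region) units", len(rows))

    fst_records: List[diff.FstRecord] = []
    if stages["differentiation"] and snps:
        fst_records = diff.pairwise_fst(snps)
        fst_records = diff.normalize_fst(fst_records)
        n_def = sum(r.defined for r in fst_records)
        logger.info("differentiation: %d records (%d defined)",
                    len(fst_records), n_def)
        _write_tsv(pd.DataFrame([{
            "snp": r.snp_id, "pop_a": r.pop_a, "pop_b": r.pop_b, "p1": r.p1,
            "p2": r.p2, "n1": r.n1, "n2": r.n2, "fst_raw": r.fst_raw,
            "fst_norm": r.fst_norm} for r in fst_records]),
            os.path.join(outdir, "fst.tsv"), cfg)

    scores: List[sel.SelectionScore] = []
    if stages["selection"] and matrices:
        for pop, mat in sorted(matrices.items()):
            for stat in ("iHS", "nSL"):
                sc = sel.scan(mat, stat, thr["min_scan_maf"],
                              thr["ehh_cutoff"], thr["max_gap_bp"])
                sc = sel.standardize(sc, thr["n_daf_bins"])
                sel.flag_extremes(sc, thr["extreme_z"])
                scores.extend(sc)
        logger.info("selection: %d standardized scores, %d extreme",
                    len(scores), sum(s.extreme for s in scores))
        _write_tsv(pd.DataFrame([{
            "snp": s.snp_id, "pop": s.population, "stat": s.statistic,
            "unstandardized": s.unstandardized, "daf": s.daf, "bin": s.daf_bin,
            "standardized": s.standardized, "extreme": s.extreme,
            "flags": ";".join(s.flags)} for s in scores]),
            os.path.join(outdir, "selection.tsv"), cfg)

    if stages["enrichment"] and fst_records and scores:
        top = diff.top_snps(fst_records, thr["top_quantile"])
        background = sorted({r.snp_id for r in fst_records if r.defined})
        rows = []
        for stat in ("iHS", "nSL"):
            extreme = {s.snp_id for s in scores
                       if s.statistic == stat and s.extreme}
            try:
                res = enr.enrichment_test(top, background, extreme)
                rows.append({"annotation": f"extreme_{stat}",
                             "chi_square": res.chi_square, "p": res.p,
                             "focal_fraction": res.focal_fraction,
                             "background_fraction": res.background_fraction})
            except ValueError as exc:
                logger.warning("enrichment for %s skipped: %s", stat, exc)
        _write_tsv(pd.DataFrame(rows), os.path.join(outdir, "enrichment.tsv"), cfg)

    if stages["targeting"]:
        if synthetic:
            rng = np.random.default_rng(seed)
            mature = "UAGCUUAUCAGACUGAUGUUGA"
            sv = tgt.extract_allele_seeds(mature, 3, "G", "C",
                                          mature_id="syn-mir-1-5p",
                                          snp_id="rs_syn1")
            pool, _pool_truth = syn.simulate_utr_pool(
                (sv.seed_ancestral, sv.seed_derived), (30, 30, 40),
                seed=seed)
            variants = [sv]
        else:
            pool = _read_utr_fasta(cfg["inputs"]["utr_fasta"])
            variants = _read_variant_table(cfg["inputs"]["variant_table"])
        rows = []
        for sv in variants:
            anc, der, cos = tgt.allele_target_shift(sv, pool)
            rows.append({"mature": sv.mature_id, "snp": sv.snp_id,
                         "seed_AA": sv.seed_ancestral, "seed_DA": sv.seed_derived,
                         "targets_AA": len(anc), "targets_DA": len(der),
                         "overlap": len(anc.genes & der.genes),
                         "cosine": cos})
        _write_tsv(pd.DataFrame(rows), os.path.join(outdir, "target_shift.tsv"), cfg)
        logger.info("targeting: %d seed-variant miRNAs", len(rows))

    return outdir


def _read_utr_fasta(path: str) -> Dict[str, str]:
    """FASTA of 3'UTRs; header ``gene`` or ``gene|transcript``.  Only the
    longest isoform per gene is kept."""
    from Bio import SeqIO
    per_gene: Dict[str, Dict[str, str]] = {}
    for rec in SeqIO.parse(path, "fasta"):
        parts = rec.id.split("|")
        gene = parts[0]
        tx = parts[1] if len(parts) > 1 else rec.id
        per_gene.setdefault(gene, {})[tx] = str(rec.seq)
    return tgt.longest_isoform(per_gene)


def _read_variant_table(path: str) -> List[tgt.SeedVariantMirna]:
    """TSV: mature_id, mature_seq, snp_id, offset, ancestral, derived."""
    df = pd.read_csv(path, sep="\t", comment="#")
    out = []
    for _, row in df.iterrows():
        out.append(tgt.extract_allele_seeds(
            row["mature_seq"], int(row["offset"]), row["ancestral"],
            row["derived"], mature_id=str(row["mature_id"]),
            snp_id=str(row.get("snp_id", ""))))
    return out
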