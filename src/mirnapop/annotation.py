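"""miRNA hairpin annotation: parsing, functional region partitioning, genomic
context and cluster detection.

A miRNA hairpin (precursor) carries up to two annotated mature sequences (the
5p and 3p arms of the duplex).  The hairpin is partitioned into functional
regions: the *seed* (transcript positions 2-8 of each mature, the primary
determinant of target recognition), the rest of the mature (*mat*), the *loop*
between the two matures, the remaining precursor sequence (*pre*), and two
flanking regions (*flank5*, *flank3*) adjoining the hairpin on each side, each
sized equal to the whole hairpin.  When only one mature is annotated the loop
cannot be delimited, so everything between the end of the given mature and the
opposite flank is labelled *pre* and no loop is emitted.

All coordinates are 0-based half-open internally; 1-based GFF3 input is
converted at the boundary.
"""

from __future__ import annotations

import logging
import os
import tempfile
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Set, Tuple

import gffutils
from intervaltree import IntervalTree

logger = logging.getLogger(__name__)

Interval = Tuple[int, int]  # 0-based half-open [start, end)

REGION_LABELS = ("seed", "mat", "loop", "pre", "flank5", "flank3", "ovlp")


@dataclass
class MirnaHairpin:
    """A precursor miRNA with optional 5p/3p mature arms.

    ``span``, ``mature5p`` and ``mature3p`` are 0-based half-open genomic
    intervals; mature intervals, when present, must lie within the span.
    ``age_group`` is 1 (primate-specific) .. 4 (conserved beyond mammals) or
    ``"unclassified"``.
    """

    id: str
    chrom: str
    strand: str
    span: Interval
    mature5p: Optional[Interval] = None
    mature3p: Optional[Interval] = None
    age_group: object = "unclassified"

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        s, e = self.span
        if e - s < 1:
            raise ValueError(f"{self.id}: span length must be >= 1")
        for name in ("mature5p", "mature3p"):
            iv = getattr(self, name)
            if iv is not None and not (s <= iv[0] < iv[1] <= e):
                raise ValueError(f"{self.id}: {name} {iv} outside span {self.span}")

    @property
    def length(self) -> int:
        return self.span[1] - self.span[0]

    @property
    def matures(self) -> Dict[str, Interval]:
        out = {}
        if self.mature5p is not None:
            out["5p"] = self.mature5p
        if self.mature3p is not None:
            out["3p"] = self.mature3p
        return out


@dataclass
class Region:
    label: str
    interval: Interval
    arm: str = "na"  # {5p, 3p, na}

    def __post_init__(self) -> None:
        if self.label not in REGION_LABELS:
            raise ValueError(f"unknown region label {self.label!r}")


@dataclass
class RegionSet:
    """Functional region partition of one hairpin.

    Non-flank regions tile the hairpin span exactly; the two flanks abut the
    span on each side, each with length equal to the span.
    """

    hairpin_id: str
    chrom: str
    strand: str
    regions: List[Region]

    def by_label(self, label: str) -> List[Region]:
        return [r for r in self.regions if r.label == label]

    def intervals(self, label: str) -> List[Interval]:
        return [r.interval for r in self.by_label(label)]


@dataclass
class GenomicContext:
    """Hosting context of a hairpin: protein-coding gene (PC), long non-coding
    RNA (LNC), transposable element (TE) overlap flags, or intergenic (Intg)
    when neither gene class overlaps."""

    hairpin_id: str
    flags: Set[str]
    te_families: List[str] = field(default_factory=list)
    location: str = "na"  # {intronic, exonic, mixed, na}

    def __post_init__(self) -> None:
        if not self.flags:
            raise ValueError("flags must be non-empty")
        if ("Intg" in self.flags) != ("PC" not in self.flags and "LNC" not in self.flags):
            raise ValueError("Intg flag must be set iff neither PC nor LNC is set")


@dataclass
class MirnaCluster:
    """Two or more same-strand, same-chromosome hairpins chained by inter-span
    gaps of at most the cluster threshold (default 10 kb)."""

    cluster_id: str
    chrom: str
    strand: str
    member_ids: List[str]

    def __post_init__(self) -> None:
        if len(self.member_ids) < 2:
            raise ValueError("a cluster needs at least two members")


# ---------------------------------------------------------------------------
# GFF3 parsing (miRBase dialect)
# ---------------------------------------------------------------------------

def read_mirna_annotation(gff3_path: str,
                          age_table: Optional[Dict[str, object]] = None) -> List[MirnaHairpin]:
    """Read a miRBase-dialect GFF3 into hairpins with attached matures.

    Records of type ``miRNA_primary_transcript`` become hairpins; ``miRNA``
    records are attached to their parent via ``Derives_from`` (or ``Parent``).
    The arm is taken from a ``-5p``/``-3p`` name suffix; otherwise the mature
    nearer the transcript 5' end is called 5p.  Matures whose parent id is
    unknown are skipped with a warning.

    Parameters
    ----------
    gff3_path : str
        Path to the GFF3 file.
    age_table : dict, optional
        Mapping of hairpin id (or Name) to evolutionary age group
        (1-4 or "unclassified").
    """
    if not os.path.exists(gff3_path):
        raise FileNotFoundError(gff3_path)
    try:
        db = gffutils.create_db(gff3_path, ":memory:", force=True,
                                merge_strategy="create_unique",
                                keep_order=True)
    except Exception as exc:  # pragma: no cover - gffutils wraps line info
        raise ValueError(f"malformed GFF3 {gff3_path!r}: {exc}") from exc

    hairpins: Dict[str, MirnaHairpin] = {}
    names: Dict[str, str] = {}
    raw_matures: List[Tuple[str, str, Interval]] = []  # (parent, name, interval)

    for feat in db.all_features():
        attrs = feat.attributes
        fid = (attrs.get("ID") or [feat.id])[0]
        name = (attrs.get("Name") or [fid])[0]
        iv = (feat.start - 1, feat.end)  # GFF3 1-based closed -> 0-based half-open
        if feat.featuretype == "miRNA_primary_transcript":
            hairpins[fid] = MirnaHairpin(id=name, chrom=feat.seqid,
                                         strand=feat.strand, span=iv)
            names[fid] = name
        elif feat.featuretype == "miRNA":
            parent = (attrs.get("Derives_from") or attrs.get("Parent") or [None])[0]
            if parent is None:
                logger.warning("mature %s has no parent reference; skipped", name)
                continue
            raw_matures.append((parent, name, iv))

    pending: Dict[str, List[Tuple[str, Interval]]] = {}
    for parent, name, iv in raw_matures:
        if parent not in hairpins:
            logger.warning("mature %s refers to unknown parent %s; skipped", name, parent)
            continue
        pending.setdefault(parent, []).append((name, iv))

    for parent, matures in pending.items():
        h = hairpins[parent]
        unnamed: List[Interval] = []
        for name, iv in matures:
            low = name.lower()
            if low.endswith("-5p"):
                h.mature5p = iv
            elif low.endswith("-3p"):
                h.mature3p = iv
            else:
                unnamed.append(iv)
        # fallback: the mature nearer the transcript 5' end is the 5p arm
        for iv in sorted(unnamed, key=lambda iv: iv[0], reverse=(h.strand == "-")):
            if h.mature5p is None and (h.mature3p is None or
                                       _is_transcript_upstream(iv, h.mature3p, h.strand)):
                h.mature5p = iv
            elif h.mature3p is None:
                h.mature3p = iv
            else:
                logger.warning("hairpin %s has more than two matures; extra ignored", h.id)

    out = list(hairpins.values())
    if age_table:
        for h in out:
            if h.id in age_table:
                h.age_group = age_table[h.id]
    return out


def _is_transcript_upstream(a: Interval, b: Interval, strand: str) -> bool:
    """True when interval ``a`` is nearer the transcript 5' end than ``b``."""
    return a[0] < b[0] if strand == "+" else a[1] > b[1]


# ---------------------------------------------------------------------------
# Region partition
# ---------------------------------------------------------------------------

def _seed_interval(mature: Interval, strand: str) -> Interval:
    """Transcript positions 2-8 (1-based, 7 nt) of a mature, as genomic
    coordinates.  On the minus strand transcript order runs from the high
    genomic coordinate downward."""
    s, e = mature
    if e - s < 8:
        raise ValueError(f"mature {mature} shorter than 8 nt; seed undefined")
    if strand == "+":
        return (s + 1, s + 8)
    return (e - 8, e - 1)


def partition_regions(h: MirnaHairpin) -> RegionSet:
    """Partition a hairpin into seed/mat/loop/pre plus flank5/flank3.

    Seed is transcript positions 2-8 of each annotated mature (position 1
    stays in mat).  The loop is emitted only when both matures are annotated;
    with a single mature the opposite-arm precursor runs from the end of that
    mature to the start of the opposite flank.  Flanks have span length and
    abut the span; flank5 is on the transcript 5' side.
    """
    matures = h.matures
    if not matures:
        raise ValueError(f"{h.id}: no mature annotated; cannot partition")
    s, e = h.span
    L = e - s
    regions: List[Region] = []

    for arm, miv in matures.items():
        if not (s <= miv[0] < miv[1] <= e):
            raise ValueError(f"{h.id}: mature {miv} outside span {h.span}")
        seed = _seed_interval(miv, h.strand)
        regions.append(Region("seed", seed, arm))
        for piece in _subtract(miv, [seed]):
            regions.append(Region("mat", piece, arm))

    if len(matures) == 2:
        m5, m3 = h.mature5p, h.mature3p
        lo_m, hi_m = (m5, m3) if m5[0] <= m3[0] else (m3, m5)
        if lo_m[1] > hi_m[0]:
            raise ValueError(f"{h.id}: mature arms overlap")
        if lo_m[1] < hi_m[0]:
            regions.append(Region("loop", (lo_m[1], hi_m[0]), "na"))
        for piece in _subtract(h.span, [lo_m, hi_m, (lo_m[1], hi_m[0])]):
            regions.append(Region("pre", piece, "na"))
    else:
        (arm, miv), = matures.items()
        for piece in _subtract(h.span, [miv]):
            regions.append(Region("pre", piece, "na"))

    left = (s - L, s)
    right = (e, e + L)
    if h.strand == "+":
        regions.append(Region("flank5", left, "na"))
        regions.append(Region("flank3", right, "na"))
    else:
        regions.append(Region("flank5", right, "na"))
        regions.append(Region("flank3", left, "na"))

    regions.sort(key=lambda r: r.interval)
    return RegionSet(hairpin_id=h.id, chrom=h.chrom, strand=h.strand, regions=regions)


def _subtract(iv: Interval, holes: Sequence[Interval]) -> List[Interval]:
    """Pieces of ``iv`` not covered by ``holes`` (holes may touch, not overlap)."""
    pieces = []
    cur = iv[0]
    for hs, he in sorted(h for h in holes if h[1] > h[0]):
        if hs > cur:
            pieces.append((cur, hs))
        cur = max(cur, he)
    if cur < iv[1]:
        pieces.append((cur, iv[1]))
    return pieces


# ---------------------------------------------------------------------------
# Overlaps, context, clusters
# ---------------------------------------------------------------------------

def mark_overlaps(hairpins: Sequence[MirnaHairpin]) -> Dict[str, List[Interval]]:
    """Intervals shared by two or more hairpin spans, per hairpin.

    Overlapping ("ovlp") intervals are excluded from region-specific diversity
    downstream; this is an analysis-level flag, the hairpins are kept.
    """
    by_chrom: Dict[str, List[MirnaHairpin]] = {}
    for h in hairpins:
        by_chrom.setdefault(h.chrom, []).append(h)
    out: Dict[str, List[Interval]] = {}
    for chrom_hps in by_chrom.values():
        for i, a in enumerate(chrom_hps):
            pieces: List[Interval] = []
            for j, b in enumerate(chrom_hps):
                if i == j:
                    continue
                lo = max(a.span[0], b.span[0])
                hi = min(a.span[1], b.span[1])
                if lo < hi:
                    pieces.append((lo, hi))
            merged = merge_intervals(pieces)
            if merged:
                out[a.id] = merged
    return out


def merge_intervals(ivs: Iterable[Interval]) -> List[Interval]:
    merged: List[List[int]] = []
    for s, e in sorted(ivs):
        if merged and s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return [(s, e) for s, e in merged]


def assign_context(h: MirnaHairpin,
                   pc: Sequence[Interval] = (),
                   lnc: Sequence[Interval] = (),
                   te: Sequence[Tuple[int, int, str]] = (),
                   exons: Optional[Sequence[Interval]] = None) -> GenomicContext:
    """Genomic context of a hairpin by >= 1 bp overlap with protein-coding
    (PC) gene, lncRNA (LNC) and transposable-element (TE) interval sets.

    ``te`` intervals carry a family label in their third slot.  ``Intg`` is
    set iff neither PC nor LNC overlaps.  When ``exons`` (sub-intervals of the
    host genes) are given, ``location`` distinguishes intronic / exonic /
    mixed placement of the hairpin within its host; otherwise it is "na".
    """
    s, e = h.span
    flags: Set[str] = set()
    if any(max(s, a) < min(e, b) for a, b in pc):
        flags.add("PC")
    if any(max(s, a) < min(e, b) for a, b in lnc):
        flags.add("LNC")
    fams = sorted({fam for a, b, fam in te if max(s, a) < min(e, b)})
    if fams:
        flags.add("TE")
    if "PC" not in flags and "LNC" not in flags:
        flags.add("Intg")

    location = "na"
    if exons is not None and ("PC" in flags or "LNC" in flags):
        exonic_bp = sum(min(e, b) - max(s, a)
                        for a, b in merge_intervals(exons) if max(s, a) < min(e, b))
        if exonic_bp == 0:
            location = "intronic"
        elif exonic_bp >= e - s:
            location = "exonic"
        else:
            location = "mixed"
    return GenomicContext(hairpin_id=h.id, flags=flags, te_families=fams,
                          location=location)


def detect_clusters(hairpins: Sequence[MirnaHairpin],
                    max_gap: int = 10_000) -> List[MirnaCluster]:
    """Single-linkage chaining of hairpins on the same chromosome and strand
    whose inter-span gap is <= ``max_gap`` bp (gap measured between span ends;
    overlapping spans have gap 0).  Singletons are isolated, not clusters."""
    groups: Dict[Tuple[str, str], List[MirnaHairpin]] = {}
    for h in hairpins:
        groups.setdefault((h.chrom, h.strand), []).append(h)
    clusters: List[MirnaCluster] = []
    for (chrom, strand), hps in sorted(groups.items()):
        hps = sorted(hps, key=lambda h: h.span)
        chain: List[MirnaHairpin] = []
        chain_end = None
        for h in hps:
            if chain and h.span[0] - chain_end <= max_gap:
                chain.append(h)
                chain_end = max(chain_end, h.span[1])
            else:
                if len(chain) >= 2:
                    clusters.append(_mk_cluster(chrom, strand, chain, len(clusters)))
                chain = [h]
                chain_end = h.span[1]
        if len(chain) >= 2:
            clusters.append(_mk_cluster(chrom, strand, chain, len(clusters)))
    return clusters


def _mk_cluster(chrom: str, strand: str, members: List[MirnaHairpin],
                idx: int) -> MirnaCluster:
    return MirnaCluster(cluster_id=f"cluster_{chrom}{strand}_{idx}",
                        chrom=chrom, strand=strand,
                        member_ids=[h.id for h in members])


# ---------------------------------------------------------------------------
# Small format helpers used by the pipeline
# ---------------------------------------------------------------------------

def read_bed_intervals(path: str) -> List[Tuple[str, int, int, str]]:
    """BED (>=3 cols) -> list of (chrom, start, end, name)."""
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            name = parts[3] if len(parts) > 3 else "."
            out.append((parts[0], int(parts[1]), int(parts[2]), name))
    return out


def read_age_table(path: str) -> Dict[str, object]:
    """Two-column TSV id -> age group (1-4 or 'unclassified')."""
    table: Dict[str, object] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            mirna, grp = line.split("\t")[:2]
            table[mirna] = int(grp) if grp.isdigit() else grp
    return table


def region_tree(regionsets: Sequence[RegionSet],
                ovlp: Optional[Dict[str, List[Interval]]] = None
                ) -> Dict[str, IntervalTree]:
    """Per-chromosome interval tree of (hairpin, region, arm) annotations,
    with ovlp intervals added as their own label."""
    trees: Dict[str, IntervalTree] = {}
    for rs in regionsets:
        tree = trees.setdefault(rs.chrom, IntervalTree())
        for r in rs.regions:
            tree.addi(r.interval[0], r.interval[1], (rs.hairpin_id, r.label, r.arm))
        if ovlp and rs.hairpin_id in ovlp:
            for s, e in ovlp[rs.hairpin_id]:
                tree.addi(s, e, (rs.hairpin_id, "ovlp", "na"))
    return trees
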