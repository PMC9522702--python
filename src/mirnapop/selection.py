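"""Haplotype-based selection statistics: EHH, iHS and nSL.

Extended haplotype homozygosity (EHH) at an offset from a core site is the
probability that two randomly drawn haplotypes carrying the core allele are
identical over every site from the core out to that offset:

    EHH = sum_g C(|g|, 2) / C(n_core, 2)

over the groups g of carriers sharing the same extension.  The curve starts
at 1 at the core and is non-increasing outward; it is truncated when EHH
drops below a cutoff (default 0.05) or the physical gap to the next site
exceeds 20 kb.  iHH integrates EHH over physical distance (trapezoid rule)
on both flanks; the unstandardized iHS of a core is ln(iHH_ancestral /
iHH_derived).  nSL is the same construction with inter-site distance
measured in segregating sites (1 per step) instead of bp; the 20-kb gap rule
still bounds the scan.  Scores are standardized to mean 0, variance 1 within
derived-allele-frequency bins, separately per population; |z| >= 2 flags an
extreme score.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .variation import HaplotypeMatrix

logger = logging.getLogger(__name__)

MAX_GAP_BP = 20_000
EHH_CUTOFF = 0.05


@dataclass
class EhhCurve:
    """One-allele EHH decay around a core site.

    ``offsets`` are signed distances from the core (bp for iHS, site counts
    for nSL), ``ehh`` the matching homozygosity values; ``ihh`` is the
    trapezoid area under the curve over both flanks.
    """

    core_id: str
    allele: str  # {ancestral, derived}
    offsets: np.ndarray
    ehh: np.ndarray
    ihh: float
    truncated_by_gap: bool = False
    edge_truncated: bool = False


@dataclass
class SelectionScore:
    snp_id: str
    population: str
    statistic: str  # {iHS, nSL}
    unstandardized: Optional[float]
    daf: float
    daf_bin: Optional[int] = None
    standardized: Optional[float] = None
    extreme: bool = False
    flags: List[str] = field(default_factory=list)

    @property
    def defined(self) -> bool:
        return self.unstandardized is not None and math.isfinite(self.unstandardized)


def _ehh_one_flank(hap: np.ndarray, carriers: np.ndarray, core_idx: int,
                   positions: np.ndarray, step: int, coord: str,
                   cutoff: float, max_gap: int
                   ) -> Tuple[List[float], List[float], bool, bool]:
    """EHH values walking outward from the core in one direction.

    Returns (offsets, ehh, truncated_by_gap, edge_truncated); offsets are
    unsigned distances in the requested coordinate (bp or sites).
    """
    n = len(carriers)
    pairs_total = n * (n - 1) // 2
    offsets = [0.0]
    ehh_vals = [1.0]
    group_ids = np.zeros(n, dtype=np.int64)
    truncated_by_gap = False
    idx = core_idx
    n_sites = hap.shape[1]
    dist_sites = 0
    while True:
        nxt = idx + step
        if nxt < 0 or nxt >= n_sites:
            return offsets, ehh_vals, truncated_by_gap, True  # hit matrix edge
        gap = abs(int(positions[nxt]) - int(positions[idx]))
        if gap > max_gap:
            return offsets, ehh_vals, True, False
        idx = nxt
        dist_sites += 1
        # refine the partition of carriers by the allele at the new site;
        # re-encoding via the inverse index also guards against overflow
        _, group_ids, sizes = np.unique(group_ids * 2 + hap[carriers, idx],
                                        return_inverse=True, return_counts=True)
        ehh = float((sizes * (sizes - 1) // 2).sum() / pairs_total)
        offsets.append(float(abs(int(positions[idx]) - int(positions[core_idx])))
                       if coord == "bp" else float(dist_sites))
        ehh_vals.append(ehh)
        if ehh < cutoff:
            return offsets, ehh_vals, truncated_by_gap, False


def ehh(hapmat: HaplotypeMatrix, core: int, allele: str,
        coord: str = "bp", cutoff: float = EHH_CUTOFF,
        max_gap: int = MAX_GAP_BP) -> Optional[EhhCurve]:
    """EHH curve for one core allele; None (undefined) with < 2 carriers.

    ``core`` is a site index; ``allele`` is "ancestral" (0) or "derived" (1).
    The curve covers both flanks, sorted by signed offset, and always
    contains the core itself at offset 0 with EHH 1.
    """
    if allele not in ("ancestral", "derived"):
        raise ValueError(f"allele must be ancestral/derived, got {allele!r}")
    want = 1 if allele == "derived" else 0
    hap = hapmat.haplotypes
    carriers = np.flatnonzero(hap[:, core] == want)
    if len(carriers) < 2:
        return None

    off_r, ehh_r, gap_r, edge_r = _ehh_one_flank(hap, carriers, core,
                                                 hapmat.positions, +1, coord,
                                                 cutoff, max_gap)
    off_l, ehh_l, gap_l, edge_l = _ehh_one_flank(hap, carriers, core,
                                                 hapmat.positions, -1, coord,
                                                 cutoff, max_gap)
    offsets = np.array([-o for o in reversed(off_l)] + off_r[1:])
    values = np.array(list(reversed(ehh_l)) + ehh_r[1:])
    ihh = _ihh(off_l, ehh_l, cutoff) + _ihh(off_r, ehh_r, cutoff)
    return EhhCurve(core_id=hapmat.site_ids[core], allele=allele,
                    offsets=offsets, ehh=values, ihh=ihh,
                    truncated_by_gap=gap_r or gap_l,
                    edge_truncated=edge_r or edge_l)


def _ihh(offsets: Sequence[float], values: Sequence[float],
         cutoff: float) -> float:
    """Trapezoid integral of one flank's EHH decay over its coordinate.
    The contribution of EHH below the cutoff is clipped at the cutoff
    crossing, matching standard scan-software behaviour."""
    area = 0.0
    for i in range(1, len(offsets)):
        x0, x1 = offsets[i - 1], offsets[i]
        y0, y1 = values[i - 1], values[i]
        if y1 < cutoff < y0:
            # linear interpolation to the cutoff crossing
            frac = (y0 - cutoff) / (y0 - y1)
            x1 = x0 + frac * (x1 - x0)
            y1 = cutoff
        area += 0.5 * (y0 + y1) * (x1 - x0)
        if y1 <= cutoff:
            break
    return area


def _log_ihh_ratio(hapmat: HaplotypeMatrix, core: int, coord: str,
                   statistic: str, population: str, cutoff: float,
                   max_gap: int) -> SelectionScore:
    daf = float(hapmat.haplotypes[:, core].mean())
    curve_a = ehh(hapmat, core, "ancestral", coord, cutoff, max_gap)
    curve_d = ehh(hapmat, core, "derived", coord, cutoff, max_gap)
    flags: List[str] = []
    un: Optional[float] = None
    if curve_a is None or curve_d is None:
        flags.append("undefined")
    else:
        if curve_a.truncated_by_gap or curve_d.truncated_by_gap:
            flags.append("gap-truncated")
        if curve_a.edge_truncated or curve_d.edge_truncated:
            flags.append("edge-truncated")
        if curve_a.ihh > 0 and curve_d.ihh > 0:
            un = math.log(curve_a.ihh / curve_d.ihh)
        else:
            flags.append("undefined")
    return SelectionScore(snp_id=hapmat.site_ids[core], population=population,
                          statistic=statistic, unstandardized=un, daf=daf,
                          flags=flags)


def ihs(hapmat: HaplotypeMatrix, core: int, cutoff: float = EHH_CUTOFF,
        max_gap: int = MAX_GAP_BP, min_maf: float = 0.05) -> SelectionScore:
    """Unstandardized iHS = ln(iHH_ancestral / iHH_derived), integrating EHH
    over physical distance.  Cores at MAF <= ``min_maf`` are rejected."""
    daf = float(hapmat.haplotypes[:, core].mean())
    if min(daf, 1 - daf) <= min_maf:
        raise ValueError(f"core MAF {min(daf, 1 - daf):.3f} not above {min_maf}")
    return _log_ihh_ratio(hapmat, core, "bp", "iHS", hapmat.population,
                          cutoff, max_gap)


def nsl(hapmat: HaplotypeMatrix, core: int, cutoff: float = EHH_CUTOFF,
        max_gap: int = MAX_GAP_BP, min_maf: float = 0.05) -> SelectionScore:
    """Unstandardized nSL: as iHS but with distance counted in segregating
    sites, making it invariant to monotone distortions of physical
    positions.  The bp gap rule still truncates the scan."""
    daf = float(hapmat.haplotypes[:, core].mean())
    if min(daf, 1 - daf) <= min_maf:
        raise ValueError(f"core MAF {min(daf, 1 - daf):.3f} not above {min_maf}")
    return _log_ihh_ratio(hapmat, core, "sites", "nSL", hapmat.population,
                          cutoff, max_gap)


def scan(hapmat: HaplotypeMatrix, statistic: str = "iHS",
         min_maf: float = 0.05, cutoff: float = EHH_CUTOFF,
         max_gap: int = MAX_GAP_BP) -> List[SelectionScore]:
    """Per-site scores over all cores passing the MAF filter."""
    fn = ihs if statistic == "iHS" else nsl
    daf = hapmat.derived_freq()
    maf = np.minimum(daf, 1 - daf)
    return [fn(hapmat, i, cutoff, max_gap, min_maf)
            for i in np.flatnonzero(maf > min_maf)]


def _daf_bin(daf: float, edges: np.ndarray, n_bins: int) -> int:
    return min(int(np.searchsorted(edges, daf, side="right")) - 1, n_bins - 1)


def standardize(scores: Sequence[SelectionScore], n_bins: int = 50,
                reference: Optional[Sequence[SelectionScore]] = None
                ) -> List[SelectionScore]:
    """Standardize scores to mean 0, variance 1 within equal-width DAF bins
    on (0, 1), separately per population.

    Bin means and standard deviations are estimated from ``reference``
    (default: the scores themselves, the usual whole-scan convention; an
    explicit reference lets a neutral score set calibrate bins when the
    scored region is known to be enriched in sweeps).  Scores whose bin has
    fewer than two reference values, or zero reference variance, are dropped
    with a warning (their z is undefined).
    """
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    out = [s for s in scores if s.defined]
    ref = [s for s in (reference if reference is not None else out) if s.defined]

    stats: Dict[Tuple[str, int], Tuple[float, float]] = {}
    by_key: Dict[Tuple[str, int], List[float]] = {}
    for s in ref:
        by_key.setdefault((s.population, _daf_bin(s.daf, edges, n_bins)),
                          []).append(s.unstandardized)
    for key, vals in by_key.items():
        arr = np.array(vals)
        if len(arr) < 2 or arr.std(ddof=0) == 0:
            continue
        stats[key] = (float(arr.mean()), float(arr.std(ddof=0)))

    kept: List[SelectionScore] = []
    for s in out:
        b = _daf_bin(s.daf, edges, n_bins)
        s.daf_bin = b
        key = (s.population, b)
        if key not in stats:
            logger.warning("bin %d of population %s lacks reference scores; "
                           "%s dropped", b, s.population, s.snp_id)
            continue
        mu, sd = stats[key]
        s.standardized = float((s.unstandardized - mu) / sd)
        kept.append(s)
    kept.sort(key=lambda s: (s.population, s.snp_id))
    return kept


def flag_extremes(scores: Sequence[SelectionScore], threshold: float = 2.0,
                  two_tailed: bool = True) -> List[bool]:
    """Mark standardized scores with |z| >= threshold (inclusive) as
    extreme; ``two_tailed=False`` restricts to the positive tail."""
    out = []
    for s in scores:
        z = s.standardized
        if z is None:
            s.extreme = False
        elif two_tailed:
            s.extreme = abs(z) >= threshold
        else:
            s.extreme = z >= threshold
        out.append(s.extreme)
    return out
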