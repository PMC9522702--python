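"""Per-SNP population differentiation with the Hudson F_st estimator.

For derived-allele fractions p1, p2 estimated from n1, n2 haplotypes,

    N = (p1 - p2)^2 - p1(1-p1)/(n1-1) - p2(1-p2)/(n2-1)
    D = p1(1-p2) + p2(1-p1)
    Fst = N / D

an estimator that is unbiased with respect to sample size.  N and D are
undefined when both populations are monomorphic for the same allele (D = 0);
such records are flagged and dropped before aggregation.  Per-SNP scores are
normalized by frequency: a linear regression of Fst on global MAF is fitted
and its residuals used as the comparable score.  SNP scores are aggregated to
regions, mature sequences or precursors as the mean over the unit's SNPs, and
candidate units are ranked by their maximum mean Fst over a set of reference
population comparisons.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .variation import SnpRecord

logger = logging.getLogger(__name__)


@dataclass
class FstRecord:
    snp_id: str
    pop_a: str
    pop_b: str
    p1: float
    p2: float
    n1: int
    n2: int
    fst_raw: Optional[float]  # None when D = 0 (undefined)
    fst_norm: Optional[float] = None
    global_maf: Optional[float] = None

    @property
    def defined(self) -> bool:
        return self.fst_raw is not None


def hudson_fst(p1: float, n1: int, p2: float, n2: int) -> Optional[float]:
    """Hudson estimator for one SNP; None when undefined (D = 0).

    Fixed differences give exactly 1.0.  For identical non-trivial
    frequencies the estimate is slightly negative (finite-sample bias) and
    tends to 0 as n grows.
    """
    if n1 <= 1 or n2 <= 1:
        raise ValueError("need n > 1 haplotypes in each population")
    if not (0.0 <= p1 <= 1.0 and 0.0 <= p2 <= 1.0):
        raise ValueError("allele fractions must lie in [0, 1]")
    N = (p1 - p2) ** 2 - p1 * (1 - p1) / (n1 - 1) - p2 * (1 - p2) / (n2 - 1)
    D = p1 * (1 - p2) + p2 * (1 - p1)
    if D == 0.0:
        return None
    return N / D


def hudson_fst_components(p1: np.ndarray, n1: int, p2: np.ndarray, n2: int
                          ) -> Tuple[np.ndarray, np.ndarray]:
    """Vectorized per-site (N, D) components of the Hudson estimator."""
    p1 = np.asarray(p1, dtype=float)
    p2 = np.asarray(p2, dtype=float)
    N = (p1 - p2) ** 2 - p1 * (1 - p1) / (n1 - 1) - p2 * (1 - p2) / (n2 - 1)
    D = p1 * (1 - p2) + p2 * (1 - p1)
    return N, D


def mean_fst(N: np.ndarray, D: np.ndarray,
             method: str = "ratio_of_means") -> float:
    """Combine per-site components into a multi-locus F_st.

    ``ratio_of_means`` (sum N / sum D) is the recommended multi-locus form of
    this estimator and is consistent for the differentiation parameter;
    ``mean_of_ratios`` averages the per-site ratios over sites with D > 0.
    """
    N = np.asarray(N, dtype=float)
    D = np.asarray(D, dtype=float)
    ok = D > 0
    if not ok.any():
        raise ValueError("no sites with defined Fst")
    if method == "ratio_of_means":
        return float(N[ok].sum() / D[ok].sum())
    if method == "mean_of_ratios":
        return float(np.mean(N[ok] / D[ok]))
    raise ValueError(f"unknown method {method!r}")


def pairwise_fst(snps: Sequence[SnpRecord],
                 pairs: Optional[Sequence[Tuple[str, str]]] = None
                 ) -> List[FstRecord]:
    """Per-SNP Hudson F_st for every requested population pair (default: all
    pairs present in the SNPs' frequency maps).  Only SNPs passing the
    per-population MAF rule in *both* populations of a pair are computed."""
    records: List[FstRecord] = []
    if not snps:
        return records
    pops = sorted(snps[0].pop_freq)
    if pairs is None:
        pairs = [(a, b) for i, a in enumerate(pops) for b in pops[i + 1:]]
    for s in snps:
        for a, b in pairs:
            if not (s.include_pop.get(a, True) and s.include_pop.get(b, True)):
                continue
            fst = hudson_fst(s.pop_freq[a], s.pop_n[a], s.pop_freq[b], s.pop_n[b])
            records.append(FstRecord(snp_id=s.id, pop_a=a, pop_b=b,
                                     p1=s.pop_freq[a], p2=s.pop_freq[b],
                                     n1=s.pop_n[a], n2=s.pop_n[b],
                                     fst_raw=fst, global_maf=s.global_maf))
    return records


def normalize_fst(records: Sequence[FstRecord], pooled: bool = False
                  ) -> List[FstRecord]:
    """Frequency normalization: regress fst_raw on global MAF and keep the
    residual as ``fst_norm``.

    The regression is fitted per population pair by default (``pooled=True``
    fits a single regression over all pairs).  With fewer than 3 defined
    records, or a degenerate all-equal MAF design, the records are
    mean-centered instead, with a warning.
    """
    records = list(records)
    groups: Dict[object, List[FstRecord]] = {}
    for r in records:
        if not r.defined:
            continue
        key = None if pooled else (r.pop_a, r.pop_b)
        groups.setdefault(key, []).append(r)

    for key, grp in groups.items():
        y = np.array([r.fst_raw for r in grp])
        x = np.array([r.global_maf for r in grp], dtype=float)
        if len(grp) < 3 or np.allclose(x, x[0]):
            logger.warning("degenerate MAF regression for pair %s; mean-centering", key)
            resid = y - y.mean()
        else:
            slope, intercept = np.polyfit(x, y, 1)
            resid = y - (slope * x + intercept)
        for r, e in zip(grp, resid):
            r.fst_norm = float(e)
    return records


def aggregate_fst(records: Sequence[FstRecord],
                  snp_units: Dict[str, Sequence[str]],
                  reference_pairs: Sequence[Tuple[str, str]] = (),
                  use: str = "raw",
                  method: str = "mean_of_ratios") -> pd.DataFrame:
    """Aggregate per-SNP F_st to units (regions / matures / precursors).

    ``snp_units`` maps snp_id -> unit ids it belongs to.  Per (unit, pair)
    the mean over the unit's defined SNP scores is reported (the
    ``ratio_of_means`` alternative combines the estimator's N and D sums and
    requires ``use='raw'``).  Units with no defined SNPs are omitted.  Per
    unit, the maximum mean over ``reference_pairs`` (default: all pairs seen)
    is reported with percentile rank and top1/top5 tier over that maximum.
    """
    if use not in ("raw", "norm"):
        raise ValueError("use must be 'raw' or 'norm'")
    rows = []
    for r in records:
        if not r.defined:
            continue
        score = r.fst_raw if use == "raw" else r.fst_norm
        if score is None:
            continue
        for unit in snp_units.get(r.snp_id, ()):
            rows.append({"unit": unit, "pair": (r.pop_a, r.pop_b),
                         "score": score, "p1": r.p1, "p2": r.p2,
                         "n1": r.n1, "n2": r.n2})
    if not rows:
        return pd.DataFrame(columns=["unit", "pair", "mean_fst"])
    df = pd.DataFrame(rows)
    if method == "mean_of_ratios":
        per = df.groupby(["unit", "pair"])["score"].mean().rename("mean_fst")
        per = per.reset_index()
    elif method == "ratio_of_means":
        if use != "raw":
            raise ValueError("ratio_of_means aggregation needs raw estimator components")
        def _rom(g: pd.DataFrame) -> float:
            N, D = hudson_fst_components(g["p1"].to_numpy(), int(g["n1"].iloc[0]),
                                         g["p2"].to_numpy(), int(g["n2"].iloc[0]))
            return mean_fst(N, D, "ratio_of_means")
        per = (df.groupby(["unit", "pair"])
                 .apply(_rom, include_groups=False).rename("mean_fst").reset_index())
    else:
        raise ValueError(f"unknown method {method!r}")

    pairs = reference_pairs or sorted(set(per["pair"]))
    ref = per[per["pair"].isin(list(pairs))]
    out = ref.groupby("unit")["mean_fst"].max().rename("max_fst").reset_index()
    out["percentile"] = out["max_fst"].rank(pct=True)
    q99 = out["max_fst"].quantile(0.99)
    q95 = out["max_fst"].quantile(0.95)
    out["tier"] = np.where(out["max_fst"] > q99, "top1",
                           np.where(out["max_fst"] > q95, "top5", "none"))
    return out.merge(per, on="unit")


def top_snps(records: Sequence[FstRecord], quantile: float = 0.99,
             use: str = "norm") -> List[str]:
    """SNPs whose score strictly exceeds the stated quantile of the pooled
    per-record distribution (ties at the quantile are excluded; with
    all-equal scores the result is empty)."""
    vals = []
    for r in records:
        v = r.fst_norm if use == "norm" else r.fst_raw
        if v is not None:
            vals.append((r.snp_id, v))
    if not vals:
        return []
    scores = np.array([v for _, v in vals])
    cut = np.quantile(scores, quantile)
    return sorted({sid for sid, v in vals if v > cut})
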