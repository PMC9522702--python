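"""Nucleotide diversity of miRNA functional regions.

Per-SNP diversity is the expected number of pairwise mismatches between two
haplotypes at that site, pi = 2 p (1-p) n/(n-1) with p the derived-allele
fraction among n haplotypes (the unbiased per-site heterozygosity).  Region
diversity Pi sums pi over the SNPs of a region and divides by the region
length L in bp (Pi = pi/L).  Per-position profiles average pi at homologous
positions across hairpins, either anchored on the mature 5' end or on a fixed
number of relative-length bins.  Category comparisons use Kruskal-Wallis and
pairwise Wilcoxon rank-sum tests with Bonferroni correction, and the joint
contribution of age, clustering and genomic context is estimated by ordinary
least squares.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .annotation import MirnaHairpin, RegionSet
from .variation import SnpRecord


@dataclass
class DiversityResult:
    """Diversity of one unit (hairpin or hairpin region): pi summed over its
    SNPs, the region length L, and Pi = pi_sum / L."""

    unit_id: str
    pi_sum: float
    L: int
    scope: str = "pooled"
    n_snps: int = 0

    def __post_init__(self) -> None:
        if self.L <= 0:
            raise ValueError(f"{self.unit_id}: region length must be positive")
        if self.pi_sum < 0:
            raise ValueError("pi_sum must be non-negative")

    @property
    def Pi(self) -> float:
        return self.pi_sum / self.L


@dataclass
class PositionProfile:
    """Mean per-site pi indexed by an anchoring scheme; positions never
    covered are absent, not zero."""

    anchor: str
    mean_pi: Dict[object, float] = field(default_factory=dict)
    coverage: Dict[object, int] = field(default_factory=dict)


def pi_site(derived_count: int, n_hap: int) -> float:
    """Expected pairwise mismatches at one site: 2 p (1-p) n/(n-1).

    Equals the fraction of the C(n,2) haplotype pairs that differ at the
    site; two haplotypes differing at one site give exactly 1.0.
    """
    if n_hap < 2:
        raise ValueError("need at least two haplotypes")
    if not 0 <= derived_count <= n_hap:
        raise ValueError("derived_count outside [0, n_hap]")
    p = derived_count / n_hap
    return 2.0 * p * (1.0 - p) * n_hap / (n_hap - 1)


def snp_pi(snp: SnpRecord, scope: str = "pooled") -> float:
    """pi of one SNP in the pooled sample or within one population."""
    if scope == "pooled":
        n = sum(snp.pop_n.values())
        d = round(sum(snp.pop_freq[p] * snp.pop_n[p] for p in snp.pop_n))
    else:
        n = snp.pop_n[scope]
        d = round(snp.pop_freq[scope] * n)
    return pi_site(int(d), n)


def region_pi(snps: Sequence[SnpRecord], L: int, unit_id: str = "region",
              scope: str = "pooled") -> DiversityResult:
    """Pi = sum of per-SNP pi over a region / region length.

    SNPs flagged as lying in hairpin-overlap intervals are excluded, as are
    SNPs failing the scope's MAF inclusion rule.
    """
    if L <= 0:
        raise ValueError("region length L must be positive")
    total = 0.0
    used = 0
    for s in snps:
        if s.in_ovlp:
            continue
        if scope == "pooled":
            if not s.include_global:
                continue
        elif not s.include_pop.get(scope, True):
            continue
        total += snp_pi(s, scope)
        used += 1
    return DiversityResult(unit_id=unit_id, pi_sum=total, L=L, scope=scope,
                           n_snps=used)


# ---------------------------------------------------------------------------
# Per-position profile
# ---------------------------------------------------------------------------

def _transcript_offset(pos: int, interval: Tuple[int, int], strand: str) -> int:
    """0-based offset of a genomic position within an interval, counted in
    transcript orientation."""
    s, e = interval
    return pos - s if strand == "+" else e - 1 - pos


def position_profile(hairpins: Sequence[MirnaHairpin],
                     regionsets: Sequence[RegionSet],
                     snps: Sequence[SnpRecord],
                     anchor: str = "mature-anchored",
                     n_bins: int = 100) -> PositionProfile:
    """Mean pi per homologous precursor position.

    ``mature-anchored``: positions are (region, arm, offset) with the offset
    counted from the transcript-5' end of the region; the profile key is that
    triple.  ``relative-length``: each precursor is scaled onto ``n_bins``
    bins; a SNP at transcript offset ``o`` in a hairpin of length ``len``
    falls into bin ``floor(n_bins * o / len)``.  Every scanned position
    contributes to the coverage counts; positions with no coverage are
    absent from the result.
    """
    if anchor not in ("mature-anchored", "relative-length"):
        raise ValueError(f"unknown anchor scheme {anchor!r}")

    hp = {h.id: h for h in hairpins}
    pi_by_key: Dict[object, float] = {}
    cov: Dict[object, int] = {}

    # pi of every (hairpin, genomic pos) with a usable SNP
    snp_at: Dict[Tuple[str, int], float] = {}
    for s in snps:
        if s.in_ovlp or not s.include_global:
            continue
        for hid, _label, _arm in s.region_hits:
            snp_at[(hid, s.pos)] = snp_pi(s, "pooled")

    for rs in regionsets:
        h = hp[rs.hairpin_id]
        span_len = h.length
        for r in rs.regions:
            if r.label in ("flank5", "flank3"):
                continue
            for pos in range(r.interval[0], r.interval[1]):
                if anchor == "mature-anchored":
                    off = _transcript_offset(pos, r.interval, h.strand)
                    key = (r.label, r.arm, off)
                else:
                    off = _transcript_offset(pos, h.span, h.strand)
                    key = int(n_bins * off // span_len)
                cov[key] = cov.get(key, 0) + 1
                pi_by_key[key] = pi_by_key.get(key, 0.0) + snp_at.get((rs.hairpin_id, pos), 0.0)

    mean_pi = {k: pi_by_key[k] / cov[k] for k in cov}
    return PositionProfile(anchor=anchor, mean_pi=mean_pi, coverage=cov)


# ---------------------------------------------------------------------------
# Group comparisons and regression
# ---------------------------------------------------------------------------

def compare_groups(values: Dict[str, Sequence[float]],
                   test: str = "kruskal-wallis") -> pd.DataFrame:
    """Rank tests across >= 2 groups.

    ``kruskal-wallis`` returns one row; ``pairwise-wilcoxon-bonferroni``
    returns one row per group pair with the two-sided Wilcoxon rank-sum
    (Mann-Whitney) p multiplied by the number of comparisons, capped at 1.
    """
    names = list(values)
    if len(names) < 2:
        raise ValueError("need at least two groups")
    for g in names:
        if len(values[g]) < 1:
            raise ValueError(f"group {g!r} is empty")

    if test == "kruskal-wallis":
        arrays = [np.asarray(values[g], dtype=float) for g in names]
        flat = np.concatenate(arrays)
        if np.all(flat == flat[0]):
            stat, p = 0.0, 1.0  # all observations tied
        else:
            stat, p = stats.kruskal(*arrays)
        return pd.DataFrame([{"comparison": " vs ".join(names),
                              "statistic": stat, "p": p}])

    if test == "pairwise-wilcoxon-bonferroni":
        pairs = list(itertools.combinations(names, 2))
        m = len(pairs)
        rows = []
        for a, b in pairs:
            xa = np.asarray(values[a], dtype=float)
            xb = np.asarray(values[b], dtype=float)
            both = np.concatenate([xa, xb])
            if np.all(both == both[0]):
                stat, p = 0.0, 1.0  # all observations tied
            else:
                # R wilcox.test convention: exact null when both groups are
                # small and tie-free, normal approximation otherwise
                no_ties = len(np.unique(both)) == len(both)
                method = ("exact" if no_ties and max(len(xa), len(xb)) < 50
                          else "asymptotic")
                res = stats.mannwhitneyu(xa, xb, alternative="two-sided",
                                         method=method)
                stat, p = float(res.statistic), float(res.pvalue)
            rows.append({"comparison": f"{a} vs {b}", "statistic": stat,
                         "p_raw": p, "p": min(1.0, p * m), "bonferroni_m": m})
        return pd.DataFrame(rows)

    raise ValueError(f"unknown test {test!r}")


def diversity_regression(data: pd.DataFrame, response: str = "Pi",
                         predictors: Optional[Sequence[str]] = None
                         ) -> pd.DataFrame:
    """OLS of region diversity on annotation categories.

    Categorical predictors are one-hot encoded with the first level (sorted)
    as reference.  Returns coefficient, standard error, t and p per term.
    Raises on a collinear design, naming the aliased column.
    """
    if predictors is None:
        predictors = [c for c in data.columns if c != response]
    if not predictors:
        raise ValueError("need at least one predictor")

    X_parts = []
    for col in predictors:
        s = data[col]
        if s.dtype.kind in "OUSb" or isinstance(s.dtype, pd.CategoricalDtype):
            dummies = pd.get_dummies(s.astype(str), prefix=col, drop_first=True,
                                     dtype=float)
            X_parts.append(dummies)
        else:
            X_parts.append(s.astype(float).to_frame(col))
    X = pd.concat(X_parts, axis=1)
    X = sm.add_constant(X, has_constant="add")

    # detect aliased (linearly dependent) columns before fitting
    arr = X.to_numpy(dtype=float)
    if np.linalg.matrix_rank(arr) < arr.shape[1]:
        for j in range(1, arr.shape[1]):
            if np.linalg.matrix_rank(arr[:, :j + 1]) <= np.linalg.matrix_rank(arr[:, :j]):
                raise ValueError(f"collinear design: column {X.columns[j]!r} is aliased")

    fit = sm.OLS(data[response].astype(float), X).fit()
    return pd.DataFrame({"coef": fit.params, "se": fit.bse,
                         "t": fit.tvalues, "p": fit.pvalues})
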