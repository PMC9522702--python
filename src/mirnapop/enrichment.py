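"""Enrichment of highly differentiated SNPs in functional annotation sets.

Tests whether a focal SNP set (e.g. the top-F_st tail) carries an annotation
(extreme iHS/nSL score, eQTL membership, GWAS association) more often than a
background set, via a Pearson chi-square on the 2x2 table.  CADD PHRED
deleteriousness scores are compared across miRNA regions with rank tests,
using >= 10 as the conventional cut marking the 1% most deleterious variants
genome-wide.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Set

import numpy as np
import pandas as pd
from scipy import stats

from .diversity import compare_groups

logger = logging.getLogger(__name__)

CADD_DELETERIOUS = 10.0


@dataclass
class SnpAnnotation:
    snp_id: str
    cadd_phred: Optional[float] = None
    is_eqtl: bool = False
    is_gwas: bool = False
    is_extreme_ihs: bool = False
    is_extreme_nsl: bool = False

    def __post_init__(self) -> None:
        if self.cadd_phred is not None and self.cadd_phred < 0:
            raise ValueError("PHRED-scaled CADD scores are non-negative")


@dataclass
class ContingencyResult:
    """2x2 focal/background x annotated/not table with the Pearson
    chi-square."""

    table: np.ndarray  # rows: focal, background; cols: annotated, not
    chi_square: float
    p: float
    expected: np.ndarray
    focal_fraction: float
    background_fraction: float
    low_expected: bool = False


def enrichment_test(focal: Iterable[str], background: Iterable[str],
                    annotated: Iterable[str],
                    correction: str = "none",
                    exclude_focal_from_background: bool = True
                    ) -> ContingencyResult:
    """Pearson chi-square for over-representation of an annotation in the
    focal set relative to the background.

    By default the background excludes the focal SNPs (overlapping background
    slightly dilutes the contrast; ``exclude_focal_from_background=False``
    reproduces a whole-dataset background literally).  ``correction`` is
    "none" or "yates".  A warning is logged when any expected count is
    below 5; a degenerate margin (all or none annotated, or an empty group)
    raises.
    """
    if correction not in ("none", "yates"):
        raise ValueError(f"unknown correction {correction!r}")
    focal_set = set(focal)
    bg = set(background)
    if exclude_focal_from_background:
        bg -= focal_set
    ann = set(annotated)

    a = len(focal_set & ann)
    b = len(focal_set - ann)
    c = len(bg & ann)
    d = len(bg - ann)
    table = np.array([[a, b], [c, d]])
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        raise ValueError(f"degenerate margin in contingency table {table.tolist()}")

    chi2, p, _dof, expected = stats.chi2_contingency(
        table, correction=(correction == "yates"))
    low = bool((expected < 5).any())
    if low:
        logger.warning("expected count below 5 in %s", table.tolist())
    return ContingencyResult(table=table, chi_square=float(chi2), p=float(p),
                             expected=expected,
                             focal_fraction=a / (a + b),
                             background_fraction=c / (c + d),
                             low_expected=low)


def compare_cadd(scores_by_region: Dict[str, Sequence[float]]) -> Dict[str, object]:
    """Rank-test table plus distribution summaries of CADD PHRED scores per
    miRNA region.

    Returns the pairwise Wilcoxon (Bonferroni) table, per-region quantiles,
    and the per-region fraction of scores at or above the deleteriousness
    convention (PHRED >= 10).
    """
    if len(scores_by_region) < 2:
        raise ValueError("need scores for at least two regions")
    tests = compare_groups(scores_by_region, "pairwise-wilcoxon-bonferroni")
    summaries = {}
    for region, vals in scores_by_region.items():
        arr = np.asarray(vals, dtype=float)
        summaries[region] = {
            "n": int(arr.size),
            "q25": float(np.quantile(arr, 0.25)),
            "median": float(np.quantile(arr, 0.5)),
            "q75": float(np.quantile(arr, 0.75)),
            "mean": float(arr.mean()),
            "frac_deleterious": float((arr >= CADD_DELETERIOUS).mean()),
        }
    return {"tests": tests, "summaries": summaries}


def read_annotation_table(path: str) -> Dict[str, SnpAnnotation]:
    """TSV keyed by snp_id with optional columns cadd_phred, is_eqtl,
    is_gwas (booleans as 0/1 or true/false)."""
    df = pd.read_csv(path, sep="\t", comment="#")
    out: Dict[str, SnpAnnotation] = {}

    def _bool(v: object) -> bool:
        return str(v).strip().lower() in ("1", "true", "yes")

    for _, row in df.iterrows():
        cadd = row.get("cadd_phred")
        out[str(row["snp_id"])] = SnpAnnotation(
            snp_id=str(row["snp_id"]),
            cadd_phred=None if pd.isna(cadd) else float(cadd),
            is_eqtl=_bool(row.get("is_eqtl", False)),
            is_gwas=_bool(row.get("is_gwas", False)),
        )
    return out
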