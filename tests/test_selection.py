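"""EHH curves, iHS/nSL statistics, DAF-bin standardization, extreme flags."""

import itertools
import math

import numpy as np
import pytest

from mirnapop.selection import (SelectionScore, ehh, flag_extremes, ihs, nsl,
                                scan, standardize)
from mirnapop.variation import HaplotypeMatrix
from conftest import random_hapmat


def _mat(rows, positions=None, population="P"):
    rows = np.asarray(rows, dtype=np.int8)
    if positions is None:
        positions = np.arange(rows.shape[1]) * 100 + 100
    return HaplotypeMatrix(population=population, haplotypes=rows,
                           positions=np.asarray(positions),
                           site_ids=[f"s{i}" for i in range(rows.shape[1])])


def ehh_bruteforce(hap, core, allele, target):
    """Fraction of carrier pairs identical at every site between the core
    and the target site (inclusive of the target, exclusive of nothing)."""
    carriers = [i for i in range(hap.shape[0]) if hap[i, core] == allele]
    lo, hi = min(core, target), max(core, target)
    pairs = list(itertools.combinations(carriers, 2))
    if not pairs:
        return None
    same = sum(1 for a, b in pairs
               if np.array_equal(hap[a, lo:hi + 1], hap[b, lo:hi + 1]))
    return same / len(pairs)


class TestEhh:
    def test_offset_zero_is_one(self, rng):
        mat = random_hapmat(rng, 12, 20)
        for allele in ("ancestral", "derived"):
            curve = ehh(mat, 10, allele)
            if curve is not None:
                assert curve.ehh[curve.offsets == 0][0] == 1.0

    def test_identical_carriers_stay_at_one(self):
        rows = np.tile([1, 0, 1, 1, 0], (4, 1))
        curve = ehh(_mat(rows), 2, "derived")
        assert np.all(curve.ehh == 1.0)

    def test_two_two_split_gives_one_third(self):
        # 4 carriers of the derived core (site 1) splitting 2/2 at site 2
        rows = [[0, 1, 0], [0, 1, 0], [0, 1, 1], [0, 1, 1]]
        curve = ehh(_mat(rows), 1, "derived")
        right = curve.ehh[curve.offsets > 0]
        assert right[0] == pytest.approx(1 / 3)

    def test_fewer_than_two_carriers_undefined(self):
        rows = [[0, 1, 0], [0, 0, 0], [0, 0, 1], [0, 0, 1]]
        assert ehh(_mat(rows), 1, "derived") is None

    def test_monotone_nonincreasing_outward(self, rng):
        for _ in range(20):
            mat = random_hapmat(rng, 16, 30)
            curve = ehh(mat, 15, "derived", cutoff=0.0)
            if curve is None:
                continue
            right = curve.ehh[curve.offsets >= 0]
            left = curve.ehh[curve.offsets <= 0][::-1]
            assert np.all(np.diff(right) <= 1e-12)
            assert np.all(np.diff(left) <= 1e-12)

    def test_matches_bruteforce_pairwise_identity(self, rng):
        """Exact agreement with the pairwise-identity definition on random
        20 x 50 matrices (cutoff disabled so every offset is visited)."""
        for _ in range(10):
            mat = random_hapmat(rng, 20, 50)
            core = int(rng.integers(5, 45))
            for allele, want in (("derived", 1), ("ancestral", 0)):
                curve = ehh(mat, core, allele, cutoff=0.0, max_gap=10**9)
                if curve is None:
                    continue
                pos_to_idx = {int(p): j for j, p in enumerate(mat.positions)}
                core_pos = int(mat.positions[core])
                for off, val in zip(curve.offsets, curve.ehh):
                    target = pos_to_idx[core_pos + int(off)]
                    assert val == pytest.approx(
                        ehh_bruteforce(mat.haplotypes, core, want, target)), \
                        (core, allele, off)

    def test_gap_truncation_flag(self):
        rows = np.ones((4, 3), dtype=np.int8)
        curve = ehh(_mat(rows, positions=[100, 200, 30_000]), 1, "derived")
        assert curve.truncated_by_gap

    def test_edge_truncation_flag(self):
        rows = np.ones((4, 3), dtype=np.int8)
        curve = ehh(_mat(rows), 1, "derived")
        assert curve.edge_truncated  # identical haplotypes reach the edge


def _symmetric_matrix(n_side=8, n_sites=41):
    """Core at the center; ancestral and derived carrier sets have identical
    haplotype structure, so iHH_A = iHH_D exactly."""
    rng = np.random.default_rng(5)
    flank = rng.integers(0, 2, size=(n_side, n_sites)).astype(np.int8)
    core = n_sites // 2
    anc = flank.copy()
    der = flank.copy()
    anc[:, core] = 0
    der[:, core] = 1
    return _mat(np.vstack([anc, der])), core


class TestIhs:
    def test_symmetric_structure_gives_zero(self):
        mat, core = _symmetric_matrix()
        assert ihs(mat, core).unstandardized == pytest.approx(0.0, abs=1e-12)

    def test_low_maf_core_rejected(self):
        rows = np.zeros((20, 5), dtype=np.int8)
        rows[0, 2] = 1
        with pytest.raises(ValueError, match="MAF"):
            ihs(_mat(rows), 2)

    def test_scale_invariance_of_distance(self):
        mat, core = _symmetric_matrix()
        doubled = HaplotypeMatrix(population="P", haplotypes=mat.haplotypes,
                                  positions=mat.positions * 2,
                                  site_ids=list(mat.site_ids))
        a = ihs(mat, core, max_gap=10**9).unstandardized
        b = ihs(doubled, core, max_gap=10**9).unstandardized
        assert a == pytest.approx(b, abs=1e-12)

    def test_planted_sweep_drives_ihs_negative(self, rng):
        """Long identical haplotypes around the derived core force
        iHH_D >> iHH_A, i.e. a strongly negative log-ratio."""
        mat = random_hapmat(rng, 40, 101, spacing=50)
        hap = mat.haplotypes.copy()
        core = 50
        carriers = rng.choice(40, size=28, replace=False)
        hap[carriers, :] = hap[carriers[0], :]
        hap[carriers, core] = 1
        hap[[i for i in range(40) if i not in carriers], core] = 0
        swept = HaplotypeMatrix("P", hap, mat.positions, list(mat.site_ids))
        assert ihs(swept, core).unstandardized < -1.0


class TestNsl:
    def test_symmetric_structure_gives_zero(self):
        mat, core = _symmetric_matrix()
        assert nsl(mat, core).unstandardized == pytest.approx(0.0, abs=1e-12)

    def test_invariant_to_monotone_position_distortion(self, rng):
        mat = random_hapmat(rng, 16, 41)
        core = 20
        warped_pos = np.cumsum(rng.integers(1, 7, size=41))
        warped = HaplotypeMatrix("P", mat.haplotypes, warped_pos,
                                 list(mat.site_ids))
        a = nsl(mat, core, max_gap=10**9)
        b = nsl(warped, core, max_gap=10**9)
        if a.defined and b.defined:
            assert a.unstandardized == pytest.approx(b.unstandardized, abs=1e-12)

    def test_sign_agrees_with_ihs_on_sweeps(self, rng):
        agree = total = 0
        for _ in range(20):
            mat = random_hapmat(rng, 30, 81, spacing=50)
            hap = mat.haplotypes.copy()
            core = 40
            carriers = rng.choice(30, size=21, replace=False)
            hap[carriers, :] = hap[carriers[0], :]
            hap[carriers, core] = 1
            hap[[i for i in range(30) if i not in carriers], core] = 0
            swept = HaplotypeMatrix("P", hap, mat.positions, list(mat.site_ids))
            a, b = ihs(swept, core), nsl(swept, core)
            if a.defined and b.defined:
                total += 1
                agree += (a.unstandardized < 0) == (b.unstandardized < 0)
        assert total > 0 and agree / total >= 0.95


def _scores(rng, n=300, pop="P"):
    return [SelectionScore(snp_id=f"rs{i}", population=pop, statistic="iHS",
                           unstandardized=float(rng.normal()), daf=float(d))
            for i, d in enumerate(rng.uniform(0.01, 0.99, n))]


class TestStandardize:
    def test_bins_have_mean_zero_variance_one(self, rng):
        out = standardize(_scores(rng), n_bins=10)
        by_bin = {}
        for s in out:
            by_bin.setdefault(s.daf_bin, []).append(s.standardized)
        for vals in by_bin.values():
            assert np.mean(vals) == pytest.approx(0.0, abs=1e-12)
            assert np.std(vals) == pytest.approx(1.0, abs=1e-12)

    def test_single_bin_equals_global_zscore(self, rng):
        scores = _scores(rng, 100)
        vals = np.array([s.unstandardized for s in scores])
        want = (vals - vals.mean()) / vals.std()
        out = standardize(scores, n_bins=1)
        got = {s.snp_id: s.standardized for s in out}
        for i, s in enumerate(scores):
            assert got[s.snp_id] == pytest.approx(want[i])

    def test_recovers_planted_bin_offsets(self, rng):
        scores = []
        for i, d in enumerate(rng.uniform(0.01, 0.99, 400)):
            offset = 5.0 if d < 0.5 else -3.0  # bin-dependent location shift
            scores.append(SelectionScore(f"rs{i}", "P", "iHS",
                                         float(rng.normal(offset, 1)), float(d)))
        out = standardize(scores, n_bins=2)
        # the shifts are absorbed by the per-bin means: z looks standard in both
        lo = [s.standardized for s in out if s.daf < 0.5]
        hi = [s.standardized for s in out if s.daf >= 0.5]
        assert abs(np.mean(lo)) < 1e-12 and abs(np.mean(hi)) < 1e-12

    def test_populations_standardized_separately(self, rng):
        a = _scores(rng, 100, "A")
        for s in a:
            s.unstandardized += 10.0  # population-level shift must not leak
        b = _scores(rng, 100, "B")
        out = standardize(a + b, n_bins=1)
        for pop in ("A", "B"):
            vals = [s.standardized for s in out if s.population == pop]
            assert np.mean(vals) == pytest.approx(0.0, abs=1e-12)

    def test_singleton_bin_dropped_with_warning(self, rng, caplog):
        import logging
        scores = [SelectionScore("a", "P", "iHS", 1.0, 0.01),
                  SelectionScore("b", "P", "iHS", 2.0, 0.99),
                  SelectionScore("c", "P", "iHS", 0.5, 0.98)]
        with caplog.at_level(logging.WARNING):
            out = standardize(scores, n_bins=2)
        assert {s.snp_id for s in out} == {"b", "c"}


class TestFlagExtremes:
    @pytest.mark.parametrize("z,want", [(2.0, True), (-2.5, True),
                                        (1.99, False), (-1.2, False)])
    def test_absolute_value_rule_inclusive(self, z, want):
        s = SelectionScore("rs1", "P", "iHS", 0.1, 0.5, standardized=z)
        assert flag_extremes([s]) == [want]

    def test_one_tailed_mode(self):
        s = SelectionScore("rs1", "P", "iHS", 0.1, 0.5, standardized=-2.5)
        assert flag_extremes([s], two_tailed=False) == [False]


class TestNeutralCalibration:
    def test_extreme_rate_near_five_percent_under_neutrality(self):
        """Under the neutral structured model roughly 5% (z-threshold 2,
        two-tailed normal tail ~4.6%) of standardized scores are extreme."""
        from mirnapop.synthetic import SimConfig, simulate_structured_haplotypes
        cfg = SimConfig(seed=99, n_pops=1, n_hap=60, n_sites=400, F=0.05)
        mats, _ = simulate_structured_haplotypes(cfg)
        out = standardize(scan(mats["POP1"], "iHS"), n_bins=20)
        flags = flag_extremes(out)
        rate = np.mean(flags)
        assert rate <= 0.08  # ~5% with +-3% tolerance
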