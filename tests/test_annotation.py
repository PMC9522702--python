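"""Hairpin parsing, region partition, overlap marking, context and clusters."""

import itertools

import numpy as np
import pytest

from mirnapop.annotation import (MirnaHairpin, assign_context, detect_clusters,
                                 mark_overlaps, partition_regions,
                                 read_mirna_annotation)
from conftest import random_hairpin


def _intervals(rs, label):
    return sorted(rs.intervals(label))


class TestPartitionRegions:
    def test_plus_strand_both_matures(self):
        h = MirnaHairpin("h", "chr1", "+", (1000, 1080),
                         mature5p=(1010, 1032), mature3p=(1048, 1070))
        rs = partition_regions(h)
        assert _intervals(rs, "seed") == [(1011, 1018), (1049, 1056)]
        assert _intervals(rs, "mat") == [(1010, 1011), (1018, 1032),
                                         (1048, 1049), (1056, 1070)]
        assert _intervals(rs, "loop") == [(1032, 1048)]
        assert _intervals(rs, "pre") == [(1000, 1010), (1070, 1080)]
        assert _intervals(rs, "flank5") == [(920, 1000)]
        assert _intervals(rs, "flank3") == [(1080, 1160)]
        # arms attached to seed
        assert {(r.interval, r.arm) for r in rs.by_label("seed")} == \
            {((1011, 1018), "5p"), ((1049, 1056), "3p")}

    def test_single_mature_extends_pre_to_opposite_flank(self):
        h = MirnaHairpin("h", "chr1", "+", (1000, 1080), mature5p=(1010, 1032))
        rs = partition_regions(h)
        assert _intervals(rs, "loop") == []
        assert _intervals(rs, "pre") == [(1000, 1010), (1032, 1080)]

    def test_minus_strand_seed_counted_from_high_end(self):
        # transcript position 1 sits at the highest genomic coordinate;
        # positions 2-8 of a mature ending at 1080 span [1072, 1079)
        h = MirnaHairpin("h", "chr1", "-", (1000, 1080), mature5p=(1058, 1080))
        rs = partition_regions(h)
        assert _intervals(rs, "seed") == [(1072, 1079)]
        assert _intervals(rs, "flank5") == [(1080, 1160)]
        assert _intervals(rs, "flank3") == [(920, 1000)]

    def test_no_mature_errors(self):
        h = MirnaHairpin("h", "chr1", "+", (0, 100))
        with pytest.raises(ValueError, match="no mature"):
            partition_regions(h)

    def test_nonflank_regions_tile_span_disjointly(self, rng):
        for _ in range(60):
            h = random_hairpin(rng, both_matures=bool(rng.integers(0, 2)))
            rs = partition_regions(h)
            inner = sorted(r.interval for r in rs.regions
                           if r.label not in ("flank5", "flank3"))
            # disjoint and covering: consecutive intervals abut exactly
            assert inner[0][0] == h.span[0] and inner[-1][1] == h.span[1]
            for (s0, e0), (s1, e1) in zip(inner, inner[1:]):
                assert e0 == s1
            total = sum(e - s for s, e in inner)
            assert total == h.length
            for lbl in ("flank5", "flank3"):
                (iv,) = rs.intervals(lbl)
                assert iv[1] - iv[0] == h.length
            for r in rs.by_label("seed"):
                assert r.interval[1] - r.interval[0] == 7

    def test_strand_symmetry(self, rng):
        """Mirroring a + strand hairpin around its span midline yields the
        mirrored partition on the - strand."""
        for _ in range(30):
            h = random_hairpin(rng, strand="+", both_matures=True)
            s, e = h.span
            pivot = s + e  # x -> pivot - x reflects [s, e) onto itself

            def mirror(iv):
                return (pivot - iv[1], pivot - iv[0])

            hm = MirnaHairpin(h.id, h.chrom, "-", h.span,
                              mature5p=mirror(h.mature5p),
                              mature3p=mirror(h.mature3p))
            rs, rsm = partition_regions(h), partition_regions(hm)
            for lbl in ("seed", "mat", "loop", "pre"):
                assert sorted(map(mirror, rs.intervals(lbl))) == \
                    _intervals(rsm, lbl), lbl
            assert mirror(rs.intervals("flank5")[0]) == rsm.intervals("flank5")[0]


class TestMarkOverlaps:
    def test_disjoint(self):
        hs = [MirnaHairpin("a", "chr1", "+", (0, 100)),
              MirnaHairpin("b", "chr1", "+", (200, 300))]
        assert mark_overlaps(hs) == {}

    def test_simple_pair(self):
        hs = [MirnaHairpin("a", "chr1", "+", (0, 100)),
              MirnaHairpin("b", "chr1", "+", (50, 150))]
        assert mark_overlaps(hs) == {"a": [(50, 100)], "b": [(50, 100)]}

    def test_matches_pairwise_bruteforce(self, rng):
        for _ in range(20):
            starts = rng.integers(0, 400, size=6)
            lens = rng.integers(50, 120, size=6)
            hs = [MirnaHairpin(f"h{i}", "chr1", "+", (int(s), int(s + l)))
                  for i, (s, l) in enumerate(zip(starts, lens))]
            got = mark_overlaps(hs)
            for h in hs:
                covered = set()
                for other in hs:
                    if other.id == h.id:
                        continue
                    lo = max(h.span[0], other.span[0])
                    hi = min(h.span[1], other.span[1])
                    covered.update(range(lo, hi))
                expect = covered
                pieces = got.get(h.id, [])
                assert set(itertools.chain.from_iterable(
                    range(s, e) for s, e in pieces)) == expect
                # pieces are merged: disjoint and sorted
                for (s0, e0), (s1, e1) in zip(pieces, pieces[1:]):
                    assert e0 < s1


class TestAssignContext:
    H = MirnaHairpin("h", "chr1", "+", (1000, 1080))

    def test_pc_intron(self):
        ctx = assign_context(self.H, pc=[(500, 2000)], exons=[(500, 900)])
        assert ctx.flags == {"PC"} and ctx.location == "intronic"

    def test_pc_plus_te(self):
        ctx = assign_context(self.H, pc=[(500, 2000)], te=[(1050, 1400, "Alu")])
        assert ctx.flags == {"PC", "TE"} and ctx.te_families == ["Alu"]

    def test_intergenic(self):
        ctx = assign_context(self.H)
        assert ctx.flags == {"Intg"}

    def test_one_bp_overlap_suffices(self):
        assert "PC" in assign_context(self.H, pc=[(1079, 1200)]).flags
        assert "PC" not in assign_context(self.H, pc=[(1080, 1200)]).flags

    def test_order_independent(self, rng):
        te = [(int(s), int(s) + 40, fam) for s, fam in
              zip(rng.integers(900, 1200, 6), ["Alu", "L1", "MIR"] * 2)]
        pc = [(950, 1005), (1070, 1300)]
        a = assign_context(self.H, pc=pc, te=te)
        b = assign_context(self.H, pc=pc[::-1], te=te[::-1])
        assert (a.flags, a.te_families) == (b.flags, b.te_families)


class TestDetectClusters:
    def _pair(self, gap):
        return [MirnaHairpin("a", "chr1", "+", (0, 80)),
                MirnaHairpin("b", "chr1", "+", (80 + gap, 160 + gap))]

    def test_gap_at_most_10kb_clusters(self):
        assert len(detect_clusters(self._pair(9_999))) == 1
        assert len(detect_clusters(self._pair(10_000))) == 1

    def test_gap_above_10kb_does_not(self):
        assert detect_clusters(self._pair(10_001)) == []

    def test_transitive_chaining(self):
        hs = [MirnaHairpin(n, "chr1", "+", (s, s + 80))
              for n, s in [("a", 0), ("b", 8_080), ("c", 16_160)]]
        (c,) = detect_clusters(hs)
        assert c.member_ids == ["a", "b", "c"]

    def test_strands_do_not_mix(self):
        hs = [MirnaHairpin("a", "chr1", "+", (0, 80)),
              MirnaHairpin("b", "chr1", "-", (100, 180))]
        assert detect_clusters(hs) == []

    def test_matches_transitive_closure_oracle(self, rng):
        for _ in range(15):
            n = int(rng.integers(2, 40))
            hs = []
            for i in range(n):
                start = int(rng.integers(0, 200_000))
                strand = str(rng.choice(["+", "-"]))
                hs.append(MirnaHairpin(f"h{i}", "chr1", strand,
                                       (start, start + int(rng.integers(50, 150)))))
            got = sorted(sorted(c.member_ids) for c in detect_clusters(hs))

            # O(n^2) union-find over all pairs with gap <= 10 kb
            parent = {h.id: h.id for h in hs}

            def find(x):
                while parent[x] != x:
                    parent[x] = parent[parent[x]]
                    x = parent[x]
                return x

            for a, b in itertools.combinations(hs, 2):
                if a.strand != b.strand:
                    continue
                gap = max(a.span[0], b.span[0]) - min(a.span[1], b.span[1])
                if gap <= 10_000:
                    parent[find(a.id)] = find(b.id)
            comps = {}
            for h in hs:
                comps.setdefault(find(h.id), []).append(h.id)
            want = sorted(sorted(m) for m in comps.values() if len(m) >= 2)
            assert got == want


class TestGff3Reader:
    GFF = """##gff-version 3
chr1\t.\tmiRNA_primary_transcript\t1001\t1080\t.\t+\t.\tID=MI1;Name=syn-mir-1
chr1\t.\tmiRNA\t1011\t1032\t.\t+\t.\tID=MA1;Name=syn-mir-1-5p;Derives_from=MI1
"""

    def test_two_line_primary_plus_5p(self, tmp_path):
        p = tmp_path / "a.gff3"
        p.write_text(self.GFF)
        (h,) = read_mirna_annotation(str(p))
        assert h.id == "syn-mir-1" and h.span == (1000, 1080)
        assert h.mature5p == (1010, 1032) and h.mature3p is None

    def test_both_matures_attached(self, tmp_path):
        gff = self.GFF + ("chr1\t.\tmiRNA\t1049\t1070\t.\t+\t.\t"
                          "ID=MA2;Name=syn-mir-1-3p;Derives_from=MI1\n")
        p = tmp_path / "b.gff3"
        p.write_text(gff)
        (h,) = read_mirna_annotation(str(p))
        assert h.mature5p == (1010, 1032) and h.mature3p == (1048, 1070)

    def test_unknown_parent_skipped_with_warning(self, tmp_path, caplog):
        gff = self.GFF + ("chr1\t.\tmiRNA\t1049\t1070\t.\t+\t.\t"
                          "ID=MA2;Name=x-3p;Derives_from=NOPE\n")
        p = tmp_path / "c.gff3"
        p.write_text(gff)
        import logging
        with caplog.at_level(logging.WARNING):
            (h,) = read_mirna_annotation(str(p))
        assert h.mature3p is None
        assert any("unknown parent" in r.message for r in caplog.records)

    def test_arm_inferred_from_position_when_unnamed(self, tmp_path):
        gff = """##gff-version 3
chr1\t.\tmiRNA_primary_transcript\t1001\t1080\t.\t-\t.\tID=MI1;Name=m
chr1\t.\tmiRNA\t1011\t1032\t.\t-\t.\tID=MA1;Name=m-mat;Derives_from=MI1
"""
        p = tmp_path / "d.gff3"
        p.write_text(gff)
        (h,) = read_mirna_annotation(str(p))
        # on the minus strand the low-coordinate mature is transcript-3'... but
        # a single unnamed mature defaults to the 5p slot only if it is the
        # transcript-5'-most; here it is the only one, so it lands in 5p
        assert (h.mature5p or h.mature3p) == (1010, 1032)
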