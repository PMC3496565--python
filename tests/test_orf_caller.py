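import numpy as np
import pytest

from baculokit import genome_io as gio
from baculokit import orf_caller as oc
from _oracles import orf_oracle


def _ivset(records):
    return {(r.interval.start, r.interval.end, r.interval.strand)
            for r in records}


class TestEnumerate:
    def test_single_linear_orf(self):
        seq = "CC" + "ATG" + "GCA" * 55 + "TAA" + "GG"
        g = gio.Genome("t", seq, topology="linear")
        cands = oc.enumerate_candidates(g, min_aa=50)
        assert len(cands) == 1
        rec = cands[0]
        assert rec.aa_length == 56
        assert rec.interval.span() == 3 * (rec.aa_length + 1)
        assert rec.protein.startswith("M")

    def test_wrap_candidate(self):
        core = "ATG" + "GCA" * 55 + "TAA"
        n = 300
        seq = list("C" * n)
        for i, b in enumerate(core):
            seq[(249 + i) % n] = b
        g = gio.Genome("c", "".join(seq))
        cands = oc.enumerate_candidates(g, min_aa=50)
        assert len(cands) == 1
        assert cands[0].interval.wraps_origin

    def test_minus_strand_coordinates(self):
        core = "ATG" + "GCA" * 55 + "TAA"
        g = gio.Genome("m", "TTTTT" + gio.reverse_complement(core) + "GGGGG",
                       topology="linear")
        (rec,) = oc.enumerate_candidates(g, min_aa=50)
        assert rec.interval.strand == "-"
        assert gio.subsequence(g, rec.interval) == core

    def test_matches_bruteforce_oracle(self):
        for seed in range(20):
            rng = np.random.default_rng(seed)
            n = int(rng.integers(1000, 5000))
            seq = "".join(rng.choice(list("ACGT"), size=n,
                                     p=[.29, .21, .21, .29]))
            g = gio.Genome(f"r{seed}", seq)
            assert _ivset(oc.enumerate_candidates(g, min_aa=50)) == \
                orf_oracle(g, 50)

    def test_too_short_genome(self):
        with pytest.raises(ValueError):
            oc.enumerate_candidates(gio.Genome("x", "AC"), 50)


class TestSelection:
    def _orf(self, s, e, strand="+"):
        iv = gio.FeatureInterval(s, e, strand)
        return oc.OrfRecord(interval=iv, aa_length=(e - s + 1) // 3 - 1)

    def test_disjoint_kept(self):
        a, b = self._orf(1, 300), self._orf(400, 700)
        assert len(oc.select_minimal_overlap([a, b], 1000)) == 2

    def test_nested_dropped(self):
        big = self._orf(1, 603)      # 200 aa
        small = self._orf(100, 282)  # 60 aa nested
        kept = oc.select_minimal_overlap([big, small], 1000)
        assert kept == [big]

    def test_overlap_cap_respected(self):
        rng = np.random.default_rng(0)
        orfs = [self._orf(int(s), int(s) + 299)
                for s in rng.integers(1, 4700, size=40)]
        kept = oc.select_minimal_overlap(orfs, 5000, max_overlap_nt=75)
        for i, a in enumerate(kept):
            for b in kept[i + 1 :]:
                assert oc._overlap_nt(a.interval, b.interval, 5000) <= 75

    def test_planted_orfs_beat_nested_decoys(self, planted_genome):
        g, truth = planted_genome
        cands = oc.enumerate_candidates(g, min_aa=50)
        kept = oc.select_minimal_overlap(cands, g.length)
        planted = {(o["interval"].start, o["interval"].end,
                    o["interval"].strand) for o in truth.orfs}
        assert _ivset(kept) == planted


class TestNumbering:
    def _orfs(self):
        return [
            oc.OrfRecord(interval=gio.FeatureInterval(1, 300, "+"),
                         aa_length=99),
            oc.OrfRecord(interval=gio.FeatureInterval(400, 700, "-"),
                         aa_length=99),
            oc.OrfRecord(interval=gio.FeatureInterval(800, 950, "+"),
                         aa_length=49),
        ]

    def test_anchor_at_origin_identity(self):
        orfs = self._orfs()
        out = oc.number_from_anchor(orfs, orfs[0], 1000)
        assert [o.serial for o in out] == [1, 2, 3]
        assert out[0].interval == gio.FeatureInterval(1, 300, "+")

    def test_minus_anchor_is_involution(self):
        orfs = self._orfs()
        once = oc.number_from_anchor(orfs, orfs[1], 1000)
        anchor_once = [o for o in once if o.serial == 1][0]
        assert anchor_once.interval.strand == "+"
        assert anchor_once.interval.start == 1
        # reflect+rotate applied around the original anchor twice restores
        # pairwise distances between starts
        spans_before = sorted(o.interval.span(1000) for o in orfs)
        spans_after = sorted(o.interval.span(1000) for o in once)
        assert spans_before == spans_after

    def test_missing_anchor(self):
        orfs = self._orfs()
        stray = oc.OrfRecord(interval=gio.FeatureInterval(10, 99, "+"),
                             aa_length=29)
        with pytest.raises(LookupError):
            oc.number_from_anchor(orfs, stray, 1000)


class TestGenomeStats:
    def test_single_orf_fraction(self):
        g = gio.Genome("s", "A" * 500 + "C" * 500)
        orf = oc.OrfRecord(interval=gio.FeatureInterval(1, 300, "+"),
                           aa_length=99)
        st = oc.genome_stats([orf], g)
        assert st["coding_fraction"] == pytest.approx(0.300)

    def test_overlap_counted_once(self):
        g = gio.Genome("s", "A" * 1000)
        a = oc.OrfRecord(interval=gio.FeatureInterval(1, 300, "+"),
                         aa_length=99)
        b = oc.OrfRecord(interval=gio.FeatureInterval(251, 550, "+"),
                         aa_length=99)
        st = oc.genome_stats([a, b], g)
        assert st["coding_fraction"] == pytest.approx(0.550)

    def test_monotone_in_orfs(self):
        g = gio.Genome("s", "A" * 1000)
        orfs = [oc.OrfRecord(interval=gio.FeatureInterval(i * 100 + 1,
                                                          i * 100 + 90, "+"),
                             aa_length=29) for i in range(5)]
        fracs = [oc.genome_stats(orfs[: k + 1], g)["coding_fraction"]
                 for k in range(5)]
        assert fracs == sorted(fracs)
        assert all(0 <= f <= 1 for f in fracs)
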