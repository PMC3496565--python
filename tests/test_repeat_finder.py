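import numpy as np
import pytest

from baculokit import genome_io as gio
from baculokit import repeat_finder as rf
from baculokit import synthetic_data as sd
from _oracles import palindrome_oracle


def _palset(pals):
    return {(p.interval.start, p.interval.end, p.arm_length,
             p.loop_length, p.mismatches) for p in pals}


class TestFindPalindromes:
    def test_perfect_palindrome(self):
        g = gio.Genome("t", "GGGGGGAAATTTGGGGGG", topology="linear")
        pals = rf.find_palindromes(g, min_arm=3, max_loop=0,
                                   max_mismatch_rate=0.0, max_arm=10)
        assert [(p.interval.start, p.interval.end, p.arm_length)
                for p in pals] == [(7, 12, 3)]

    def test_matches_bruteforce_oracle(self):
        for seed in range(20):
            rng = np.random.default_rng(seed)
            seq = "".join(rng.choice(list("ACGT"), size=2000,
                                     p=[.29, .21, .21, .29]))
            g = gio.Genome(f"p{seed}", seq)
            mine = rf.find_palindromes(g, min_arm=8, max_loop=10,
                                       max_mismatch_rate=0.15, max_arm=50)
            orc = palindrome_oracle(g, 8, 10, 0.15, 50)
            assert _palset(mine) == _palset(orc)

    def test_planted_imperfect_palindrome_exact_span(self):
        rng = np.random.default_rng(4)
        recipe = sd.GenomeRecipe(
            length=3000, at_target=0.5,
            hr_cassettes=[sd.HrCassette(n_palindromes=1, arm=21, loop=16,
                                        mismatches=2)],
            seed=4,
            detector_mismatch_rate=0.1,  # budget floor(21*0.1) = 2 planted
        )
        g, truth = sd.make_genome(recipe)
        planted = truth.palindromes[0]["interval"]
        pals = rf.find_palindromes(g, min_arm=15, max_loop=40,
                                   max_mismatch_rate=0.1)
        spans = [(p.interval.start, p.interval.end) for p in pals
                 if p.interval.start == planted.start]
        assert (planted.start, planted.end) in spans

    def test_mismatch_budget_verifies_by_direct_comparison(self):
        rng = np.random.default_rng(7)
        seq = "".join(rng.choice(list("ACGT"), size=3000))
        g = gio.Genome("v", seq)
        comp = {"A": "T", "T": "A", "C": "G", "G": "C"}
        for p in rf.find_palindromes(g, min_arm=8, max_loop=8,
                                     max_mismatch_rate=0.25, max_arm=40):
            s = gio.subsequence(g, p.interval)
            a = p.arm_length
            mism = sum(1 for i in range(a)
                       if comp.get(s[i]) != s[-1 - i])
            assert mism == p.mismatches
            assert mism <= int(np.floor(a * 0.25))

    def test_at_fraction_consistency_for_perfect_palindrome(self):
        g = gio.Genome("t", "CCCCATATTATATCCCC", topology="linear")
        pals = rf.find_palindromes(g, min_arm=4, max_loop=2,
                                   max_mismatch_rate=0.0, max_arm=8)
        for p in pals:
            s = gio.subsequence(g, p.interval)
            arm = s[: p.arm_length]
            assert p.at_fraction == pytest.approx(
                gio.at_fraction(arm), abs=0.25
            )


class TestHairpinDeltaG:
    def _pal(self, span, arm, loop):
        return rf.Palindrome(interval=gio.FeatureInterval(1, span, "+"),
                             arm_length=arm, loop_length=loop, mismatches=0,
                             at_fraction=0.0)

    def test_gc_stem_stabler_than_at(self):
        stem_g = "G" * 10
        stem_a = "A" * 10
        g1 = gio.Genome("g", stem_g + "TTTT"
                        + gio.reverse_complement(stem_g), topology="linear")
        g2 = gio.Genome("a", stem_a + "TTTT"
                        + gio.reverse_complement(stem_a), topology="linear")
        p = self._pal(24, 10, 4)
        assert rf.hairpin_delta_g(p, g1) < rf.hairpin_delta_g(p, g2)

    def test_mismatch_raises_energy(self):
        stem = "GCGCGCGCGC"
        perfect = stem + "TTTT" + gio.reverse_complement(stem)
        broken = list(perfect)
        broken[-1] = "A" if broken[-1] != "A" else "C"  # break outermost pair
        gp = gio.Genome("p", perfect, topology="linear")
        gb = gio.Genome("b", "".join(broken), topology="linear")
        p = self._pal(24, 10, 4)
        assert rf.hairpin_delta_g(p, gp) < rf.hairpin_delta_g(p, gb)

    def test_matches_hand_summed_table(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            arm = int(rng.integers(4, 12))
            loop = int(rng.integers(3, 8))
            stem = "".join(rng.choice(list("ACGT"), size=arm))
            seq = stem + "".join(rng.choice(list("ACGT"), size=loop)) \
                + gio.reverse_complement(stem)
            g = gio.Genome("h", seq, topology="linear")
            p = self._pal(len(seq), arm, loop)
            expect = rf._loop_penalty(loop)
            for i in range(arm - 1):
                expect += rf.NN_DELTA_G[stem[i : i + 2]]
            assert rf.hairpin_delta_g(p, g) == pytest.approx(expect)

    def test_tiny_arm_rejected(self):
        g = gio.Genome("x", "ATTTAT", topology="linear")
        with pytest.raises(ValueError):
            rf.hairpin_delta_g(self._pal(6, 1, 4), g)


class TestClusterHrs:
    def _pal_at(self, start, span=58):
        return rf.Palindrome(
            interval=gio.FeatureInterval(start, start + span - 1, "+"),
            arm_length=21, loop_length=16, mismatches=0, at_fraction=0.7)

    def test_distant_palindromes_two_hrs(self):
        g = gio.Genome("g", "A" * 10_000)
        hrs = rf.cluster_hrs([self._pal_at(100), self._pal_at(2500)], g,
                             max_gap=500)
        assert len(hrs) == 2

    def test_close_palindromes_one_hr(self):
        g = gio.Genome("g", "A" * 10_000)
        hrs = rf.cluster_hrs(
            [self._pal_at(100), self._pal_at(300), self._pal_at(500)], g,
            max_gap=500)
        assert len(hrs) == 1 and len(hrs[0].palindromes) == 3

    def test_wrap_adjacency(self):
        g = gio.Genome("g", "A" * 10_000)
        hrs = rf.cluster_hrs([self._pal_at(50), self._pal_at(9900)], g,
                             max_gap=500)
        assert len(hrs) == 1

    def test_cluster_count_monotone_in_gap(self):
        g = gio.Genome("g", "A" * 10_000)
        pals = [self._pal_at(int(s))
                for s in np.random.default_rng(0).integers(1, 9000, size=12)]
        pals.sort(key=lambda p: p.interval.start)
        counts = [len(rf.cluster_hrs(pals, g, max_gap=gap))
                  for gap in (50, 200, 800, 3200)]
        assert counts == sorted(counts, reverse=True)

    def test_planted_memberships_recovered(self, planted_genome):
        g, truth = planted_genome
        pals = rf.find_palindromes(g)
        hrs = rf.cluster_hrs(pals, g, max_gap=1000)
        assert len(hrs) == len(truth.hrs) == 16
        assert sum(len(h.palindromes) for h in hrs) == 26
        got = sorted(
            tuple(sorted(p.interval.start for p in h.palindromes))
            for h in hrs
        )
        want = {}
        for p in truth.palindromes:
            want.setdefault(p["hr"], []).append(p["interval"].start)
        assert got == sorted(tuple(sorted(v)) for v in want.values())


class TestConservedEnds:
    def test_planted_flank_recovered(self, planted_genome):
        g, truth = planted_genome
        pals = rf.find_palindromes(g)
        left, right, pfm, symmetric = rf.conserved_ends(pals, g, 15)
        assert left == sd.CONSERVED_END
        assert right == gio.reverse_complement(sd.CONSERVED_END)
        assert symmetric

    def test_block13_is_infix_of_block15(self, planted_genome):
        g, truth = planted_genome
        pals = rf.find_palindromes(g)
        l15, r15, _, _ = rf.conserved_ends(pals, g, 15)
        l13, r13, _, _ = rf.conserved_ends(pals, g, 13)
        assert l13 in l15 and r13 in r15

    def test_too_few_palindromes(self, planted_genome):
        g, truth = planted_genome
        pals = rf.find_palindromes(g)[:2]
        with pytest.raises(ValueError):
            rf.conserved_ends(pals, g, 15)


class TestSelfSimilarityAndDirectRepeats:
    def test_planted_duplicate_found_no_spurious(self):
        rng = np.random.default_rng(5)
        s = "".join(rng.choice(list("ACGT"), size=5000))
        seg = s[1000:1120]
        g = gio.Genome("d", s[:3000] + seg + s[3120:], topology="linear")
        hits = rf.self_similarity(g, min_len=100, min_identity=90)
        assert [(h.a.start, h.a.end, h.b.start, h.b.end, h.orientation)
                for h in hits] == [(1001, 1120, 3001, 3120, "direct")]

    def test_no_repeats_empty(self):
        rng = np.random.default_rng(9)
        g = gio.Genome("e", "".join(rng.choice(list("ACGT"), size=4000)),
                       topology="linear")
        assert rf.self_similarity(g, min_len=100, min_identity=90) == []

    def test_inverted_copy_orientation(self):
        rng = np.random.default_rng(5)
        s = "".join(rng.choice(list("ACGT"), size=5000))
        seg = gio.reverse_complement(s[1000:1120])
        g = gio.Genome("i", s[:3000] + seg + s[3120:], topology="linear")
        hits = rf.self_similarity(g, min_len=100, min_identity=90)
        assert any(h.orientation == "revcomp" for h in hits)

    def test_tandem_unit_pair(self):
        rng = np.random.default_rng(2)
        unit = "".join(rng.choice(list("ACGT"), size=31))
        region_seq = ("".join(rng.choice(list("ACGT"), size=100)) + unit
                      + unit + "".join(rng.choice(list("ACGT"), size=100)))
        g = gio.Genome("t", region_seq, topology="linear")
        pairs = rf.find_direct_repeats(
            gio.FeatureInterval(1, len(region_seq), "+"), g, min_unit=25)
        assert any(p.unit_length_a == 31 and p.identity == 100.0
                   for p in pairs)

    def test_random_region_empty_at_high_identity(self):
        rng = np.random.default_rng(3)
        g = gio.Genome("r", "".join(rng.choice(list("ACGT"), size=300)),
                       topology="linear")
        pairs = rf.find_direct_repeats(gio.FeatureInterval(1, 300, "+"), g,
                                       min_unit=25, min_identity=90)
        assert pairs == []

    def test_imperfect_pair_unit_lengths(self, planted_genome):
        g, truth = planted_genome
        units = truth.ori["unit_intervals"]
        b1, b2 = units[2], units[3]
        region = gio.FeatureInterval(truth.ori["interval"].start - 50,
                                     truth.ori["interval"].end + 50, "+")
        pairs = rf.find_direct_repeats(region, g, min_unit=25,
                                       min_identity=72)
        hit = [p for p in pairs
               if abs(p.a.start - b1.start) <= 10
               and abs(p.b.start - b2.start) <= 10]
        assert hit
        assert abs(hit[0].unit_length_a - b1.span()) <= 10
        assert abs(hit[0].unit_length_b - b2.span()) <= 10


class TestNonHrOri:
    def test_planted_cassette_flagged(self, planted_genome):
        g, truth = planted_genome
        pals = rf.find_palindromes(g)
        hrs = rf.cluster_hrs(pals, g)
        cands = rf.flag_non_hr_ori(g, hrs)
        oi = truth.ori["interval"]
        assert any(
            c.tier == 1
            and not (c.interval.end < oi.start or c.interval.start > oi.end)
            for c in cands
        )

    def test_plain_hr_not_flagged(self):
        recipe = sd.GenomeRecipe(
            length=6000, at_target=0.55,
            hr_cassettes=[sd.HrCassette(n_palindromes=1)],
            ori_cassette=None, seed=12,
        )
        g, truth = sd.make_genome(recipe)
        pals = rf.find_palindromes(g)
        hrs = rf.cluster_hrs(pals, g)
        assert [c for c in rf.flag_non_hr_ori(g, hrs) if c.tier == 1] == []
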