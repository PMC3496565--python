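import numpy as np
import pytest

from baculokit import genome_io as gio


@pytest.fixture
def toy():
    return gio.Genome("g", "AACCGGTT")


class TestGenomeBasics:
    def test_identity_fasta(self, tmp_path):
        p = tmp_path / "g.fa"
        p.write_text(">g\nACGT\n")
        g = gio.read_fasta(p)
        assert g.length == 4 and g.sequence == "ACGT"

    def test_fasta_roundtrip_byte_identical(self, tmp_path):
        rng = np.random.default_rng(7)
        seq = "".join(rng.choice(list("ACGT"), size=10_000))
        g = gio.Genome("fix", seq)
        p = gio.write_fasta(g, tmp_path / "x.fa")
        g2 = gio.read_fasta(p)
        assert g2.sequence == g.sequence and g2.id == g.id

    def test_bad_alphabet_names_position(self, tmp_path):
        with pytest.raises(gio.GenomeFormatError, match="position 3"):
            gio.Genome("bad", "ACXGT")

    def test_empty_fasta_rejected(self, tmp_path):
        p = tmp_path / "e.fa"
        p.write_text("")
        with pytest.raises(gio.GenomeFormatError):
            gio.read_fasta(p)

    @pytest.mark.parametrize("seq,expect", [("ATAT", 1.0), ("ACGT", 0.5)])
    def test_at_fraction(self, seq, expect):
        assert gio.at_fraction(gio.Genome("x", seq)) == expect

    def test_at_fraction_excludes_n(self):
        assert gio.at_fraction(gio.Genome("x", "ATNN")) == 1.0

    def test_all_n_undefined(self):
        with pytest.raises(gio.GenomeFormatError):
            gio.at_fraction(gio.Genome("x", "NNNN"))


class TestSubsequence:
    def test_forward(self, toy):
        assert gio.subsequence(toy, gio.FeatureInterval(3, 6, "+")) == "CCGG"

    def test_reverse_is_revcomp(self, toy):
        fwd = gio.subsequence(toy, gio.FeatureInterval(3, 6, "+"))
        rev = gio.subsequence(toy, gio.FeatureInterval(3, 6, "-"))
        assert rev == gio.reverse_complement(fwd)

    def test_wrap(self, toy):
        assert gio.subsequence(toy, gio.FeatureInterval(7, 2, "+")) == "TTAA"

    def test_wrap_on_linear_rejected(self):
        g = gio.Genome("l", "AACCGGTT", topology="linear")
        with pytest.raises(gio.TopologyError):
            gio.subsequence(g, gio.FeatureInterval(7, 2, "+"))

    def test_random_intervals_match_independent_revcomp(self):
        rng = np.random.default_rng(0)
        seq = "".join(rng.choice(list("ACGT"), size=300))
        g = gio.Genome("r", seq)
        comp = {"A": "T", "T": "A", "C": "G", "G": "C"}
        for _ in range(100):
            s, e = sorted(rng.integers(1, 301, size=2))
            fwd = gio.subsequence(g, gio.FeatureInterval(int(s), int(e), "+"))
            rev = gio.subsequence(g, gio.FeatureInterval(int(s), int(e), "-"))
            assert rev == "".join(comp[c] for c in reversed(fwd))

    def test_span_equals_subsequence_length_including_wrap(self, toy):
        for iv in (gio.FeatureInterval(3, 6), gio.FeatureInterval(7, 2),
                   gio.FeatureInterval(8, 1)):
            assert len(gio.subsequence(toy, iv)) == iv.span(toy.length)


class TestTranslate:
    @pytest.mark.parametrize("cds,aa", [("ATGAAATAA", "MK"),
                                        ("ATGTTTGGG", "MFG")])
    def test_basic(self, cds, aa):
        assert gio.translate(cds) == aa

    def test_frame_error(self):
        with pytest.raises(ValueError, match="divisible by 3"):
            gio.translate("ATGA")

    def test_internal_stop_strict(self):
        with pytest.raises(ValueError, match="internal stop"):
            gio.translate("ATGTAAAAATAA")
        assert gio.translate("ATGTAAAAATAA", strict=False) == "M"

    def test_length_relation(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            n_codons = int(rng.integers(2, 30))
            cds = "".join(
                c for c in (
                    "".join(rng.choice(list("ACGT"), size=3))
                    for _ in range(n_codons)
                )
            )
            aa = gio.translate(cds, strict=False)
            assert len(aa) <= len(cds) // 3


class TestFeatureOutput:
    def test_bed_convention(self, toy, tmp_path):
        f = gio.Feature("f1", gio.FeatureInterval(1, 3, "+"), "CDS")
        p = gio.write_outputs([f], toy, tmp_path / "x.bed", "bed")
        cols = p.read_text().split("\t")
        assert cols[1] == "0" and cols[2] == "3"

    def test_gff3_roundtrip_with_wrap_split(self, tmp_path):
        rng = np.random.default_rng(1)
        g = gio.Genome("big", "".join(rng.choice(list("ACGT"), size=2000)))
        feats = [
            gio.Feature("a", gio.FeatureInterval(10, 300, "+"), "CDS"),
            gio.Feature("w", gio.FeatureInterval(1950, 50, "-"), "CDS",
                        {"note": "wraps"}),
        ]
        p = gio.write_outputs(feats, g, tmp_path / "f.gff3", "gff3")
        lines = [l for l in p.read_text().splitlines()
                 if not l.startswith("#")]
        assert len(lines) == 3  # wrap feature split into two parts
        back = gio.read_gff3(p, genome_length=g.length)
        assert len(back) == 2
        by_id = {f.id: f for f in back}
        assert by_id["w"].interval == gio.FeatureInterval(1950, 50, "-")
        assert by_id["w"].attributes["note"] == "wraps"

    def test_feature_count_preserved(self, tmp_path):
        rng = np.random.default_rng(2)
        g = gio.Genome("g", "".join(rng.choice(list("ACGT"), size=5000)))
        feats = [
            gio.Feature(f"f{i}", gio.FeatureInterval(10 * i + 1, 10 * i + 9),
                        "CDS")
            for i in range(133)
        ]
        p = gio.write_outputs(feats, g, tmp_path / "m.gff3", "gff3")
        assert len(gio.read_gff3(p, g.length)) == 133

    def test_out_of_range_rejected(self, toy, tmp_path):
        f = gio.Feature("f", gio.FeatureInterval(1, 99), "CDS")
        with pytest.raises(ValueError):
            gio.write_outputs([f], toy, tmp_path / "x.gff3", "gff3")
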