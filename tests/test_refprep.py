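"""Reference preparation: FASTA loading, strand conversion, seed index."""
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from bsmapper import (
    FastaParseError,
    Genome,
    ReferenceSet,
    build_index,
    build_reference,
    convert_reference,
    load_fasta,
    revcomp,
)
from bsmapper._dna import ct_convert, ga_convert

from conftest import make_genome, spaces_of

dna = st.text(alphabet="ACGT", min_size=1, max_size=60)
dna_n = st.text(alphabet="ACGTN", min_size=1, max_size=60)


class TestLoadFasta:
    @pytest.mark.parametrize(
        "content,expected",
        [
            (">chr1\nACGT\n", {"chr1": "ACGT"}),
            (">a x\nAC\n>b\nGT\n", {"a": "AC", "b": "GT"}),
            (">c\nacgt\n", {"c": "ACGT"}),
            (">d\nAC\nGT\n", {"d": "ACGT"}),
        ],
    )
    def test_valid_records(self, tmp_path, content, expected):
        p = tmp_path / "g.fa"
        p.write_text(content)
        g = load_fasta(p)
        assert g.sequences == expected

    @pytest.mark.parametrize(
        "content",
        ["", "ACGT\n", ">a\nACGT\n>a\nTT\n", ">a\n>b\nAC\n"],
        ids=["empty", "no-header", "duplicate-name", "empty-record"],
    )
    def test_malformed_input_raises(self, tmp_path, content):
        p = tmp_path / "g.fa"
        p.write_text(content)
        with pytest.raises(FastaParseError):
            load_fasta(p)

    def test_ambiguity_codes_collapse_to_n(self, tmp_path):
        p = tmp_path / "g.fa"
        p.write_text(">a\nACRYGT\n")
        assert load_fasta(p).sequences == {"a": "ACNNGT"}

    def test_invalid_character_reported(self, tmp_path):
        p = tmp_path / "g.fa"
        p.write_text(">a\nAC!T\n")
        with pytest.raises(FastaParseError, match="'!'"):
            load_fasta(p)


class TestConvertReference:
    def test_four_spaces_of_tacg(self):
        sp = spaces_of("TACG")
        assert sp["W_CT"].sequence("chr1") == "TATG"
        assert sp["C_CT"].sequence("chr1") == "TGTA"  # revcomp then C->T
        assert sp["RCW_GA"].sequence("chr1") == "CATA"
        assert sp["RCC_GA"].sequence("chr1") == "TACA"

    @settings(derandomize=True, max_examples=60)
    @given(seq=dna_n)
    def test_revcomp_identity_and_alphabet(self, seq):
        sp = spaces_of(seq)
        w, c = sp["W_CT"].sequence("chr1"), sp["C_CT"].sequence("chr1")
        assert sp["RCW_GA"].sequence("chr1") == revcomp(w)
        assert sp["RCC_GA"].sequence("chr1") == revcomp(c)
        assert "C" not in w and "C" not in c
        assert "G" not in sp["RCW_GA"].sequence("chr1")
        assert "G" not in sp["RCC_GA"].sequence("chr1")
        for s in sp.values():
            assert len(s.sequence("chr1")) == len(seq)

    @settings(derandomize=True, max_examples=30)
    @given(seq=dna_n)
    def test_conversion_idempotent(self, seq):
        assert ct_convert(ct_convert(seq)) == ct_convert(seq)
        assert ga_convert(ga_convert(seq)) == ga_convert(seq)

    def test_multi_chromosome_order_preserved(self):
        g = make_genome({"b": "ACG", "a": "TTT"})
        sp = convert_reference(g)[0]
        assert sp.names == ("b", "a")


class TestSeedIndex:
    def test_exhaustive_enumeration_tatg(self):
        sp = spaces_of("TATG")["W_CT"]
        idx = build_index(sp, 2)
        assert idx.table == {"TA": [("chr1", 0)], "AT": [("chr1", 1)], "TG": [("chr1", 2)]}

    def test_kmers_containing_n_excluded(self):
        from conftest import make_space

        idx = build_index(make_space("TNTG"), 2)
        assert idx.table == {"TG": [("chr1", 2)]}

    def test_k_exceeding_every_chromosome_raises(self):
        sp = spaces_of("ACGT")["W_CT"]
        with pytest.raises(ValueError):
            build_index(sp, 5)
        with pytest.raises(ValueError):
            build_index(sp, 0)

    def test_lookup_matches_naive_scan(self, rng):
        seq = "".join(rng.choice(list("ACGTN"), size=1000, p=[0.24, 0.24, 0.24, 0.24, 0.04]))
        sp = spaces_of(seq)["W_CT"]
        conv = sp.sequence("chr1")
        k = 4
        idx = build_index(sp, k)
        for _ in range(50):
            i = int(rng.integers(0, len(conv) - k + 1))
            kmer = conv[i : i + k]
            if "N" in kmer:
                continue
            expected = [
                ("chr1", j)
                for j in range(len(conv) - k + 1)
                if conv[j : j + k] == kmer
            ]
            assert idx.lookup(kmer) == expected

    def test_positions_sorted_per_kmer(self):
        sp = spaces_of("ATATATAT")["W_CT"]
        idx = build_index(sp, 2)
        assert idx.table["AT"] == [("chr1", 0), ("chr1", 2), ("chr1", 4), ("chr1", 6)]

    def test_multi_chromosome_offsets_are_local(self):
        g = make_genome({"a": "TTAA", "b": "AATT"})
        sp = convert_reference(g)[0]
        idx = build_index(sp, 2)
        assert idx.table["AA"] == [("a", 2), ("b", 0)]


def test_reference_set_save_load_roundtrip(tmp_path):
    g = make_genome({"a": "ACGTACGTNACGT", "b": "TTTTCCCC"})
    refset = build_reference(g, 3)
    path = tmp_path / "ref.npz"
    refset.save(path)
    loaded = ReferenceSet.load(path)
    assert loaded.k == 3
    assert loaded.genome.sequences == g.sequences
    assert loaded.spaces["W_CT"].sequences == refset.spaces["W_CT"].sequences
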