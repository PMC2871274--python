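"""Context classification, per-read calling, and aggregation."""
import numpy as np
import pytest

from bsmapper import (
    ContextMap,
    MappedRead,
    aggregate,
    call_read,
    classify_context,
    decode_methylation_string,
    revcomp,
)

from conftest import make_genome


class TestClassifyContext:
    G = make_genome("ACGTACAGTACATT")
    #               12345678901234

    @pytest.mark.parametrize(
        "pos,strand,expected",
        [
            (2, "+", "CG"),   # C followed by G
            (6, "+", "CHG"),  # C,A,G
            (11, "+", "CHH"), # C,A,T
        ],
    )
    def test_plus_strand_examples(self, pos, strand, expected):
        assert classify_context(self.G, "chr1", pos, strand) == expected

    def test_minus_strand(self):
        g = make_genome("ACGT")  # G at pos 3 is a C on Crick, followed by G (comp of C at 2)
        assert classify_context(g, "chr1", 3, "-") == "CG"
        g2 = make_genome("TTCAG")  # Crick C at pos 5 (G); next on Crick = comp(A) -> H; next2 comp(C)=G
        assert classify_context(g2, "chr1", 5, "-") == "CHG"

    def test_chromosome_end_treated_as_h(self):
        g = make_genome("AAC")
        assert classify_context(g, "chr1", 3, "+") == "CHH"

    def test_non_cytosine_raises(self):
        with pytest.raises(ValueError):
            classify_context(self.G, "chr1", 1, "+")
        with pytest.raises(ValueError):
            classify_context(self.G, "chr1", 2, "-")


def test_context_map_agrees_with_scalar(rng):
    seq = "".join(rng.choice(list("ACGT"), size=500))
    g = make_genome(seq)
    ctx = ContextMap(g)
    for strand, base in (("+", "C"), ("-", "G")):
        for i, ch in enumerate(seq):
            if ch == base:
                assert ctx.context("chr1", i + 1, strand) == classify_context(
                    g, "chr1", i + 1, strand
                )


class TestCallRead:
    def _mapped(self, genome, start, form, read_seq, gseq):
        return MappedRead("r1", "chr1", start, form, read_seq, gseq, 0, 0)

    def test_fw_read_states(self):
        # genome CCGA: pos1 C read T -> unmethylated; pos2 C (CG) read C -> methylated
        g = make_genome("CCGA")
        m = self._mapped(g, 1, "+FW", "TCGA", "CCGA")
        calls, s = call_read(m, g)
        assert calls == [
            ("chr1", 1, "+", "CHG", False),  # C,C,G
            ("chr1", 2, "+", "CG", True),
        ]
        assert s == "yX--"

    def test_read_base_other_than_c_t_gives_no_call(self):
        g = make_genome("CAAA")
        m = self._mapped(g, 1, "+FW", "AAAA", "CAAA")
        calls, s = call_read(m, g)
        assert calls == []
        assert s == ".---"

    def test_read_without_genomic_c_empty(self):
        g = make_genome("TTGA")
        m = self._mapped(g, 1, "+FW", "TTGA", "TTGA")
        calls, s = call_read(m, g)
        assert calls == [] and s == "----"

    def test_minus_strand_read_sites_on_crick(self):
        # -FW read over Watson "ACGT": Crick fragment is "ACGT" -> Crick C at
        # Watson pos 3, CG context; read written in Crick orientation.
        g = make_genome("ACGT")
        m = self._mapped(g, 1, "-FW", "ACGT", revcomp("ACGT"))
        calls, s = call_read(m, g)
        assert calls == [("chr1", 3, "-", "CG", True)]

    def test_rc_form_string_in_written_orientation(self):
        # +RC read: written = revcomp of the Watson fragment "CCGA"
        g = make_genome("CCGA")
        read_fw = "TCGA"
        m = self._mapped(g, 1, "+RC", revcomp(read_fw), revcomp("CCGA"))
        calls, s = call_read(m, g)
        assert set(calls) == {
            ("chr1", 1, "+", "CHG", False),
            ("chr1", 2, "+", "CG", True),
        }
        assert s == "yX--"[::-1]

    def test_decode_round_trip(self):
        g = make_genome("CCGA")
        for form, read_seq, gseq in [
            ("+FW", "TCGA", "CCGA"),
            ("+RC", revcomp("TCGA"), revcomp("CCGA")),
        ]:
            m = self._mapped(g, 1, form, read_seq, gseq)
            calls, s = call_read(m, g)
            decoded = decode_methylation_string(s, 1, form)
            assert {(p, st, c, b) for (_, p, st, c, b) in calls} == set(decoded)


class TestAggregate:
    def test_site_counts(self):
        calls = [("chr1", 5, "+", "CG", True)] * 3 + [("chr1", 5, "+", "CG", False)]
        table, summary = aggregate(calls)
        row = table.iloc[0]
        assert (row.n_methylated, row.n_total) == (3, 4)
        assert summary.rate_CG == 75.0

    def test_zero_coverage_context_is_na_not_zero(self):
        _, summary = aggregate([("chr1", 5, "+", "CG", True)])
        assert summary.rate_CHH is None
        assert summary.rate_CHG is None
        assert "NA" in summary.as_text()

    def test_observation_conservation(self):
        calls = [
            ("chr1", 5, "+", "CG", True),
            ("chr1", 5, "+", "CG", False),
            ("chr1", 9, "-", "CHH", False),
        ]
        table, _ = aggregate(calls)
        assert int(table.n_total.sum()) == len(calls)

    def test_opposite_strand_cg_sites_never_merged(self):
        # both cytosines of one CG dinucleotide: Watson C at pos p and
        # Crick C at pos p+1 stay distinct sites
        calls = [("chr1", 5, "+", "CG", True), ("chr1", 6, "-", "CG", False)]
        table, _ = aggregate(calls)
        assert len(table) == 2

    def test_empty_input(self):
        table, summary = aggregate([])
        assert table.empty
        assert summary.rate_CG is None
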