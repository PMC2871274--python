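"""Simulator: methylome drawing, read construction, determinism, evaluator."""
from types import SimpleNamespace

import numpy as np
import pandas as pd
import pytest

from bsmapper import (
    ContextMap,
    SimConfig,
    TagConfig,
    default_error_profile,
    evaluate,
    revcomp,
    simulate_methylome,
    simulate_reads,
    synthetic_genome,
)
from bsmapper.io import write_fastq

from conftest import make_genome


class TestSyntheticGenome:
    def test_deterministic_given_seed(self):
        a = synthetic_genome(5000, seed=3).sequence("chrSim")
        b = synthetic_genome(5000, seed=3).sequence("chrSim")
        c = synthetic_genome(5000, seed=4).sequence("chrSim")
        assert a == b != c

    def test_length_and_alphabet(self):
        g = synthetic_genome(1234, seed=0)
        s = g.sequence("chrSim")
        assert len(s) == 1234 and set(s) <= set("ACGT")

    def test_repeat_copies_present(self):
        from bsmapper import build_index, convert_reference

        g = synthetic_genome(20000, seed=1, repeat_fraction=0.5, divergence=0.0,
                             repeat_length=(500, 1000))
        idx = build_index(convert_reference(g)[0], 20)
        multi = sum(1 for v in idx.table.values() if len(v) > 1)
        assert multi > 100  # exact copies leave many duplicated 20-mers


class TestSimulateMethylome:
    G = synthetic_genome(30000, seed=5, repeat_fraction=0.0)

    def test_all_zero_probabilities(self):
        m = simulate_methylome(self.G, 0, 0, 0, seed=1)
        for strand in "+-":
            st = m["chrSim"][strand]
            assert not (st == 1).any()
            assert (st >= 0).any()

    def test_p_cg_one_methylates_every_cg(self):
        m = simulate_methylome(self.G, 1.0, 0.0, 0.0, seed=1)
        ctx = ContextMap(self.G)
        for strand in "+-":
            codes = ctx.codes("chrSim", strand)
            st = m["chrSim"][strand]
            assert (st[codes == 0] == 1).all()
            assert (st[codes == 1] == 0).all()
            assert (st[codes == 2] == 0).all()

    def test_half_probability_within_three_se(self):
        m = simulate_methylome(self.G, 0.5, 0.0, 0.0, seed=2)
        ctx = ContextMap(self.G)
        meth = tot = 0
        for strand in "+-":
            codes = ctx.codes("chrSim", strand)
            st = m["chrSim"][strand]
            meth += int((st[codes == 0] == 1).sum())
            tot += int((codes == 0).sum())
        assert tot > 1000
        se = np.sqrt(0.25 / tot)
        assert abs(meth / tot - 0.5) <= 3 * se

    def test_deterministic(self):
        a = simulate_methylome(self.G, 0.3, 0.1, 0.05, seed=9)
        b = simulate_methylome(self.G, 0.3, 0.1, 0.05, seed=9)
        for strand in "+-":
            assert (a["chrSim"][strand] == b["chrSim"][strand]).all()


class TestSimulateReads:
    # 5-bp genome AACGT: one possible fragment per strand, so each form's
    # read is predictable. Watson C (pos 3) is CG context; the Crick C
    # (pos 4, over Watson G) is CG on Crick.
    G = make_genome({"chr1": "AACGT"})

    def _run(self, protocol, p_cg, read_len, n=400, seed=0):
        m = simulate_methylome(self.G, p_cg, 0.0, 0.0, seed=seed)
        cfg = SimConfig(n_reads=n, read_len=read_len, protocol=protocol,
                        p_CG=p_cg, rng_seed=seed + 1)
        return simulate_reads(self.G, m, cfg)

    def test_lister_forms_fully_converted(self):
        records, truth = self._run("lister", p_cg=0.0, read_len=5)
        expected = {"+FW": "AATGT", "-FW": "ATGTT"}  # crick=ACGTT -> ATGTT
        assert set(truth.form) == {"+FW", "-FW"}
        for (rid, seq, _q), form in zip(records, truth.form):
            assert seq == expected[form]

    def test_methylated_cg_left_unconverted(self):
        records, truth = self._run("lister", p_cg=1.0, read_len=5)
        expected = {"+FW": "AACGT", "-FW": "ACGTT"}
        for (rid, seq, _q), form in zip(records, truth.form):
            assert seq == expected[form]

    def test_cokus_four_forms_with_tags(self):
        records, truth = self._run("cokus", p_cg=0.0, read_len=10)
        core = {"+FW": "AATGT", "-FW": "ATGTT",
                "+RC": revcomp("AATGT"), "-RC": revcomp("ATGTT")}
        tags = TagConfig()
        assert set(truth.form) == set(core)
        for (rid, seq, _q), form in zip(records, truth.form):
            tag, rest = seq[:5], seq[5:]
            assert rest == core[form]
            pats = tags.fw_patterns if form.endswith("FW") else tags.rc_patterns
            assert tag in pats

    def test_truth_start_and_meth_states(self):
        _, truth = self._run("lister", p_cg=1.0, read_len=5)
        assert (truth.start == 1).all()
        assert (truth.meth_states == "1").all()  # one covered C per strand

    def test_same_seed_byte_identical_output(self, tmp_path):
        g = synthetic_genome(3000, seed=6, repeat_fraction=0.0)
        m = simulate_methylome(g, 0.7, 0.0, 0.0, seed=1)
        cfg = dict(n_reads=200, read_len=36, protocol="cokus", p_CG=0.7,
                   error_profile=default_error_profile(36), rng_seed=4)
        ra, ta = simulate_reads(g, m, SimConfig(**cfg))
        rb, tb = simulate_reads(g, m, SimConfig(**cfg))
        pa, pb = tmp_path / "a.fq", tmp_path / "b.fq"
        write_fastq(ra, pa)
        write_fastq(rb, pb)
        assert pa.read_bytes() == pb.read_bytes()
        assert ta.equals(tb)
        rc, _ = simulate_reads(g, m, SimConfig(**{**cfg, "rng_seed": 5}))
        assert [x[1] for x in rc] != [x[1] for x in ra]

    def test_error_profile_injects_recorded_errors(self):
        g = synthetic_genome(3000, seed=6, repeat_fraction=0.0)
        m = simulate_methylome(g, 0.0, 0.0, 0.0, seed=1)
        cfg = SimConfig(n_reads=100, read_len=36, protocol="lister",
                        error_profile=np.full(36, 0.5), rng_seed=2)
        _, truth = simulate_reads(g, m, cfg)
        assert truth.n_errors.sum() > 100
        cfg0 = SimConfig(n_reads=100, read_len=36, protocol="lister", rng_seed=2)
        _, truth0 = simulate_reads(g, m, cfg0)
        assert (truth0.n_errors == 0).all()

    def test_fragment_longer_than_chromosome_rejected(self):
        m = simulate_methylome(self.G, 0, 0, 0, seed=1)
        with pytest.raises(ValueError):
            simulate_reads(self.G, m, SimConfig(n_reads=1, read_len=6, protocol="lister"))


class TestSimConfigValidation:
    def test_probability_out_of_range(self):
        with pytest.raises(ValueError):
            SimConfig(n_reads=1, p_CG=1.5)

    def test_error_profile_length_checked(self):
        with pytest.raises(ValueError):
            SimConfig(n_reads=1, read_len=36, error_profile=np.zeros(10))


class TestEvaluate:
    TRUTH = pd.DataFrame(
        [("r1", "chr1", 10, "+FW", 0, ""), ("r2", "chr1", 20, "-FW", 0, "")],
        columns=["read_id", "chrom", "start", "form", "n_errors", "meth_states"],
    )

    def _result(self, mapped):
        return SimpleNamespace(mapped=mapped, calls=[], n_reads=2)

    def test_perfect_run(self):
        mapped = [SimpleNamespace(read_id="r1", chrom="chr1", start=10, form="+FW")]
        m = evaluate(self._result(mapped), self.TRUTH)
        assert m.accuracy == 100.0 and m.pct_unique == 50.0

    def test_wrong_position_counted_incorrect(self):
        mapped = [SimpleNamespace(read_id="r1", chrom="chr1", start=11, form="+FW")]
        assert evaluate(self._result(mapped), self.TRUTH).accuracy == 0.0

    def test_zero_unique_reads_accuracy_na(self):
        m = evaluate(self._result([]), self.TRUTH)
        assert m.accuracy is None and m.n_unique == 0
        assert "NA" in m.as_text()

    def test_unknown_read_id_errors(self):
        mapped = [SimpleNamespace(read_id="rX", chrom="chr1", start=1, form="+FW")]
        with pytest.raises(KeyError):
            evaluate(self._result(mapped), self.TRUTH)
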