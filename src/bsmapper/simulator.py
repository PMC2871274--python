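"""Bisulfite-read simulation with ground truth, and the matching evaluator.

The simulator emulates a whole-genome bisulfite sequencing experiment at
the read level:

1. every genomic cytosine (on each strand independently) is assigned a
   methylation state with its context's probability (p_CG, p_CHG, p_CHH);
2. read origins are sampled uniformly over (chromosome, strand, start)
   with replacement — reads are the fragments, there is no fragment-length
   model;
3. the bisulfite rule is applied on the origin strand (unmethylated
   C -> T, methylated C unchanged);
4. the read form is drawn uniformly over the protocol's allowed forms
   (non-directional: +FW/+RC/-FW/-RC; directional: +FW/-FW); RC forms
   emit the reverse complement of the converted fragment; non-directional
   reads are prefixed with the form-appropriate 5-nt tag pattern
   (N wildcards sampled uniformly), so the emitted read length includes
   the tag;
5. per-cycle substitution errors are applied last, each substituting one
   of the three other bases uniformly.

Everything is deterministic given the seed; identical seeds give
byte-identical FASTQ and truth outputs.

``synthetic_genome`` additionally generates a test genome with diverged
repeat copies, emulating the repeat structure of real chromosomes that
drives non-unique and (under sequencing errors) incorrectly placed
reads.

The evaluator scores a mapping run against the simulator truth:
mapability (percent of reads surviving the uniqueness and quality
filters), accuracy (fraction of uniquely mapped reads whose reported
(chromosome, position, form) equals the true origin), and the inferred
context-wise methylation rates.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._dna import decode, revcomp, revcomp_arr, T, encode
from .methcall import ContextMap, RateSummary, aggregate
from .readprep import TagConfig
from .refprep import Genome

COKUS_FORMS = ("+FW", "+RC", "-FW", "-RC")
LISTER_FORMS = ("+FW", "-FW")


def synthetic_genome(
    length: int,
    seed: int,
    gc: float = 0.42,
    repeat_fraction: float = 0.15,
    repeat_length: tuple[int, int] = (300, 3000),
    divergence: float = 0.02,
    name: str = "chrSim",
) -> Genome:
    """Random test genome with diverged repeat copies.

    A uniform-composition backbone (GC content ``gc``) is overwritten
    with copies of its own segments until ``repeat_fraction`` of the
    genome consists of copied material; each copy carries independent
    substitutions at rate ``divergence``. With ``repeat_fraction=0`` the
    genome is plain i.i.d. sequence.
    """
    rng = np.random.default_rng(seed)
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    arr = rng.choice(4, size=length, p=p).astype(np.uint8)
    copied = 0
    target = repeat_fraction * length
    lo, hi = repeat_length
    while copied < target:
        seg_len = int(rng.integers(lo, hi + 1))
        seg_len = min(seg_len, length // 2)
        src = int(rng.integers(0, length - seg_len + 1))
        dst = int(rng.integers(0, length - seg_len + 1))
        if abs(src - dst) < seg_len:
            continue
        seg = arr[src : src + seg_len].copy()
        mut = np.nonzero(rng.random(seg_len) < divergence)[0]
        if mut.size:
            seg[mut] = (seg[mut] + rng.integers(1, 4, mut.size).astype(np.uint8)) % 4
        arr[dst : dst + seg_len] = seg
        copied += seg_len
    return Genome.from_sequences({name: decode(arr)})


@dataclass
class SimConfig:
    """Study conditions for one simulated library.

    ``read_len`` is the emitted read length; for the non-directional
    protocol it includes the 5-nt tag, so the genomic fragment is
    ``read_len - tag_length`` bp (36-mer reads carry 31 genomic bases,
    matching tagged-library sequencing). ``error_profile`` is a
    per-cycle substitution probability vector of length ``read_len``;
    None means error-free.
    """

    n_reads: int
    read_len: int = 36
    protocol: str = "lister"
    p_CG: float = 0.72
    p_CHG: float = 0.0
    p_CHH: float = 0.0
    error_profile: np.ndarray | None = None
    rng_seed: int = 0
    tag_config: TagConfig = field(default_factory=TagConfig)

    def __post_init__(self):
        for name in ("p_CG", "p_CHG", "p_CHH"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.protocol not in ("cokus", "lister"):
            raise ValueError(f"unknown protocol {self.protocol!r}")
        if self.error_profile is not None:
            prof = np.asarray(self.error_profile, dtype=float)
            if prof.size != self.read_len:
                raise ValueError(
                    f"error profile length {prof.size} != read length {self.read_len}"
                )
            if (prof < 0).any() or (prof > 1).any():
                raise ValueError("error profile entries must lie in [0, 1]")
            self.error_profile = prof

    @property
    def forms(self) -> tuple[str, ...]:
        return COKUS_FORMS if self.protocol == "cokus" else LISTER_FORMS

    @property
    def fragment_len(self) -> int:
        if self.protocol == "cokus":
            return self.read_len - self.tag_config.tag_length
        return self.read_len


def default_error_profile(read_len: int, start: float = 0.002, end: float = 0.02) -> np.ndarray:
    """Per-cycle substitution probabilities rising linearly with cycle
    number, the characteristic shape of sequencer base-calling error."""
    return np.linspace(start, end, read_len)


def simulate_methylome(
    genome: Genome, p_CG: float, p_CHG: float, p_CHH: float, seed: int
) -> dict[str, dict[str, np.ndarray]]:
    """Draw a methylation state for every genomic C on both strands.

    Returns per chromosome, per strand ('+'/'-') an int8 array indexed
    by Watson position: -1 = not a C on that strand, 0 = unmethylated,
    1 = methylated. Each C is methylated independently with its
    context's probability; deterministic given the seed.
    """
    rng = np.random.default_rng(seed)
    ctx = ContextMap(genome)
    probs = (p_CG, p_CHG, p_CHH)
    out: dict[str, dict[str, np.ndarray]] = {}
    for name in genome.names:
        out[name] = {}
        for strand in "+-":
            codes = ctx.codes(name, strand)
            state = np.full(codes.size, -1, np.int8)
            for code, p in enumerate(probs):
                mask = codes == code
                n = int(mask.sum())
                if n:
                    state[mask] = (rng.random(n) < p).astype(np.int8)
            out[name][strand] = state
    return out


def _converted_strands(genome: Genome, methylome) -> dict[str, tuple[str, str]]:
    """Bisulfite-converted Watson and Crick strand strings per chromosome.

    The Crick string is in Crick 5'->3' orientation (index j maps to
    Watson position L-1-j).
    """
    out = {}
    for name in genome.names:
        warr = genome.array(name).copy()
        wst = methylome[name]["+"]
        warr[wst == 0] = T  # unmethylated C -> T
        carr = revcomp_arr(genome.array(name))
        cst = methylome[name]["-"][::-1]  # Crick orientation
        carr[cst == 0] = T
        out[name] = (decode(warr), decode(carr))
    return out


def simulate_reads(genome: Genome, methylome, cfg: SimConfig):
    """Generate reads and the ground-truth table.

    Returns ``(records, truth)``: records is a list of
    ``(read_id, seq, qual)`` FASTQ tuples, truth a DataFrame with
    columns read_id, chrom, start (1-based Watson of the genomic
    fragment), form, n_errors, meth_states (per-covered-C 0/1 string in
    origin-strand 5'->3' order).
    """
    flen = cfg.fragment_len
    if flen < 1:
        raise ValueError("fragment length must be positive")
    lengths = genome.lengths
    for name, L in lengths.items():
        if L < flen:
            raise ValueError(
                f"chromosome {name} ({L} bp) shorter than the fragment length {flen}"
            )
    rng = np.random.default_rng(cfg.rng_seed)
    strands = _converted_strands(genome, methylome)
    names = list(genome.names)
    weights = np.array([lengths[n] - flen + 1 for n in names], dtype=float)
    weights /= weights.sum()
    chrom_idx = rng.choice(len(names), size=cfg.n_reads, p=weights)
    forms = cfg.forms
    form_idx = rng.integers(0, len(forms), size=cfg.n_reads)
    prof = cfg.error_profile
    tagcfg = cfg.tag_config
    qual = "I" * cfg.read_len
    records = []
    truth_rows = []
    for i in range(cfg.n_reads):
        name = names[int(chrom_idx[i])]
        L = lengths[name]
        form = forms[int(form_idx[i])]
        s = int(rng.integers(0, L - flen + 1))
        watson_bs, crick_bs = strands[name]
        if form.startswith("+"):
            frag = watson_bs[s : s + flen]
            states = methylome[name]["+"][s : s + flen]
            meth_states = states[states >= 0]
        else:
            frag = crick_bs[L - s - flen : L - s]
            states = methylome[name]["-"][s : s + flen][::-1]
            meth_states = states[states >= 0]
        core = frag if form.endswith("FW") else revcomp(frag)
        if cfg.protocol == "cokus":
            pats = tagcfg.fw_patterns if form.endswith("FW") else tagcfg.rc_patterns
            pat = pats[int(rng.integers(0, len(pats)))]
            if "N" in pat:
                pat = "".join(
                    "ACGT"[int(rng.integers(0, 4))] if c == "N" else c for c in pat
                )
            seq = pat + core
        else:
            seq = core
        n_errors = 0
        if prof is not None:
            u = rng.random(cfg.read_len)
            hit = np.nonzero(u < prof)[0]
            if hit.size:
                arr = encode(seq)
                shifts = rng.integers(1, 4, hit.size).astype(np.uint8)
                arr[hit] = (arr[hit] + shifts) % 4
                seq = decode(arr)
                n_errors = int(hit.size)
        read_id = f"sim{i:06d}"
        records.append((read_id, seq, qual))
        truth_rows.append(
            (read_id, name, s + 1, form, n_errors,
             "".join(str(int(x)) for x in meth_states))
        )
    truth = pd.DataFrame(
        truth_rows,
        columns=["read_id", "chrom", "start", "form", "n_errors", "meth_states"],
    )
    return records, truth


@dataclass
class SimMetrics:
    """Evaluation of a mapping run against simulator ground truth."""

    n_reads: int
    n_unique: int
    n_correct: int
    pct_unique: float
    accuracy: float | None  # None (NA) when no read mapped uniquely
    rates: RateSummary
    site_table: pd.DataFrame

    def as_text(self) -> str:
        acc = "NA" if self.accuracy is None else f"{self.accuracy:.4f}"
        return (
            f"total_reads\t{self.n_reads}\n"
            f"uniquely_mapped\t{self.n_unique}\n"
            f"pct_unique\t{self.pct_unique:.4f}\n"
            f"correctly_mapped\t{self.n_correct}\n"
            f"accuracy_percent\t{acc}\n" + self.rates.as_text()
        )


def evaluate(result, truth: pd.DataFrame) -> SimMetrics:
    """Score a :class:`~bsmapper.pipeline.MappingResult` against truth.

    A mapped read is correct iff its (chrom, start, form) equals the
    simulator's record. Every mapped read must be present in the truth
    table; accuracy is NA (None), never 0, when nothing mapped uniquely.
    """
    by_id = {
        r.read_id: (r.chrom, int(r.start), r.form)
        for r in truth.itertuples(index=False)
    }
    n_reads = len(truth)
    n_unique = len(result.mapped)
    n_correct = 0
    for m in result.mapped:
        if m.read_id not in by_id:
            raise KeyError(f"mapped read {m.read_id!r} absent from the truth table")
        if (m.chrom, m.start, m.form) == by_id[m.read_id]:
            n_correct += 1
    pct_unique = 100.0 * n_unique / n_reads if n_reads else 0.0
    accuracy = 100.0 * n_correct / n_unique if n_unique else None
    site_table, rates = aggregate(result.calls)
    return SimMetrics(
        n_reads=n_reads,
        n_unique=n_unique,
        n_correct=n_correct,
        pct_unique=pct_unique,
        accuracy=accuracy,
        rates=rates,
        site_table=site_table,
    )
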