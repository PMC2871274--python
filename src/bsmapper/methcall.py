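"""Per-cytosine methylation calling and context-wise aggregation.

Bisulfite treatment converts unmethylated cytosines to thymine while
methylated cytosines stay cytosine, so for every read position whose
origin-strand genome base is C the read base encodes methylation state:
C = methylated, T = unmethylated, anything else (a sequencing error) is
excluded from the counts. Context (CG, CHG, CHH with H in {A,C,T}) is
assigned from the reference genome on the cytosine's strand — never
from the read, so sequencing errors cannot shift a site's context.

Sites are reported in 1-based Watson coordinates with the strand the C
resides on; the two cytosines of a CG dinucleotide are two distinct
sites and are never merged. Genome-wide rates are pooled over
observations (weighted by coverage), not averaged over sites.

Per-read states are serialised into a ``methylation_string`` with one
character per written read base:

    ``X``/``x``  methylated / unmethylated C in CG context
    ``Y``/``y``  methylated / unmethylated C in CHG context
    ``Z``/``z``  methylated / unmethylated C in CHH context
    ``.``        genomic C with an uncallable read base
    ``-``        origin-strand genome base is not a C
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._dna import C, G, T, encode, revcomp_arr
from .postprocess import MappedRead
from .refprep import Genome

CONTEXTS = ("CG", "CHG", "CHH")
_CTX_CHARS = {0: "Xx", 1: "Yy", 2: "Zz"}
_CHAR_TO_CTX = {
    "X": ("CG", True), "x": ("CG", False),
    "Y": ("CHG", True), "y": ("CHG", False),
    "Z": ("CHH", True), "z": ("CHH", False),
}


def classify_context(genome: Genome, chrom: str, pos: int, strand: str) -> str:
    """Context of the cytosine at 1-based Watson position ``pos``.

    On the C's strand: next base G gives CG, else next-next base G gives
    CHG, else CHH. Positions running off the chromosome end treat the
    missing base as H. Raises ValueError if the base there is not a C on
    the requested strand.
    """
    arr = genome.array(chrom)
    i = pos - 1
    if not 0 <= i < arr.size:
        raise ValueError(f"position {pos} outside {chrom}")
    if strand == "+":
        if arr[i] != C:
            raise ValueError(f"{chrom}:{pos}(+) is not a cytosine")
        if i + 1 < arr.size and arr[i + 1] == G:
            return "CG"
        if i + 2 < arr.size and arr[i + 2] == G:
            return "CHG"
        return "CHH"
    if strand == "-":
        # C on the Crick strand appears as G on Watson; the next base in
        # Crick 5'->3' direction is the complement of Watson[i-1].
        if arr[i] != G:
            raise ValueError(f"{chrom}:{pos}(-) is not a cytosine")
        if i - 1 >= 0 and arr[i - 1] == C:
            return "CG"
        if i - 2 >= 0 and arr[i - 2] == C:
            return "CHG"
        return "CHH"
    raise ValueError(f"strand must be '+' or '-', got {strand!r}")


class ContextMap:
    """Vectorised per-chromosome context codes (0=CG, 1=CHG, 2=CHH,
    -1 = not a cytosine on that strand), indexed by Watson position.

    Agrees with :func:`classify_context` everywhere; built once per
    genome for the hot calling path.
    """

    def __init__(self, genome: Genome):
        self.genome = genome
        self._plus: dict[str, np.ndarray] = {}
        self._minus: dict[str, np.ndarray] = {}
        for name in genome.names:
            arr = genome.array(name)
            L = arr.size
            plus = np.full(L, -1, np.int8)
            is_c = arr == C
            nxt_g = np.zeros(L, bool)
            nxt_g[: L - 1] = arr[1:] == G
            nxt2_g = np.zeros(L, bool)
            nxt2_g[: L - 2] = arr[2:] == G
            plus[is_c & nxt_g] = 0
            plus[is_c & ~nxt_g & nxt2_g] = 1
            plus[is_c & ~nxt_g & ~nxt2_g] = 2
            minus = np.full(L, -1, np.int8)
            is_g = arr == G
            prv_c = np.zeros(L, bool)
            prv_c[1:] = arr[:-1] == C
            prv2_c = np.zeros(L, bool)
            prv2_c[2:] = arr[:-2] == C
            minus[is_g & prv_c] = 0
            minus[is_g & ~prv_c & prv2_c] = 1
            minus[is_g & ~prv_c & ~prv2_c] = 2
            self._plus[name] = plus
            self._minus[name] = minus

    def codes(self, chrom: str, strand: str) -> np.ndarray:
        return (self._plus if strand == "+" else self._minus)[chrom]

    def context(self, chrom: str, pos: int, strand: str) -> str:
        code = int(self.codes(chrom, strand)[pos - 1])
        if code < 0:
            raise ValueError(f"{chrom}:{pos}({strand}) is not a cytosine")
        return CONTEXTS[code]


def call_read(mapped: MappedRead, genome: Genome, ctx_map: ContextMap | None = None):
    """Methylation calls for one uniquely mapped read.

    Returns ``(calls, methylation_string)`` where each call is a tuple
    ``(chrom, pos_1based, strand, context, methylated)`` and the string
    is per written read base (encoding in the module docstring).
    """
    n = len(mapped.read_seq)
    rc_form = mapped.form.endswith("RC")
    if rc_form:
        read_fw = revcomp_arr(encode(mapped.read_seq))
        gseq_fw = revcomp_arr(encode(mapped.genome_seq))
    else:
        read_fw = encode(mapped.read_seq)
        gseq_fw = encode(mapped.genome_seq)
    plus_origin = mapped.form.startswith("+")
    strand = "+" if plus_origin else "-"
    start0 = mapped.start - 1
    codes = ctx_map.codes(mapped.chrom, strand) if ctx_map is not None else None

    chars = ["-"] * n
    calls = []
    for i in np.nonzero(gseq_fw == C)[0]:
        i = int(i)
        pos0 = start0 + i if plus_origin else start0 + n - 1 - i
        pos1 = pos0 + 1
        if codes is not None:
            ctx_code = int(codes[pos0])
            context = CONTEXTS[ctx_code]
        else:
            context = classify_context(genome, mapped.chrom, pos1, strand)
            ctx_code = CONTEXTS.index(context)
        rb = int(read_fw[i])
        if rb == C:
            state = True
        elif rb == T:
            state = False
        else:
            chars[i] = "."
            continue
        chars[i] = _CTX_CHARS[ctx_code][0 if state else 1]
        calls.append((mapped.chrom, pos1, strand, context, state))
    if rc_form:
        chars.reverse()  # back to written orientation
    return calls, "".join(chars)


def decode_methylation_string(
    meth_string: str, start: int, form: str
) -> list[tuple[int, str, str, bool]]:
    """Recover ``(pos_1based, strand, context, methylated)`` calls from a
    mapping-table row without the genome (the string is context-encoded)."""
    n = len(meth_string)
    start0 = start - 1
    strand = "+" if form.startswith("+") else "-"
    # written index j maps to Watson position depending on orientation
    left_anchored = form in ("+FW", "-RC")
    out = []
    for j, ch in enumerate(meth_string):
        if ch not in _CHAR_TO_CTX:
            continue
        context, state = _CHAR_TO_CTX[ch]
        pos0 = start0 + j if left_anchored else start0 + n - 1 - j
        out.append((pos0 + 1, strand, context, state))
    return out


def calls_from_mapping(df) -> list[tuple[str, int, str, str, bool]]:
    """Reconstruct the call stream from a mapping table (DataFrame with
    strand_code, chrom, start and methylation_string columns)."""
    from .postprocess import FORM_FROM_CODE

    calls = []
    for row in df.itertuples(index=False):
        form = FORM_FROM_CODE[row.strand_code]
        for pos, strand, context, state in decode_methylation_string(
            row.methylation_string, int(row.start), form
        ):
            calls.append((row.chrom, pos, strand, context, state))
    return calls


@dataclass
class RateSummary:
    """Genome-wide pooled methylation rates per context, in percent.

    A context with zero coverage is reported as None (NA), never 0.
    """

    rate_CG: float | None
    rate_CHG: float | None
    rate_CHH: float | None
    counts: dict[str, tuple[int, int]]  # context -> (n_methylated, n_total)

    def rate(self, context: str) -> float | None:
        return getattr(self, f"rate_{context}")

    def as_text(self) -> str:
        lines = []
        for ctx in CONTEXTS:
            r = self.rate(ctx)
            meth, tot = self.counts[ctx]
            val = "NA" if r is None else f"{r:.4f}"
            lines.append(f"rate_{ctx}_percent\t{val}\t(methylated {meth} / {tot})")
        return "\n".join(lines) + "\n"


def aggregate(calls) -> tuple[pd.DataFrame, RateSummary]:
    """Sum calls per (chrom, pos, strand) and pool genome-wide rates.

    ``calls`` is an iterable of ``(chrom, pos, strand, context,
    methylated)`` tuples from uniquely mapped, quality-passed reads.
    """
    cols = ["chrom", "pos", "strand", "context", "methylated"]
    df = pd.DataFrame(list(calls), columns=cols)
    if df.empty:
        table = pd.DataFrame(
            columns=["chrom", "pos", "strand", "context", "n_methylated", "n_total"]
        )
    else:
        table = (
            df.groupby(["chrom", "pos", "strand", "context"], as_index=False)
            .agg(n_methylated=("methylated", "sum"), n_total=("methylated", "size"))
            .sort_values(["chrom", "pos", "strand"], kind="mergesort")
            .reset_index(drop=True)
        )
        table["n_methylated"] = table["n_methylated"].astype(int)
        table["n_total"] = table["n_total"].astype(int)
    counts = {}
    rates = {}
    for ctx in CONTEXTS:
        sub = table[table["context"] == ctx] if not table.empty else table
        tot = int(sub["n_total"].sum()) if not table.empty else 0
        meth = int(sub["n_methylated"].sum()) if not table.empty else 0
        counts[ctx] = (meth, tot)
        rates[ctx] = (100.0 * meth / tot) if tot > 0 else None
    summary = RateSummary(
        rate_CG=rates["CG"], rate_CHG=rates["CHG"], rate_CHH=rates["CHH"], counts=counts
    )
    return table, summary
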