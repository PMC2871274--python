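"""Post-processing of alignment hits: uniqueness, coordinates, mismatches.

A read's hits from all logical reference spaces are pooled. The read is
kept only if it is *unique*: no other hit has the same or fewer
mismatches in the 3-letter alignment. Ties at the best mismatch count
are discarded as ambiguous, never randomly assigned — random assignment
of non-unique reads lowers accuracy and biases methylation estimates.

The surviving hit is transformed to Watson-strand coordinates with its
read-form label, and mismatches are recounted in the original alphabet
under the asymmetric bisulfite rule: for FW forms a read T over a
genomic C is a match (bisulfite conversion) while a read C over a
genomic T is a mismatch; for RC forms the rule is read A over genomic G
matches, read G over genomic A does not. Alignments whose recounted
mismatch count exceeds the user threshold are discarded as low quality.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._dna import A, C, G, N, T, encode, revcomp
from .aligner import AlignmentHit
from .refprep import SPACE_TRANSFORM, Genome

#: read form -> two-character display code: first char is the origin
#: strand (+ Watson / - Crick), second is + for FW, - for RC.
STRAND_CODE = {"+FW": "++", "+RC": "+-", "-FW": "-+", "-RC": "--"}
FORM_FROM_CODE = {v: k for k, v in STRAND_CODE.items()}

UNMAPPED_REASONS = ("no_hit", "ambiguous", "low_quality", "too_short")


@dataclass
class MappedRead:
    """Final unique placement of a read in Watson coordinates.

    ``start`` is the 1-based Watson coordinate of the read's leftmost
    Watson-coordinate base regardless of form; orientation is carried by
    ``form``/``strand_code``. ``genome_seq`` is the original-alphabet
    reference segment in the orientation of the read's written sequence.
    """

    read_id: str
    chrom: str
    start: int
    form: str
    read_seq: str
    genome_seq: str
    mismatches_orig: int
    mismatches3: int
    methylation_string: str = ""

    @property
    def strand_code(self) -> str:
        return STRAND_CODE[self.form]


def merge_hits(hit_lists) -> list[AlignmentHit]:
    """Pool one read's hits from all logical spaces, dropping duplicate
    (space, chrom, offset) entries while preserving order."""
    seen = {}
    for hits in hit_lists:
        for h in hits:
            key = (h.space_id, h.chrom, h.offset)
            if key not in seen:
                seen[key] = h
    return list(seen.values())


def uniqueness_filter(hits: list[AlignmentHit]):
    """Apply the uniqueness rule to a merged hit list.

    Returns ``(hit, None)`` when exactly one hit attains the minimum
    3-letter mismatch count, else ``(None, reason)`` with reason
    ``"no_hit"`` or ``"ambiguous"``. A strictly worse hit does not break
    uniqueness.
    """
    if not hits:
        return None, "no_hit"
    best = min(h.mismatches3 for h in hits)
    winners = [h for h in hits if h.mismatches3 == best]
    if len(winners) > 1:
        return None, "ambiguous"
    return winners[0], None


def to_watson(hit: AlignmentHit, genome: Genome, read_len: int):
    """Transform a space hit to Watson coordinates.

    Returns ``(chrom, start_1based, form, genome_seq)`` where
    ``genome_seq`` is oriented to match the read's written sequence:
    the Watson segment for +FW/-RC, its reverse complement for -FW/+RC.
    """
    form, flip = SPACE_TRANSFORM[hit.space_id]
    L = genome.lengths[hit.chrom]
    start0 = L - hit.offset - read_len if flip else hit.offset
    # Out-of-bounds here means a coordinate-transform invariant was broken
    # upstream; never clip.
    assert 0 <= start0 and start0 + read_len <= L, (
        f"transformed coordinates out of bounds: {hit} -> start0={start0}"
    )
    seg = genome.sequence_slice(hit.chrom, start0, start0 + read_len)
    genome_seq = seg if form in ("+FW", "-RC") else revcomp(seg)
    return hit.chrom, start0 + 1, form, genome_seq


def recount_mismatches(read_orig: str, genome_seq: str, form: str) -> int:
    """Original-alphabet mismatch count under the asymmetric bisulfite rule.

    FW forms: match iff equal, or read T over genomic C.
    RC forms: match iff equal, or read A over genomic G.
    A read N always counts as a mismatch.
    """
    if len(read_orig) != len(genome_seq):
        raise ValueError(
            f"length mismatch: read {len(read_orig)} vs genome {len(genome_seq)}"
        )
    if form not in STRAND_CODE:
        raise ValueError(f"unknown read form {form!r}")
    r = encode(read_orig)
    g = encode(genome_seq)
    match = (r == g) & (r != N)
    if form.endswith("RC"):
        match |= (r == A) & (g == G)
    else:
        match |= (r == T) & (g == C)
    return int(r.size - np.count_nonzero(match))


def quality_filter(mismatches_orig: int, max_mm: int) -> bool:
    """Keep iff the recounted mismatch count does not exceed the
    user-defined maximum (discard only when strictly larger)."""
    return mismatches_orig <= max_mm
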