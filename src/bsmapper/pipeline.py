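"""Pipeline driver: wire read preparation, alignment and post-processing.

One logical *alignment pass* is a (converted read form, logical
reference space) combination. The directional protocol needs two passes
(C/T-converted reads against W_CT and C_CT); the non-directional
protocol needs four, with the two G/A passes executed against the C/T
indexes by aligning the G/A-converted read as its reverse complement
and transforming offsets — the reverse-complement identity between the
spaces makes the results provably identical.
"""
from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field, replace

import pandas as pd

from ._dna import ct_convert, ga_convert, revcomp
from .aligner import AlignmentHit, align_read
from .methcall import ContextMap, aggregate, call_read
from .postprocess import (
    MappedRead,
    merge_hits,
    quality_filter,
    recount_mismatches,
    to_watson,
    uniqueness_filter,
)
from .readprep import (
    DEFAULT_MIN_ALIGNABLE,
    BSRead,
    ReadTooShortError,
    TagConfig,
    classify_tag,
)
from .refprep import Genome, ReferenceSet, build_reference

logger = logging.getLogger(__name__)

DEFAULT_HIT_CAP = 500


@dataclass(frozen=True)
class MapParams:
    """Mapping parameters.

    ``m3`` is the mismatch ceiling of the 3-letter alignment phase;
    ``max_mm`` the independent original-alphabet ceiling applied after
    recounting. ``seed_len`` is an upper bound on the seed k-mer length;
    the effective k is reduced so that m3+1 non-overlapping seeds fit in
    the shortest read (pigeonhole completeness).
    """

    protocol: str = "lister"
    m3: int = 3
    max_mm: int = 2
    seed_len: int = 12
    min_alignable: int = DEFAULT_MIN_ALIGNABLE
    hit_cap: int = DEFAULT_HIT_CAP
    tag_config: TagConfig = field(default_factory=TagConfig)

    def effective_k(self, min_read_len: int) -> int:
        return max(1, min(self.seed_len, min_read_len // (self.m3 + 1)))


def logical_spaces_for(tag_class: str, protocol: str) -> tuple[str, ...]:
    """Logical reference spaces searched for a read of the given tag class.

    Directional-protocol reads are always FW. Untagged (UNKNOWN) reads
    under the non-directional protocol are treated as if they could be
    both FW and RC, i.e. searched in all four spaces.
    """
    if protocol == "lister" or tag_class == "FW":
        return ("W_CT", "C_CT")
    if tag_class == "RC":
        return ("RCW_GA", "RCC_GA")
    return ("W_CT", "C_CT", "RCW_GA", "RCC_GA")


@dataclass
class MappingResult:
    """Outcome of a mapping run: placements, calls, and an audit trail."""

    mapped: list[MappedRead]
    calls: list
    n_reads: int
    discards: Counter
    n_passes: int
    params: MapParams
    k: int
    unmapped: list[tuple[str, str]] = field(default_factory=list)

    @property
    def pct_unique(self) -> float:
        return 100.0 * len(self.mapped) / self.n_reads if self.n_reads else 0.0

    def to_dataframe(self) -> pd.DataFrame:
        rows = [
            (m.read_id, m.strand_code, m.chrom, m.start, m.read_seq,
             m.genome_seq, m.mismatches_orig, m.methylation_string)
            for m in self.mapped
        ]
        return pd.DataFrame(
            rows,
            columns=["read_id", "strand_code", "chrom", "start", "read_seq",
                     "genome_seq", "mismatches_orig", "methylation_string"],
        )

    def report(self) -> str:
        lines = [
            f"total_reads\t{self.n_reads}",
            f"uniquely_mapped\t{len(self.mapped)}",
            f"pct_unique\t{self.pct_unique:.4f}",
            f"alignment_passes\t{self.n_passes}",
        ]
        for reason in ("no_hit", "ambiguous", "low_quality", "too_short"):
            lines.append(f"discarded_{reason}\t{self.discards.get(reason, 0)}")
        return "\n".join(lines) + "\n"


def prepare_read(raw: BSRead, params: MapParams):
    """Protocol-aware read preparation; returns (read, None) or (None, reason)."""
    if params.protocol == "lister":
        if len(raw.seq) < params.min_alignable:
            return None, "too_short"
        return (
            replace(raw, protocol="lister", tag_class="FW",
                    trimmed_seq=raw.seq, trimmed_qual=raw.qual),
            None,
        )
    raw = replace(raw, protocol="cokus")
    try:
        return classify_tag(raw, params.tag_config, params.min_alignable), None
    except ReadTooShortError:
        return None, "too_short"


def map_reads(reads, refset: ReferenceSet, params: MapParams) -> MappingResult:
    """Map an iterable of raw :class:`BSRead` against a reference set.

    Implements the full per-read chain: tag handling, 3-letter
    conversion, alignment in the protocol's logical spaces, hit merging,
    the uniqueness rule, Watson-coordinate transform, asymmetric
    mismatch recounting, the quality threshold, and methylation calling.
    """
    genome = refset.genome
    idx_w = refset.indexes["W_CT"]
    idx_c = refset.indexes["C_CT"]
    lengths = genome.lengths
    ctx_map = ContextMap(genome)
    n_passes = 2 if params.protocol == "lister" else 4
    mapped: list[MappedRead] = []
    calls: list = []
    discards: Counter = Counter()
    unmapped: list[tuple[str, str]] = []
    n_reads = 0
    for raw in reads:
        n_reads += 1
        read, reason = prepare_read(raw, params)
        if read is None:
            discards[reason] += 1
            unmapped.append((raw.read_id, reason))
            continue
        n = len(read.trimmed_seq)
        hits: list[AlignmentHit] = []
        spaces = logical_spaces_for(read.tag_class, params.protocol)
        if "W_CT" in spaces:
            r3 = ct_convert(read.trimmed_seq)
            hits.extend(align_read(r3, idx_w, params.m3, read_id=read.read_id))
            hits.extend(align_read(r3, idx_c, params.m3, read_id=read.read_id))
        if "RCW_GA" in spaces:
            # G/A space hits obtained through the C/T indexes via the
            # reverse-complement identity; offsets transformed back.
            rc3 = revcomp(ga_convert(read.trimmed_seq))
            for idx, logical in ((idx_w, "RCW_GA"), (idx_c, "RCC_GA")):
                for h in align_read(rc3, idx, params.m3, read_id=read.read_id):
                    hits.append(
                        AlignmentHit(
                            read_id=h.read_id,
                            space_id=logical,
                            chrom=h.chrom,
                            offset=lengths[h.chrom] - h.offset - n,
                            mismatches3=h.mismatches3,
                        )
                    )
        merged = merge_hits([hits])
        if len(merged) > params.hit_cap:
            discards["ambiguous"] += 1
            unmapped.append((read.read_id, "ambiguous"))
            continue
        best, why = uniqueness_filter(merged)
        if best is None:
            discards[why] += 1
            unmapped.append((read.read_id, why))
            continue
        chrom, start1, form, gseq = to_watson(best, genome, n)
        mm_orig = recount_mismatches(read.trimmed_seq, gseq, form)
        if not quality_filter(mm_orig, params.max_mm):
            discards["low_quality"] += 1
            unmapped.append((read.read_id, "low_quality"))
            continue
        mr = MappedRead(
            read_id=read.read_id,
            chrom=chrom,
            start=start1,
            form=form,
            read_seq=read.trimmed_seq,
            genome_seq=gseq,
            mismatches_orig=mm_orig,
            mismatches3=best.mismatches3,
        )
        read_calls, meth_string = call_read(mr, genome, ctx_map)
        mr.methylation_string = meth_string
        mapped.append(mr)
        calls.extend(read_calls)
    logger.info(
        "mapped %d/%d reads uniquely (%.2f%%); discards: %s",
        len(mapped), n_reads,
        100.0 * len(mapped) / n_reads if n_reads else 0.0,
        dict(discards),
    )
    return MappingResult(
        mapped=mapped,
        calls=calls,
        n_reads=n_reads,
        discards=discards,
        n_passes=n_passes,
        params=params,
        k=refset.k,
        unmapped=unmapped,
    )


def run_mapping(genome: Genome, reads: list[BSRead], params: MapParams) -> MappingResult:
    """Convenience wrapper: choose the effective seed length from the
    read lengths, build the reference set, and map."""
    tag = params.tag_config.tag_length if params.protocol == "cokus" else 0
    min_len = min((len(r.seq) - tag for r in reads), default=params.seed_len)
    k = params.effective_k(max(min_len, 1))
    refset = build_reference(genome, k)
    return map_reads(reads, refset, params)
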