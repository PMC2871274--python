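"""Ungapped seed-and-extend alignment in a converted reference space.

``align_read`` returns *every* placement of a 3-letter read within
Hamming distance m of a reference-space window. Completeness comes from
pigeonhole seeding: the read is cut into m+1 non-overlapping k-long
segments, so any placement with at most m mismatches contains at least
one exact segment, which the seed index finds. Reads too short to carry
m+1 seeds fall back to a full scan of the space — hits are never
silently dropped, because the downstream uniqueness decision is only
correct if no qualifying hit is missed.

``align_bruteforce`` is the independent sliding-window oracle used by
the test suite to verify that contract.

Indels are out of scope: the mismatch-count framework is ungapped. An
external aligner may substitute for :func:`align_read` provided it
honours the same completeness contract.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from ._dna import N, encode
from .refprep import ReferenceSpace, SeedIndex, kmer_code

logger = logging.getLogger(__name__)

DEFAULT_M3 = 3  # 3-letter mismatch ceiling


@dataclass(frozen=True, slots=True)
class AlignmentHit:
    """A candidate placement of a converted read in one reference space."""

    read_id: str
    space_id: str
    chrom: str
    offset: int  # 0-based start within the space
    mismatches3: int


def _read_array(read3: str) -> np.ndarray:
    arr = encode(read3.upper())
    # A read N must never match anything, including a genomic N: replace
    # with a sentinel outside the genome alphabet.
    arr = arr.copy()
    arr[arr == N] = 255
    return arr


def _verify(seq: np.ndarray, cand: np.ndarray, arr: np.ndarray) -> np.ndarray:
    """Mismatch count of ``arr`` against each candidate window start."""
    n = arr.size
    windows = seq[cand[:, None] + np.arange(n)]
    return (windows != arr).sum(axis=1)


_PRESCREEN_POSITIONS = 10
_SUBSET_CACHE: dict[int, np.ndarray] = {}


def _prescreen_subset(n: int) -> np.ndarray:
    sub = _SUBSET_CACHE.get(n)
    if sub is None:
        sub = np.unique(
            np.round(np.linspace(0, n - 1, _PRESCREEN_POSITIONS)).astype(np.int64)
        )
        _SUBSET_CACHE[n] = sub
    return sub


def _verify_pruned(
    seq: np.ndarray, cand: np.ndarray, arr: np.ndarray, m: int
) -> tuple[np.ndarray, np.ndarray]:
    """Two-stage verification: a subset of positions gives a lower bound
    on the mismatch count, pruning candidates that cannot reach <= m;
    survivors get the full count. Returns (kept candidates, mismatches).
    """
    n = arr.size
    if cand.size > 64 and n > 2 * _PRESCREEN_POSITIONS:
        sub = _prescreen_subset(n)
        lower = (seq[cand[:, None] + sub] != arr[sub]).sum(axis=1)
        cand = cand[lower <= m]
        if cand.size == 0:
            return cand, np.empty(0, np.int64)
    mm = _verify(seq, cand, arr)
    keep = mm <= m
    return cand[keep], mm[keep]


def _hits_from_global(
    index: SeedIndex, gpos: np.ndarray, mm: np.ndarray, read_id: str
) -> list[AlignmentHit]:
    hits = []
    for g, m in zip(gpos, mm):
        ci = int(np.searchsorted(index.chrom_starts, g, side="right")) - 1
        hits.append(
            AlignmentHit(
                read_id=read_id,
                space_id=index.space_id,
                chrom=index.names[ci],
                offset=int(g - index.chrom_starts[ci]),
                mismatches3=int(m),
            )
        )
    return hits


def _scan_global(index: SeedIndex, arr: np.ndarray, m: int) -> tuple[np.ndarray, np.ndarray]:
    """Full Hamming scan over every in-bounds window of the index's space."""
    n = arr.size
    gpos_parts, mm_parts = [], []
    for ci in range(len(index.names)):
        cs, ce = int(index.chrom_starts[ci]), int(index.chrom_starts[ci + 1])
        L = ce - cs
        if L < n:
            continue
        seg = index.seq[cs:ce]
        mm = np.zeros(L - n + 1, np.int32)
        for i in range(n):
            mm += seg[i : L - n + 1 + i] != arr[i]
        keep = np.nonzero(mm <= m)[0]
        gpos_parts.append(keep.astype(np.int64) + cs)
        mm_parts.append(mm[keep])
    if not gpos_parts:
        return np.empty(0, np.int64), np.empty(0, np.int32)
    return np.concatenate(gpos_parts), np.concatenate(mm_parts)


def align_read(
    read3: str,
    index: SeedIndex,
    m: int = DEFAULT_M3,
    read_id: str = "",
) -> list[AlignmentHit]:
    """All placements of ``read3`` in the indexed space with <= m mismatches.

    Hits are deduplicated and sorted by (chromosome order, offset).
    """
    if m < 0:
        raise ValueError("mismatch ceiling m must be >= 0")
    arr = _read_array(read3)
    n = arr.size
    if n == 0:
        raise ValueError("empty read")
    k = index.k
    if n < (m + 1) * k:
        # Too short for pigeonhole seeding at this k: complete scan instead.
        logger.debug(
            "read %s: length %d < (m+1)*k = %d; falling back to full scan",
            read_id, n, (m + 1) * k,
        )
        gpos, mm = _scan_global(index, arr, m)
        return _hits_from_global(index, gpos, mm, read_id)

    cand_parts = []
    for i in range(m + 1):
        s = i * k
        seg = arr[s : s + k]
        if (seg > 4).any():  # sentinel N in the seed: cannot be exact
            continue
        pos = index.positions_for_code(kmer_code(seg))
        if pos.size:
            cand_parts.append(pos - s)
    if not cand_parts:
        return []
    cand = np.concatenate(cand_parts)
    cand.sort()
    if cand.size > 1:  # dedupe (sorted)
        cand = cand[np.concatenate(([True], cand[1:] != cand[:-1]))]
    total = index.total_length
    cand = cand[(cand >= 0) & (cand + n <= total)]
    if cand.size == 0:
        return []
    # windows must lie within a single chromosome
    ci = np.searchsorted(index.chrom_starts, cand, side="right") - 1
    cand = cand[cand + n <= index.chrom_starts[ci + 1]]
    if cand.size == 0:
        return []
    kept, mm = _verify_pruned(index.seq, cand, arr, m)
    return _hits_from_global(index, kept, mm, read_id)


def align_bruteforce(
    read3: str,
    space: ReferenceSpace,
    m: int = DEFAULT_M3,
    read_id: str = "",
) -> list[AlignmentHit]:
    """Sliding-window Hamming scan over a reference space (test oracle)."""
    if m < 0:
        raise ValueError("mismatch ceiling m must be >= 0")
    arr = _read_array(read3)
    n = arr.size
    if n == 0:
        raise ValueError("empty read")
    hits = []
    for name in space.names:
        seg = space.arrays[name]
        L = seg.size
        if L < n:
            continue
        mm = np.zeros(L - n + 1, np.int32)
        for i in range(n):
            mm += seg[i : L - n + 1 + i] != arr[i]
        for off in np.nonzero(mm <= m)[0]:
            hits.append(
                AlignmentHit(
                    read_id=read_id,
                    space_id=space.space_id,
                    chrom=name,
                    offset=int(off),
                    mismatches3=int(mm[off]),
                )
            )
    return hits
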