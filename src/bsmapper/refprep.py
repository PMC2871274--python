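"""Reference-genome preparation for bisulfite mapping.

A bisulfite read can originate from either genomic strand, and may be
sequenced either as the converted fragment itself or as its reverse
complement. After collapsing the alphabet (C->T for forward-form reads,
G->A for reverse-complement-form reads), every read matches exactly one
of four converted *reference spaces*:

====== =============================================== ==========
space  converted sequence                              read form
====== =============================================== ==========
W_CT   Watson strand, C->T                             +FW
C_CT   Crick strand (revcomp of Watson), C->T          -FW
RCW_GA revcomp of Watson, G->A                         +RC
RCC_GA revcomp of Crick (= Watson), G->A               -RC
====== =============================================== ==========

Because complementation swaps C and G, ``RCW_GA == revcomp(W_CT)`` and
``RCC_GA == revcomp(C_CT)`` character for character. The mapper exploits
this identity to search all four logical spaces with only the two C/T
seed indexes; the four spaces remain the external contract and are all
materialised by :func:`convert_reference`.

Internal coordinates are 0-based half-open offsets *within each space*;
1-based Watson coordinates appear only in output writers.
"""
from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
from Bio import SeqIO

from . import _dna
from ._dna import (
    N,
    ct_convert_arr,
    decode,
    encode,
    ga_convert_arr,
    revcomp_arr,
)

logger = logging.getLogger(__name__)

SPACE_IDS = ("W_CT", "C_CT", "RCW_GA", "RCC_GA")

#: space_id -> (read form, whether the space offset is reflected through the
#: chromosome length to obtain the Watson start)
SPACE_TRANSFORM = {
    "W_CT": ("+FW", False),
    "C_CT": ("-FW", True),
    "RCW_GA": ("+RC", True),
    "RCC_GA": ("-RC", False),
}


class FastaParseError(ValueError):
    """Raised for malformed or empty FASTA input."""


@dataclass(frozen=True)
class Genome:
    """An in-memory reference genome over {A,C,G,T,N}.

    Sequences are stored encoded (uint8); chromosome order is the input
    order and is preserved everywhere downstream.
    """

    names: tuple[str, ...]
    _arrays: dict[str, np.ndarray]

    @classmethod
    def from_sequences(cls, mapping) -> "Genome":
        names = []
        arrays = {}
        for name, seq in dict(mapping).items():
            name = str(name)
            if not name:
                raise ValueError("empty chromosome name")
            if name in arrays:
                raise ValueError(f"duplicate chromosome name {name!r}")
            arr = encode(str(seq).upper())
            if arr.size == 0:
                raise ValueError(f"chromosome {name!r} has an empty sequence")
            arr.flags.writeable = False
            names.append(name)
            arrays[name] = arr
        if not names:
            raise ValueError("genome must contain at least one sequence")
        return cls(tuple(names), arrays)

    def array(self, name: str) -> np.ndarray:
        return self._arrays[name]

    def sequence(self, name: str) -> str:
        return decode(self._arrays[name])

    def sequence_slice(self, name: str, start: int, end: int) -> str:
        return decode(self._arrays[name][start:end])

    @property
    def sequences(self) -> dict[str, str]:
        return {n: decode(a) for n, a in self._arrays.items()}

    @property
    def lengths(self) -> dict[str, int]:
        return {n: int(a.size) for n, a in self._arrays.items()}

    def __contains__(self, name: str) -> bool:
        return name in self._arrays

    def __len__(self) -> int:
        return len(self.names)


def load_fasta(path) -> Genome:
    """Load a (multi-)FASTA file into a :class:`Genome`.

    Sequence names are truncated at the first whitespace; sequences are
    uppercased and IUPAC ambiguity codes are collapsed to N. Malformed
    or empty input raises :class:`FastaParseError`.
    """
    with open(path) as fh:
        # SeqIO is forgiving about leading junk; insist on a FASTA header.
        for lineno, line in enumerate(fh, start=1):
            if line.strip():
                if not line.startswith(">"):
                    raise FastaParseError(
                        f"{path}: line {lineno}: expected FASTA header '>', "
                        f"got {line.strip()[:30]!r}"
                    )
                break
        else:
            raise FastaParseError(f"{path}: empty FASTA file")
        fh.seek(0)
        seqs: dict[str, str] = {}
        for record in SeqIO.parse(fh, "fasta"):
            if record.id in seqs:
                raise FastaParseError(f"{path}: duplicate sequence name {record.id!r}")
            if len(record.seq) == 0:
                raise FastaParseError(f"{path}: record {record.id!r} has no sequence")
            seqs[record.id] = str(record.seq)
    if not seqs:
        raise FastaParseError(f"{path}: no FASTA records found")
    try:
        return Genome.from_sequences(seqs)
    except _dna.SequenceAlphabetError as e:
        raise FastaParseError(f"{path}: {e}") from e


@dataclass(frozen=True)
class ReferenceSpace:
    """One converted logical reference space (see module docstring)."""

    space_id: str
    conversion: str  # "C_to_T" | "G_to_A"
    names: tuple[str, ...]
    arrays: dict[str, np.ndarray]

    @property
    def sequences(self) -> dict[str, str]:
        return {n: decode(a) for n, a in self.arrays.items()}

    def sequence(self, name: str) -> str:
        return decode(self.arrays[name])

    def to_watson(self, chrom_len: int, offset: int, read_len: int) -> tuple[int, str]:
        """Map a 0-based offset in this space to the 0-based Watson start
        of the covered segment, and the read-form label."""
        form, flip = SPACE_TRANSFORM[self.space_id]
        start0 = chrom_len - offset - read_len if flip else offset
        return start0, form


def convert_reference(genome: Genome) -> list[ReferenceSpace]:
    """Build the four converted reference spaces of a genome.

    Each space is computed directly from its definition (conversion of
    the appropriate strand), not via the revcomp shortcut, so the
    identity ``RCW_GA == revcomp(W_CT)`` is a checkable property rather
    than a construction artefact.
    """
    w_ct, c_ct, rcw_ga, rcc_ga = {}, {}, {}, {}
    for name in genome.names:
        arr = genome.array(name)
        w_ct[name] = ct_convert_arr(arr)
        c_ct[name] = ct_convert_arr(revcomp_arr(arr))
        rcw_ga[name] = ga_convert_arr(revcomp_arr(arr))
        rcc_ga[name] = ga_convert_arr(arr)  # revcomp(Crick) is Watson itself
    names = genome.names
    return [
        ReferenceSpace("W_CT", "C_to_T", names, w_ct),
        ReferenceSpace("C_CT", "C_to_T", names, c_ct),
        ReferenceSpace("RCW_GA", "G_to_A", names, rcw_ga),
        ReferenceSpace("RCC_GA", "G_to_A", names, rcc_ga),
    ]


def _window_codes(arr: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Base-5 integer codes for every k-window, plus a validity mask
    (False where the window contains N)."""
    L = arr.size
    nwin = L - k + 1
    if nwin <= 0:
        return np.empty(0, np.uint64), np.empty(0, bool)
    a64 = arr.astype(np.uint64)
    codes = np.zeros(nwin, np.uint64)
    for j in range(k):
        codes = codes * np.uint64(5) + a64[j : j + nwin]
    is_n = (arr == N).astype(np.int64)
    cum = np.concatenate([[0], np.cumsum(is_n)])
    valid = (cum[k:] - cum[:-k]) == 0
    return codes, valid


def kmer_code(arr: np.ndarray) -> int | None:
    """Base-5 code of a single k-mer, or None if it contains N."""
    if (arr == N).any():
        return None
    code = 0
    for b in arr:
        code = code * 5 + int(b)
    return code


@dataclass
class SeedIndex:
    """Exact k-mer lookup table over one reference space.

    Positions are stored as a single int64 array grouped by k-mer code
    (ascending within each group); chromosomes are concatenated and
    addressed through ``chrom_starts``. Windows containing N are not
    indexed. Stands in for the external aligner's index.
    """

    k: int
    space_id: str
    names: tuple[str, ...]
    chrom_starts: np.ndarray  # int64, len(names)+1, last entry = total length
    seq: np.ndarray  # concatenated encoded space sequence
    _codes: np.ndarray = field(repr=False)  # unique kmer codes, sorted
    _bucket_starts: np.ndarray = field(repr=False)
    _positions: np.ndarray = field(repr=False)  # global offsets

    @property
    def total_length(self) -> int:
        return int(self.chrom_starts[-1])

    def positions_for_code(self, code: int | None) -> np.ndarray:
        """Global positions of one k-mer code (empty array if absent)."""
        if code is None:
            return np.empty(0, np.int64)
        i = int(np.searchsorted(self._codes, np.uint64(code)))
        if i == len(self._codes) or self._codes[i] != np.uint64(code):
            return np.empty(0, np.int64)
        return self._positions[self._bucket_starts[i] : self._bucket_starts[i + 1]]

    def lookup(self, kmer: str) -> list[tuple[str, int]]:
        """(chromosome, offset) occurrences of ``kmer``, offsets ascending."""
        arr = encode(kmer.upper())
        if arr.size != self.k:
            raise ValueError(f"k-mer length {arr.size} != index k {self.k}")
        out = []
        for g in self.positions_for_code(kmer_code(arr)):
            ci = int(np.searchsorted(self.chrom_starts, g, side="right")) - 1
            out.append((self.names[ci], int(g - self.chrom_starts[ci])))
        return out

    @property
    def table(self) -> dict[str, list[tuple[str, int]]]:
        """Materialised k-mer -> positions map (small inputs / debugging)."""
        out: dict[str, list[tuple[str, int]]] = {}
        for i, code in enumerate(self._codes):
            kmer = _decode_code(int(code), self.k)
            positions = self._positions[
                self._bucket_starts[i] : self._bucket_starts[i + 1]
            ]
            entries = []
            for g in positions:
                ci = int(np.searchsorted(self.chrom_starts, g, side="right")) - 1
                entries.append((self.names[ci], int(g - self.chrom_starts[ci])))
            out[kmer] = entries
        return out


def _decode_code(code: int, k: int) -> str:
    digits = []
    for _ in range(k):
        digits.append("ACGTN"[code % 5])
        code //= 5
    return "".join(reversed(digits))


def build_index(space: ReferenceSpace, k: int) -> SeedIndex:
    """Index every N-free k-mer occurrence in a reference space."""
    lengths = [space.arrays[n].size for n in space.names]
    if k < 1:
        raise ValueError("seed length k must be >= 1")
    if k > max(lengths):
        raise ValueError(
            f"seed length k={k} exceeds every chromosome length (max {max(lengths)})"
        )
    starts = np.concatenate([[0], np.cumsum(lengths)]).astype(np.int64)
    seq = np.concatenate([space.arrays[n] for n in space.names])
    code_parts, pos_parts = [], []
    for i, name in enumerate(space.names):
        codes, valid = _window_codes(space.arrays[name], k)
        if codes.size == 0:
            continue
        local = np.nonzero(valid)[0].astype(np.int64)
        code_parts.append(codes[valid])
        pos_parts.append(local + starts[i])
    if code_parts:
        all_codes = np.concatenate(code_parts)
        all_pos = np.concatenate(pos_parts)
        order = np.lexsort((all_pos, all_codes))
        sorted_codes = all_codes[order]
        positions = all_pos[order]
        uniq, first = np.unique(sorted_codes, return_index=True)
        bucket_starts = np.concatenate([first, [sorted_codes.size]]).astype(np.int64)
    else:
        uniq = np.empty(0, np.uint64)
        bucket_starts = np.zeros(1, np.int64)
        positions = np.empty(0, np.int64)
    return SeedIndex(
        k=k,
        space_id=space.space_id,
        names=space.names,
        chrom_starts=starts,
        seq=seq,
        _codes=uniq,
        _bucket_starts=bucket_starts,
        _positions=positions,
    )


REFSET_FORMAT_VERSION = 1


@dataclass
class ReferenceSet:
    """Genome plus its four converted spaces and the two physical seed
    indexes (W_CT and C_CT; the G/A spaces are searched through them,
    see module docstring)."""

    genome: Genome
    spaces: dict[str, ReferenceSpace]
    indexes: dict[str, SeedIndex]
    k: int

    def save(self, path) -> None:
        """Serialize as a versioned .npz (genome + parameters).

        Converted spaces and seed tables are deterministic functions of
        the genome and are rebuilt on load.
        """
        meta = {
            "format_version": REFSET_FORMAT_VERSION,
            "k": self.k,
            "names": list(self.genome.names),
        }
        arrays = {f"seq_{i}": self.genome.array(n) for i, n in enumerate(self.genome.names)}
        np.savez_compressed(path, meta=np.frombuffer(json.dumps(meta).encode(), np.uint8), **arrays)

    @classmethod
    def load(cls, path) -> "ReferenceSet":
        with np.load(path) as data:
            meta = json.loads(data["meta"].tobytes().decode())
            if meta.get("format_version") != REFSET_FORMAT_VERSION:
                raise ValueError(
                    f"reference set {path} has format version "
                    f"{meta.get('format_version')!r}; expected {REFSET_FORMAT_VERSION}"
                )
            seqs = {n: decode(data[f"seq_{i}"]) for i, n in enumerate(meta["names"])}
        genome = Genome.from_sequences(seqs)
        return build_reference(genome, meta["k"])


def build_reference(genome: Genome, k: int) -> ReferenceSet:
    """Convert the genome and build the two physical seed indexes."""
    spaces = {s.space_id: s for s in convert_reference(genome)}
    logger.info("building seed indexes (k=%d) over W_CT and C_CT", k)
    indexes = {
        "W_CT": build_index(spaces["W_CT"], k),
        "C_CT": build_index(spaces["C_CT"], k),
    }
    return ReferenceSet(genome=genome, spaces=spaces, indexes=indexes, k=k)
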