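"""Read preparation: FASTQ parsing, protocol tag handling, conversion.

Two library chemistries are supported. The non-directional (Cokus-style)
protocol produces four read forms (+FW, +RC, -FW, -RC), each carrying a
5-nt adapter-derived tag whose pattern identifies whether the read is a
forward (FW) or reverse-complement (RC) form. The directional
(Lister-style) protocol, built with premethylated adapters, produces
only +FW/-FW reads and no tags.

Tag *patterns* are configuration, not constants: their sequences are
chemistry-specific and user-supplied. The shipped defaults are synthetic
(DpnI recognition site GATC plus one discriminating base) and documented
as such; they match what the bundled simulator emits.

Base qualities are parsed and carried through to output but never used
in alignment or filtering: reads are modelled as discrete base calls.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace

from Bio.SeqIO.QualityIO import FastqGeneralIterator

from ._dna import ct_convert, ga_convert

PROTOCOLS = ("cokus", "lister")
TAG_CLASSES = ("FW", "RC", "UNKNOWN")

DEFAULT_MIN_ALIGNABLE = 20


class FastqParseError(ValueError):
    """Raised for malformed FASTQ records."""


class ReadTooShortError(ValueError):
    """Raised when a read is too short to align after tag trimming."""


@dataclass(frozen=True)
class TagConfig:
    """Fixed-length tag patterns for the non-directional protocol.

    Patterns are strings over {A,C,G,T,N}; N is a wildcard matching any
    base. FW and RC pattern sets must be disjoint, including through
    wildcards (no concrete tag may match patterns from both sets).
    """

    tag_length: int = 5
    fw_patterns: tuple[str, ...] = ("GATCT",)
    rc_patterns: tuple[str, ...] = ("GATCA",)

    def __post_init__(self):
        if self.tag_length < 1:
            raise ValueError("tag_length must be >= 1")
        for p in self.fw_patterns + self.rc_patterns:
            if len(p) != self.tag_length:
                raise ValueError(
                    f"pattern {p!r} has length {len(p)}, expected {self.tag_length}"
                )
            if any(c not in "ACGTN" for c in p):
                raise ValueError(f"pattern {p!r} contains characters outside ACGTN")
        for f in self.fw_patterns:
            for r in self.rc_patterns:
                if _patterns_compatible(f, r):
                    raise ValueError(
                        f"FW pattern {f!r} and RC pattern {r!r} can match the "
                        "same tag; pattern sets must be disjoint"
                    )

    @classmethod
    def from_file(cls, path) -> "TagConfig":
        """Read a small key=value config: tag_length, fw, rc (comma-separated)."""
        kv = {}
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                if "=" not in line:
                    raise ValueError(f"{path}: malformed line {line!r}")
                key, val = line.split("=", 1)
                kv[key.strip().lower()] = val.strip()
        return cls(
            tag_length=int(kv.get("tag_length", 5)),
            fw_patterns=tuple(s.strip().upper() for s in kv["fw"].split(",")),
            rc_patterns=tuple(s.strip().upper() for s in kv["rc"].split(",")),
        )


def _patterns_compatible(a: str, b: str) -> bool:
    return all(x == y or x == "N" or y == "N" for x, y in zip(a, b))


def _pattern_matches(pattern: str, tag: str) -> bool:
    return all(p == "N" or p == t for p, t in zip(pattern, tag))


@dataclass(frozen=True)
class BSRead:
    """One sequencing read with protocol and tag metadata.

    ``trimmed_seq`` is the alignable (tag-free) suffix of ``seq``; for
    the directional protocol it equals ``seq``.
    """

    read_id: str
    seq: str
    qual: str
    protocol: str = "lister"
    tag_class: str = "UNKNOWN"
    trimmed_seq: str = ""
    trimmed_qual: str = ""

    def __post_init__(self):
        if len(self.seq) != len(self.qual):
            raise FastqParseError(
                f"read {self.read_id!r}: sequence length {len(self.seq)} != "
                f"quality length {len(self.qual)}"
            )
        if self.protocol not in PROTOCOLS:
            raise ValueError(f"unknown protocol {self.protocol!r}")
        if not self.trimmed_seq:
            object.__setattr__(self, "trimmed_seq", self.seq)
            object.__setattr__(self, "trimmed_qual", self.qual)


def read_fastq(path, protocol: str = "lister"):
    """Iterate 4-line FASTQ records as :class:`BSRead`, preserving order.

    Sequences are uppercased. Length mismatches and truncated records
    raise :class:`FastqParseError` naming the offending record.
    """
    with open(path) as fh:
        it = FastqGeneralIterator(fh)
        while True:
            try:
                title, seq, qual = next(it)
            except StopIteration:
                return
            except ValueError as e:
                raise FastqParseError(str(e)) from e
            read_id = title.split()[0] if title.split() else title
            if len(seq) != len(qual):
                raise FastqParseError(
                    f"read {read_id!r}: sequence and quality lengths differ "
                    f"({len(seq)} vs {len(qual)})"
                )
            yield BSRead(read_id=read_id, seq=seq.upper(), qual=qual, protocol=protocol)


def classify_tag(
    read: BSRead,
    cfg: TagConfig,
    min_alignable: int = DEFAULT_MIN_ALIGNABLE,
) -> BSRead:
    """Classify and trim the 5' tag of a non-directional-protocol read.

    The first ``tag_length`` bases are compared against the FW patterns,
    then the RC patterns (N in a pattern matches anything). On no match
    the class is UNKNOWN and the tag region is still trimmed — it is
    adapter-derived, not genomic, under this protocol.

    Raises :class:`ReadTooShortError` if fewer than ``min_alignable``
    bases remain after trimming.
    """
    if read.protocol != "cokus":
        raise ValueError("classify_tag applies to the cokus (tagged) protocol only")
    t = cfg.tag_length
    if len(read.seq) < t + min_alignable:
        raise ReadTooShortError(
            f"read {read.read_id!r}: {len(read.seq)} bp leaves fewer than "
            f"{min_alignable} alignable bases after removing the {t}-bp tag"
        )
    tag = read.seq[:t]
    tag_class = "UNKNOWN"
    if any(_pattern_matches(p, tag) for p in cfg.fw_patterns):
        tag_class = "FW"
    elif any(_pattern_matches(p, tag) for p in cfg.rc_patterns):
        tag_class = "RC"
    return replace(
        read,
        tag_class=tag_class,
        trimmed_seq=read.seq[t:],
        trimmed_qual=read.qual[t:],
    )


def convert_read(read: BSRead | str, direction: str) -> str:
    """Three-letter conversion of a read's alignable sequence.

    FW direction replaces every C by T; RC replaces every G by A. The
    original sequence is retained on the read for post-processing.
    """
    seq = read.trimmed_seq if isinstance(read, BSRead) else read
    if not seq:
        raise ValueError("cannot convert an empty sequence")
    if direction == "FW":
        return ct_convert(seq)
    if direction == "RC":
        return ga_convert(seq)
    raise ValueError(f"direction must be FW or RC, got {direction!r}")
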