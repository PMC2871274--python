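"""Nucleotide encoding and elementary sequence transforms.

Bases are encoded as uint8 integers: A=0, C=1, G=2, T=3, N=4. IUPAC
ambiguity codes are collapsed to N on input (U maps to T); any other
character is rejected. Complementation is ``3 - b`` for the four real
bases, with N self-complementary.
"""
from __future__ import annotations

import numpy as np

BASES = "ACGTN"
A, C, G, T, N = range(5)

_ENC = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(BASES):
    _ENC[ord(_b)] = _i
    _ENC[ord(_b.lower())] = _i
for _b in "RYSWKMBDHV":
    _ENC[ord(_b)] = N
    _ENC[ord(_b.lower())] = N
_ENC[ord("U")] = T
_ENC[ord("u")] = T

_DEC = np.frombuffer(b"ACGTN", dtype=np.uint8)

_COMP = np.array([T, G, C, A, N], dtype=np.uint8)

_CT = np.arange(5, dtype=np.uint8)
_CT[C] = T
_GA = np.arange(5, dtype=np.uint8)
_GA[G] = A


class SequenceAlphabetError(ValueError):
    """Raised when a sequence contains a character outside the accepted alphabet."""


def encode(seq: str) -> np.ndarray:
    """Encode a nucleotide string to a uint8 array (A=0 C=1 G=2 T=3 N=4)."""
    try:
        raw = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    except UnicodeEncodeError as e:
        raise SequenceAlphabetError(f"non-ASCII character in sequence: {e}") from e
    out = _ENC[raw]
    if out.size and out.max() == 255:
        i = int(np.argmax(out == 255))
        raise SequenceAlphabetError(
            f"invalid nucleotide {seq[i]!r} at position {i + 1}"
        )
    return out


def decode(arr: np.ndarray) -> str:
    return _DEC[arr].tobytes().decode("ascii")


def comp_arr(arr: np.ndarray) -> np.ndarray:
    return _COMP[arr]


def revcomp_arr(arr: np.ndarray) -> np.ndarray:
    return _COMP[arr][::-1]


def revcomp(seq: str) -> str:
    return decode(revcomp_arr(encode(seq)))


def ct_convert_arr(arr: np.ndarray) -> np.ndarray:
    """C -> T substitution (bisulfite collapse of the forward alphabet)."""
    return _CT[arr]


def ga_convert_arr(arr: np.ndarray) -> np.ndarray:
    """G -> A substitution (bisulfite collapse seen from the reverse complement)."""
    return _GA[arr]


def ct_convert(seq: str) -> str:
    return seq.replace("C", "T")


def ga_convert(seq: str) -> str:
    return seq.replace("G", "A")
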