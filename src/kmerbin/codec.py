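"""Two-bit nucleotide codec and k-mer window iteration.

DNA letters are packed two bits per letter with A=0, C=1, G=2, T=3 and the
leftmost letter in the most significant bits.  With this mapping, numeric
order of codes of equal-length mers coincides with lexicographic order of
the strings, so a plain integer comparison implements the classic
lexicographic minimizer ordering.

Reads are sanitized into maximal A/C/G/T-only segments before any window
iteration: characters outside the alphabet (N, IUPAC ambiguity codes, ...)
act as hard breaks and no k-mer or super-mer ever spans one.  Coordinates
are 0-based half-open throughout.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterator

import numpy as np

BASES = "ACGT"
_BASE_TO_BITS = {c: i for i, c in enumerate(BASES)}
_SEGMENT_RE = re.compile(r"[ACGT]+")

# fast byte-level lookup for segment vectorization; 255 marks invalid
_BYTE_LUT = np.full(256, 255, dtype=np.uint8)
for _c, _v in _BASE_TO_BITS.items():
    _BYTE_LUT[ord(_c)] = _v


@dataclass(frozen=True)
class NtSegment:
    """A maximal run of unambiguous nucleotides within one read.

    ``origin_offset`` is the 0-based offset of the first letter within the
    raw (pre-sanitization) read.
    """

    letters: str
    origin_offset: int = 0

    def __len__(self) -> int:
        return len(self.letters)


@dataclass(frozen=True)
class EncodedMer:
    """An m- or k-mer packed two bits per letter into one integer.

    ``code`` is a non-negative Python integer (arbitrary precision, so any
    k is representable); ``length`` is the letter count.  Invariant:
    ``0 <= code < 4**length``.
    """

    code: int
    length: int

    def __str__(self) -> str:
        return decode_mer(self.code, self.length)


def sanitize(raw_sequence: str) -> list[NtSegment]:
    """Split a raw read into maximal ACGT-only segments.

    Input is uppercased first (soft-masked lowercase stays usable); every
    character outside {A, C, G, T} then splits the read.  Degenerate input
    yields an empty list.
    """
    upper = raw_sequence.upper()
    return [
        NtSegment(m.group(0), m.start())
        for m in _SEGMENT_RE.finditer(upper)
    ]


def encode_mer(s: str) -> EncodedMer:
    """Encode an ACGT string; raises ``ValueError`` on other letters."""
    if not s:
        raise ValueError("cannot encode an empty mer")
    code = 0
    try:
        for c in s:
            code = (code << 2) | _BASE_TO_BITS[c]
    except KeyError:
        raise ValueError(f"non-ACGT letter in mer: {s!r}") from None
    return EncodedMer(code, len(s))


def decode_mer(code: int, length: int) -> str:
    """Inverse of :func:`encode_mer` for a raw (code, length) pair."""
    if code < 0 or code >= 4 ** length:
        raise ValueError(f"code {code} out of range for length {length}")
    out = []
    for shift in range(2 * (length - 1), -1, -2):
        out.append(BASES[(code >> shift) & 3])
    return "".join(out)


def segment_values(segment: NtSegment | str) -> np.ndarray:
    """2-bit values (uint8) of a segment's letters, vectorized."""
    letters = segment.letters if isinstance(segment, NtSegment) else segment
    vals = _BYTE_LUT[np.frombuffer(letters.encode("ascii"), dtype=np.uint8)]
    if vals.size and vals.max() == 255:
        raise ValueError("segment contains non-ACGT letters")
    return vals


def window_codes(values: np.ndarray, width: int) -> np.ndarray:
    """Codes of all overlapping ``width``-windows over 2-bit values.

    Returns a uint64 array of length ``max(0, n - width + 1)``; requires
    ``width <= 31`` so codes fit in 64 bits (minimizer lengths in practice
    are far below this).
    """
    if width < 1 or width > 31:
        raise ValueError("window width must be in 1..31")
    n = values.size - width + 1
    if n <= 0:
        return np.empty(0, dtype=np.uint64)
    codes = np.zeros(n, dtype=np.uint64)
    for i in range(width):
        codes = (codes << np.uint64(2)) | values[i : i + n].astype(np.uint64)
    return codes


def iterate_kmers(segment: NtSegment | str, k: int) -> Iterator[EncodedMer]:
    """Yield the overlapping k-windows of a segment, left to right.

    A segment shorter than k yields nothing; ``k < 1`` is rejected.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    letters = segment.letters if isinstance(segment, NtSegment) else segment
    for i in range(len(letters) - k + 1):
        yield encode_mer(letters[i : i + k])
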