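"""Minimizer orderings: total priority functions over all 4^m m-mers.

An ordering assigns every m-mer an integer *rank key*; lower key means
higher priority, and the minimizer of a k-window is the m-mer with the
smallest key among its k - m + 1 positions.  Every key embeds the m-mer's
2-bit code in its low bits, which makes all orderings strict total orders
with deterministic (lexicographic) tie-breaking by construction.

Six orderings are supported, selected by token:

``lex``
    Plain lexicographic order of the m-mer string (A < C < G < T).
``signature``
    KMC2-style signatures: m-mers starting with AAA or ACA, or containing
    AA anywhere except at the very start, are pushed below all others;
    within each class the order is lexicographic.
``random``
    Lexicographic order of ``code XOR c`` for a seeded random 2m-bit
    constant c.
``freq``
    Frequency-sampled: m-mers ordered from rare to common by their
    occurrence count in a sampled fraction of the reads, ties broken
    lexicographically.  Unseen m-mers count as zero and therefore rank
    first.
``ulex`` / ``urand`` / ``ufreq``
    The corresponding base ordering restricted to a universal hitting
    set: every non-member ranks below every member, so on any k-window
    the chosen minimizer is always a set member.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable

import numpy as np

from .codec import EncodedMer, sanitize, segment_values, window_codes
from .uhs import UniversalSet

MAX_M = 15
ORDERING_TOKENS = ("lex", "signature", "random", "freq", "ulex", "urand", "ufreq")

# rank keys are uint64; the top bit flags universal-set non-members and
# must stay clear in every base key
_NONMEMBER_BIT = np.uint64(1) << np.uint64(63)


def _check_m(m: int) -> None:
    if not 1 <= m <= MAX_M:
        raise ValueError(f"m must be in 1..{MAX_M}, got {m}")


def _as_code(mmer: EncodedMer | int) -> int:
    return mmer.code if isinstance(mmer, EncodedMer) else int(mmer)


class MinimizerOrdering:
    """Base class: a pure, stable rank function over all 4^m m-mers."""

    name: str = "base"

    def __init__(self, m: int):
        _check_m(m)
        self.m = m

    def rank(self, mmer: EncodedMer | int) -> int:
        """Scalar rank key of one m-mer (lower = higher priority)."""
        code = _as_code(mmer)
        return int(self.rank_array(np.array([code], dtype=np.uint64))[0])

    def rank_array(self, codes: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


class LexicographicOrdering(MinimizerOrdering):
    """A < C < G < T on the m-mer string; the key is the 2-bit code."""

    name = "lex"

    def rank_array(self, codes: np.ndarray) -> np.ndarray:
        return codes.astype(np.uint64)


class SignatureOrdering(MinimizerOrdering):
    """KMC2 signature rules layered on lexicographic order (m >= 3)."""

    name = "signature"

    def __init__(self, m: int):
        if m < 3:
            raise ValueError("signature ordering requires m >= 3")
        super().__init__(m)

    def _disallowed(self, codes: np.ndarray) -> np.ndarray:
        m = self.m
        codes = codes.astype(np.uint64)
        prefix3 = codes >> np.uint64(2 * (m - 3))
        bad = prefix3 == np.uint64(0b000000)  # starts with AAA
        bad |= prefix3 == np.uint64(0b000100)  # starts with ACA
        for pos in range(1, m - 1):  # AA anywhere but the start
            pair = (codes >> np.uint64(2 * (m - 2 - pos))) & np.uint64(0xF)
            bad |= pair == np.uint64(0)
        return bad

    def rank_array(self, codes: np.ndarray) -> np.ndarray:
        codes = codes.astype(np.uint64)
        cls = self._disallowed(codes).astype(np.uint64)
        return (cls << np.uint64(2 * self.m)) | codes


class RandomOrdering(MinimizerOrdering):
    """Lexicographic order of code XOR c for a seeded 2m-bit constant c."""

    name = "random"

    def __init__(self, m: int, seed: int | None = None):
        super().__init__(m)
        self.seed = seed
        self.constant = int(np.random.default_rng(seed).integers(0, 4 ** m))

    def rank_array(self, codes: np.ndarray) -> np.ndarray:
        return codes.astype(np.uint64) ^ np.uint64(self.constant)


@dataclass(frozen=True)
class FrequencyTable:
    """Sampled m-mer occurrence counts; an absent key means count zero."""

    counts: dict[int, int]
    m: int
    sample_fraction: float
    seed: int | None = None
    # sorted (codes, counts) arrays for vectorized lookup
    _codes: np.ndarray = field(init=False, repr=False, compare=False)
    _counts: np.ndarray = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        if self.counts:
            codes = np.fromiter(self.counts, dtype=np.uint64, count=len(self.counts))
            order = np.argsort(codes)
            cnts = np.fromiter(
                (self.counts[int(c)] for c in codes[order]),
                dtype=np.uint64,
                count=len(self.counts),
            )
            codes = codes[order]
        else:
            codes = np.empty(0, dtype=np.uint64)
            cnts = np.empty(0, dtype=np.uint64)
        object.__setattr__(self, "_codes", codes)
        object.__setattr__(self, "_counts", cnts)

    def count_array(self, codes: np.ndarray) -> np.ndarray:
        if self._codes.size == 0:
            return np.zeros(codes.shape, dtype=np.uint64)
        idx = np.searchsorted(self._codes, codes)
        idx = np.minimum(idx, self._codes.size - 1)
        found = self._codes[idx] == codes
        return np.where(found, self._counts[idx], np.uint64(0))


def _sequences_of(reads: Iterable) -> Iterable[str]:
    for rec in reads:
        yield rec[1] if isinstance(rec, tuple) else str(rec)


def sample_frequencies(
    reads: Iterable,
    m: int,
    fraction: float = 0.01,
    seed: int | None = None,
) -> FrequencyTable:
    """Estimate m-mer frequencies from a Bernoulli sample of reads.

    Each read is independently kept with probability ``fraction`` (seeded);
    for every kept read, every overlapping m-mer occurrence in every
    sanitized segment is counted once.  ``reads`` may be raw sequence
    strings or (read_id, sequence) tuples.
    """
    _check_m(m)
    if not 0 < fraction <= 1:
        raise ValueError("sample fraction must be in (0, 1]")
    rng = np.random.default_rng(seed)
    counts: Counter[int] = Counter()
    for seq in _sequences_of(reads):
        if rng.random() >= fraction:
            continue
        for segment in sanitize(seq):
            codes = window_codes(segment_values(segment), m)
            if codes.size:
                uniq, n = np.unique(codes, return_counts=True)
                for c, cnt in zip(uniq, n):
                    counts[int(c)] += int(cnt)
    return FrequencyTable(dict(counts), m, fraction, seed)


class FrequencyOrdering(MinimizerOrdering):
    """Rare-to-common order by sampled count, ties lexicographic."""

    name = "freq"

    def __init__(self, table: FrequencyTable):
        super().__init__(table.m)
        self.table = table
        max_count = max(table.counts.values(), default=0)
        if max_count >= 1 << (62 - 2 * self.m):
            raise ValueError("sampled counts too large to pack into rank keys")

    def rank_array(self, codes: np.ndarray) -> np.ndarray:
        codes = codes.astype(np.uint64)
        cnt = self.table.count_array(codes)
        return (cnt << np.uint64(2 * self.m)) | codes


class UniversalOrdering(MinimizerOrdering):
    """A base ordering with all non-members of a hitting set demoted."""

    def __init__(self, base: MinimizerOrdering, uhs: UniversalSet):
        if uhs.m != base.m:
            raise ValueError(
                f"universal set m={uhs.m} does not match ordering m={base.m}"
            )
        super().__init__(base.m)
        self.base = base
        self.uhs = uhs
        self.name = "u" + ("rand" if base.name == "random" else base.name)

    def rank_array(self, codes: np.ndarray) -> np.ndarray:
        codes = codes.astype(np.uint64)
        key = self.base.rank_array(codes)
        member = self.uhs.contains_array(codes)
        return np.where(member, key, key | _NONMEMBER_BIT)


def lexicographic_ordering(m: int) -> MinimizerOrdering:
    return LexicographicOrdering(m)


def signature_ordering(m: int) -> MinimizerOrdering:
    return SignatureOrdering(m)


def random_ordering(m: int, seed: int | None = None) -> MinimizerOrdering:
    return RandomOrdering(m, seed)


def frequency_ordering(table: FrequencyTable) -> MinimizerOrdering:
    return FrequencyOrdering(table)


def universal_restriction(
    base: MinimizerOrdering, uhs: UniversalSet
) -> MinimizerOrdering:
    return UniversalOrdering(base, uhs)


def make_ordering(
    token: str,
    m: int,
    *,
    seed: int | None = None,
    freq_table: FrequencyTable | None = None,
    uhs: UniversalSet | None = None,
) -> MinimizerOrdering:
    """Build an ordering from its CLI token.

    ``freq``/``ufreq`` require a sampled :class:`FrequencyTable`;
    ``ulex``/``urand``/``ufreq`` require a :class:`UniversalSet`.
    """
    if token not in ORDERING_TOKENS:
        raise ValueError(
            f"unknown ordering {token!r}; expected one of {ORDERING_TOKENS}"
        )
    if token in ("freq", "ufreq"):
        if freq_table is None:
            raise ValueError(f"ordering {token!r} requires a frequency table")
        if freq_table.m != m:
            raise ValueError(
                f"frequency table m={freq_table.m} does not match m={m}"
            )
    if token.startswith("u") and uhs is None:
        raise ValueError(f"ordering {token!r} requires a universal hitting set")
    base: MinimizerOrdering
    if token in ("lex", "ulex"):
        base = LexicographicOrdering(m)
    elif token == "signature":
        base = SignatureOrdering(m)
    elif token in ("random", "urand"):
        base = RandomOrdering(m, seed)
    else:  # freq / ufreq
        base = FrequencyOrdering(freq_table)
    if token.startswith("u"):
        return UniversalOrdering(base, uhs)
    return base
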