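"""Super-mer construction: splitting sequences under a minimizer ordering.

A super-mer is a maximal substring in which every k-mer has the same
minimizer.  Consecutive k-windows of a read usually share their minimizer,
so a read of n k-mers collapses into far fewer super-mers, each overlapping
the next by k - 1 letters.  Grouping super-mers by minimizer yields the
k-mer bins on which counting and bin-distribution analysis operate.

The per-window minimum rank is computed with a monotonic-queue sliding
minimum (O(n) per segment); its contract is equivalence with a naive
rescan of every window.  When the minimal m-mer occurs at several
positions of one window the leftmost occurrence is reported — this cannot
change the bin (same m-mer) but fixes boundary determinism.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass

import numpy as np

from .codec import EncodedMer, NtSegment, decode_mer, segment_values, window_codes
from .orderings import MinimizerOrdering


@dataclass(frozen=True)
class SuperMer:
    """A maximal run of k-mers sharing one minimizer.

    ``minimizer`` is the shared m-mer's 2-bit code; ``start`` is the
    0-based offset of the super-mer within the source read.
    """

    letters: str
    minimizer: int
    read_id: str | None = None
    start: int = 0

    def __len__(self) -> int:
        return len(self.letters)

    def kmer_count(self, k: int) -> int:
        return len(self.letters) - (k - 1)


def sliding_argmin(keys: np.ndarray, width: int) -> np.ndarray:
    """Index of the leftmost minimum in every ``width``-window of ``keys``."""
    n = keys.size - width + 1
    out = np.empty(max(n, 0), dtype=np.int64)
    if n <= 0:
        return out
    q: deque[int] = deque()
    for j in range(keys.size):
        # strict pop keeps the earliest index among equal keys (leftmost rule)
        while q and keys[q[-1]] > keys[j]:
            q.pop()
        q.append(j)
        if q[0] <= j - width:
            q.popleft()
        if j >= width - 1:
            out[j - width + 1] = q[0]
    return out


def window_minimizer(
    kmer: EncodedMer | str, m: int, ordering: MinimizerOrdering
) -> tuple[int, int]:
    """The minimizer of one k-mer: (m-mer code, leftmost position)."""
    letters = str(kmer) if isinstance(kmer, EncodedMer) else kmer
    if len(letters) < m:
        raise ValueError(f"k-mer length {len(letters)} < m={m}")
    codes = window_codes(segment_values(letters), m)
    ranks = ordering.rank_array(codes)
    pos = int(np.argmin(ranks))  # argmin returns the first minimum
    return int(codes[pos]), pos


def split_supermers(
    segment: NtSegment | str,
    k: int,
    m: int,
    ordering: MinimizerOrdering,
    read_id: str | None = None,
) -> list[SuperMer]:
    """Split a sanitized segment into its ordered super-mers.

    Consecutive k-windows with the same minimizer merge into one
    super-mer; adjacent super-mers therefore carry different minimizers,
    and the k-mer masses satisfy sum(L_i - (k - 1)) = len(segment) - k + 1.
    Segments shorter than k yield an empty list.
    """
    if k < m:
        raise ValueError(f"k={k} must be >= m={m}")
    if isinstance(segment, str):
        segment = NtSegment(segment, 0)
    letters = segment.letters
    n_kmers = len(letters) - k + 1
    if n_kmers <= 0:
        return []
    mcodes = window_codes(segment_values(letters), m)
    ranks = ordering.rank_array(mcodes)
    minpos = sliding_argmin(ranks, k - m + 1)
    mins = mcodes[minpos]
    breaks = np.flatnonzero(np.diff(mins) != 0) + 1
    starts = np.concatenate(([0], breaks))
    ends = np.concatenate((breaks, [n_kmers]))
    return [
        SuperMer(
            letters[int(s) : int(e) + k - 1],
            int(mins[int(s)]),
            read_id,
            segment.origin_offset + int(s),
        )
        for s, e in zip(starts, ends)
    ]


def bin_supermers(supermers) -> dict[int, list[SuperMer]]:
    """Group super-mers by minimizer code (the bin key)."""
    bins: dict[int, list[SuperMer]] = {}
    for sm in supermers:
        bins.setdefault(sm.minimizer, []).append(sm)
    return bins


def bin_key_string(code: int, m: int) -> str:
    """Human-readable bin key (the minimizer m-mer string)."""
    return decode_mer(code, m)
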