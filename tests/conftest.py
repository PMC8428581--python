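"""Shared fixtures and independent brute-force oracles.

The oracles deliberately avoid the library's vectorized/monotonic-queue
code paths: they rescan every window with scalar ranks and tally k-mers
with a plain dictionary, so equivalence tests are meaningful.
"""

from __future__ import annotations

from collections import Counter

import pytest

from kmerbin.codec import encode_mer, sanitize
from kmerbin.supermers import bin_supermers, split_supermers


def naive_window_minimizer(kmer: str, m: int, ordering) -> tuple[int, int]:
    """Leftmost smallest-rank m-mer of one k-mer, by full rescan."""
    best = None
    for pos in range(len(kmer) - m + 1):
        code = encode_mer(kmer[pos : pos + m]).code
        key = ordering.rank(code)
        if best is None or key < best[0]:
            best = (key, code, pos)
    return best[1], best[2]


def naive_split(letters: str, k: int, m: int, ordering) -> list[tuple[str, int]]:
    """Run-length merge of per-k-mer minimizers computed by rescan."""
    n_kmers = len(letters) - k + 1
    if n_kmers <= 0:
        return []
    mins = [
        naive_window_minimizer(letters[i : i + k], m, ordering)[0]
        for i in range(n_kmers)
    ]
    out = []
    start = 0
    for i in range(1, n_kmers + 1):
        if i == n_kmers or mins[i] != mins[start]:
            out.append((letters[start : i + k - 1], mins[start]))
            start = i
    return out


def naive_tally(reads, k: int) -> Counter:
    """Whole-dataset k-mer tally over sanitized segments, dict-based."""
    counts: Counter[str] = Counter()
    for seq in reads:
        seq = seq[1] if isinstance(seq, tuple) else seq
        for segment in sanitize(seq):
            s = segment.letters
            for i in range(len(s) - k + 1):
                counts[s[i : i + k]] += 1
    return counts


def pipeline_bins(reads, k: int, m: int, ordering):
    """Sanitize, split and bin a list of (read_id, seq) or raw strings."""
    supermers = []
    for rec in reads:
        read_id, seq = rec if isinstance(rec, tuple) else (None, rec)
        for segment in sanitize(seq):
            supermers.extend(split_supermers(segment, k, m, ordering, read_id))
    return bin_supermers(supermers)


@pytest.fixture
def toy_reads() -> list[tuple[str, str]]:
    return [
        ("r1", "ATGGCATGCA"),
        ("r2", "ACGTACGTACGT"),
        ("r3", "AAAAAAAAAA"),
        ("r4", "TTNNACGTGGNAC"),
    ]
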