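"""Per-bin k-mer counting and the abundance histogram.

Within each bin, super-mers are broken back into individual k-mers and
tallied exactly.  Because a k-mer's minimizer is a pure function of its
letters under a fixed ordering, all occurrences of one k-mer land in a
single bin; aggregating across bins is a disjoint union and never has to
merge counts of equal k-mers.  Reverse complements are NOT unified: the
counts for ACGT and its complement are separate entries.
"""

from __future__ import annotations

from collections import Counter
from pathlib import Path
from typing import Iterable, Mapping

from .supermers import SuperMer


class CorruptBinningError(RuntimeError):
    """The same k-mer surfaced from two bins — the binning pass is broken."""


def count_bin(bin_supermers: Iterable[SuperMer], k: int) -> Counter[str]:
    """Exact k-mer multiplicities of one bin's super-mers."""
    counts: Counter[str] = Counter()
    for sm in bin_supermers:
        letters = sm.letters
        for i in range(len(letters) - k + 1):
            counts[letters[i : i + k]] += 1
    return counts


def count_all(bins: Mapping[int, list[SuperMer]], k: int) -> Counter[str]:
    """Disjoint union of all per-bin count tables.

    Raises :class:`CorruptBinningError` if any k-mer appears in more than
    one bin, which cannot happen for a correct ordering-consistent pass.
    """
    merged: Counter[str] = Counter()
    for key in bins:
        table = count_bin(bins[key], k)
        for kmer, n in table.items():
            if kmer in merged:
                raise CorruptBinningError(
                    f"k-mer {kmer} found in multiple bins (second: {key})"
                )
            merged[kmer] = n
    return merged


def histogram(counts: Mapping[str, int]) -> Counter[int]:
    """Multiplicity -> number of distinct k-mers seen exactly that often."""
    hist: Counter[int] = Counter()
    for n in counts.values():
        hist[n] += 1
    return hist


def write_counts_tsv(
    counts: Mapping[str, int], path: str | Path, min_count: int = 1
) -> None:
    """``<kmer>\\t<count>`` rows, sorted lexicographically for reproducibility.

    ``min_count`` filters the output only; it never affects counting.
    """
    with open(path, "w") as fh:
        for kmer in sorted(counts):
            n = counts[kmer]
            if n >= min_count:
                fh.write(f"{kmer}\t{n}\n")


def write_histogram_tsv(hist: Mapping[int, int], path: str | Path) -> None:
    """``<multiplicity>\\t<distinct k-mers>`` rows in ascending multiplicity."""
    with open(path, "w") as fh:
        for mult in sorted(hist):
            fh.write(f"{mult}\t{hist[mult]}\n")
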