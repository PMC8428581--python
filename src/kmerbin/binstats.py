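"""Bin-distribution statistics for comparing minimizer orderings.

The minimizer-analysis mode summarizes each nonempty bin (super-mers,
distinct k-mers, total k-mers) and condenses a whole binning pass into a
small set of load-balance metrics: bin count, mean / max / stddev of bin
sizes, the max/mean ratio, the mean super-mer length in k-mers, and the
share of total k-mer mass held by the largest 0.5% of bins — the primary
evenness metric, since a few outsized bins dominate memory and runtime.

Bin size throughout means total k-mers (sum of super-mer k-mer counts)
before distinct-counting.  The standard deviation is the population form
(divide by N), and the "largest p%" is taken over nonempty bins with
ceiling rounding.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .counting import count_bin
from .supermers import SuperMer, bin_key_string


@dataclass(frozen=True)
class BinSummary:
    minimizer: str
    n_supermers: int
    n_distinct_kmers: int
    n_total_kmers: int


@dataclass(frozen=True)
class OrderingReport:
    """One comparison row for a single ordering on a single dataset."""

    n_bins: int
    mean: float
    max: int
    max_mean_ratio: float
    stddev: float
    avg_supermer_len_kmers: float
    top_fraction_pct: float


def summarize_bins(
    bins: Mapping[int, list[SuperMer]], k: int, m: int
) -> list[BinSummary]:
    """One row per nonempty bin, ordered by minimizer for determinism."""
    rows = []
    for code in sorted(bins):
        sms = bins[code]
        if not sms:
            continue
        total = sum(sm.kmer_count(k) for sm in sms)
        distinct = len(count_bin(sms, k))
        rows.append(BinSummary(bin_key_string(code, m), len(sms), distinct, total))
    return rows


def top_fraction(summaries: Sequence[BinSummary], pct: float = 0.5) -> float:
    """Percentage of total k-mer mass in the largest ``pct``% of bins."""
    if not 0 < pct < 100:
        raise ValueError("pct must be in (0, 100)")
    if not summaries:
        raise ValueError("no bins to summarize")
    sizes = np.sort(np.array([s.n_total_kmers for s in summaries]))[::-1]
    n_top = math.ceil(pct / 100 * len(sizes))
    return float(sizes[:n_top].sum() / sizes.sum() * 100.0)


def ordering_report(
    summaries: Sequence[BinSummary], k: int, top_pct: float = 0.5
) -> OrderingReport:
    """Condense bin summaries into the per-ordering comparison metrics."""
    if not summaries:
        raise ValueError("cannot report on an empty binning")
    sizes = np.array([s.n_total_kmers for s in summaries], dtype=np.float64)
    n_supermers = sum(s.n_supermers for s in summaries)
    mean = float(sizes.mean())
    return OrderingReport(
        n_bins=len(summaries),
        mean=mean,
        max=int(sizes.max()),
        max_mean_ratio=float(sizes.max() / mean),
        stddev=float(sizes.std()),  # population form
        avg_supermer_len_kmers=float(sizes.sum() / n_supermers),
        top_fraction_pct=top_fraction(summaries, top_pct),
    )


def density_points(summaries: Sequence[BinSummary]) -> list[tuple[int, float]]:
    """Raw bin-size sample for density plotting, one point per bin.

    Rows are ordered by (size, minimizer) so exports are deterministic;
    each point carries unit weight.
    """
    ordered = sorted(summaries, key=lambda s: (s.n_total_kmers, s.minimizer))
    return [(s.n_total_kmers, 1.0) for s in ordered]


def write_bin_stats_tsv(summaries: Sequence[BinSummary], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("minimizer\tsupermers\tdistinct\ttotal\n")
        for s in summaries:
            fh.write(
                f"{s.minimizer}\t{s.n_supermers}\t{s.n_distinct_kmers}"
                f"\t{s.n_total_kmers}\n"
            )


def write_report_tsv(report: OrderingReport, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("# stddev is the population standard deviation of bin sizes\n")
        fh.write("bins\tmean\tmax\tmax_mean\tstddev\tavg_supermer\ttop0.5pct\n")
        fh.write(
            f"{report.n_bins}\t{report.mean:.2f}\t{report.max}"
            f"\t{report.max_mean_ratio:.2f}\t{report.stddev:.2f}"
            f"\t{report.avg_supermer_len_kmers:.2f}"
            f"\t{report.top_fraction_pct:.2f}\n"
        )


def write_density_tsv(
    points: Sequence[tuple[int, float]], path: str | Path
) -> None:
    with open(path, "w") as fh:
        fh.write("bin_size\tweight\n")
        for size, weight in points:
            fh.write(f"{size}\t{weight}\n")
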