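"""Read ingestion and the single-machine pipeline driver.

FASTA and FASTQ inputs (optionally gzip-compressed) are auto-detected and
streamed through Biopython's parsers.  The pipeline runs the three logical
phases in sequence on one machine: an optional *sampling* pass estimating
minimizer frequencies from a fraction of the reads, a *hashing* pass
splitting reads into super-mers and grouping them into bins by minimizer,
and a *processing* pass that either counts k-mers per bin or summarizes
bin contents.  The sampling pass re-reads the input rather than caching
it, so inputs of arbitrary size stream in constant memory.

All randomized behaviour — read sampling, random orderings, toy universal
set generation — flows from the single configured seed.
"""

from __future__ import annotations

import gzip
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Sequence

from Bio import SeqIO

from .binstats import (
    density_points,
    ordering_report,
    summarize_bins,
    write_bin_stats_tsv,
    write_density_tsv,
    write_report_tsv,
)
from .codec import sanitize
from .counting import count_all, histogram, write_counts_tsv, write_histogram_tsv
from .orderings import (
    FrequencyTable,
    MinimizerOrdering,
    ORDERING_TOKENS,
    make_ordering,
    sample_frequencies,
)
from .supermers import SuperMer, split_supermers
from .uhs import UniversalSet, load_uhs

logger = logging.getLogger("kmerbin")

_GZIP_MAGIC = b"\x1f\x8b"


@dataclass
class RunConfig:
    """Configuration of one counting or analysis run."""

    k: int
    m: int
    inputs: Sequence[str | Path]
    ordering: str = "lex"
    sample_fraction: float = 0.01
    seed: int | None = None
    uhs_path: str | Path | None = None
    output_prefix: str = "kmerbin"
    min_count: int = 1
    write_counts: bool = True
    write_histogram: bool = False
    top_pct: float = 0.5
    outputs: dict[str, Path] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not 1 <= self.m <= self.k:
            raise ValueError(f"need k >= m >= 1, got k={self.k}, m={self.m}")
        if self.ordering not in ORDERING_TOKENS:
            raise ValueError(
                f"unknown ordering {self.ordering!r}; "
                f"expected one of {ORDERING_TOKENS}"
            )
        if self.ordering.startswith("u") and self.uhs_path is None:
            raise ValueError(
                f"ordering {self.ordering!r} requires a universal set file"
            )


def _open_text(path: Path):
    with open(path, "rb") as raw:
        magic = raw.read(2)
    if magic == _GZIP_MAGIC:
        return gzip.open(path, "rt")
    return open(path)


def read_sequences(paths: Sequence[str | Path]) -> Iterator[tuple[str, str]]:
    """Stream (read_id, raw sequence) records from FASTA/FASTQ files.

    The format is sniffed from the first byte ('>' FASTA, '@' FASTQ);
    gzip compression is transparent.  Quality lines are discarded and
    multi-line FASTA is supported.  An empty file logs a warning and
    yields nothing.
    """
    for path in paths:
        path = Path(path)
        if not path.exists():
            raise FileNotFoundError(path)
        with _open_text(path) as fh:
            first = fh.read(1)
            while first.isspace() and first:
                first = fh.read(1)
            if not first:
                logger.warning("empty input file: %s", path)
                continue
            if first == ">":
                fmt = "fasta"
            elif first == "@":
                fmt = "fastq"
            else:
                raise ValueError(
                    f"{path}: cannot detect format from first byte {first!r}"
                )
            fh.seek(0)
            index = 0
            try:
                for record in SeqIO.parse(fh, fmt):
                    index += 1
                    yield record.id, str(record.seq)
            except ValueError as exc:
                raise ValueError(
                    f"{path}: malformed record after record {index}: {exc}"
                ) from exc


def build_ordering(config: RunConfig) -> MinimizerOrdering:
    """Construct the configured ordering, running the sampling pass if needed."""
    freq_table: FrequencyTable | None = None
    universal: UniversalSet | None = None
    if config.ordering in ("freq", "ufreq"):
        t0 = time.perf_counter()
        freq_table = sample_frequencies(
            read_sequences(config.inputs),
            config.m,
            config.sample_fraction,
            config.seed,
        )
        logger.info(
            "sampling: %d distinct m-mers from %.1f%% of reads (%.2fs)",
            len(freq_table.counts),
            config.sample_fraction * 100,
            time.perf_counter() - t0,
        )
    if config.ordering.startswith("u"):
        universal = load_uhs(config.uhs_path, config.m, config.k)
        logger.info("universal set: %d members from %s", len(universal), universal.source)
    return make_ordering(
        config.ordering,
        config.m,
        seed=config.seed,
        freq_table=freq_table,
        uhs=universal,
    )


def hash_bins(
    config: RunConfig, ordering: MinimizerOrdering
) -> dict[int, list[SuperMer]]:
    """The hashing phase: sanitize, split into super-mers, group by minimizer."""
    t0 = time.perf_counter()
    bins: dict[int, list[SuperMer]] = {}
    n_reads = 0
    for read_id, seq in read_sequences(config.inputs):
        n_reads += 1
        for segment in sanitize(seq):
            for sm in split_supermers(segment, config.k, config.m, ordering, read_id):
                bins.setdefault(sm.minimizer, []).append(sm)
    logger.info(
        "hashing: %d reads into %d bins (%.2fs)",
        n_reads,
        len(bins),
        time.perf_counter() - t0,
    )
    return bins


def run_count(config: RunConfig) -> dict:
    """Counting mode: count k-mers per bin, write table and/or histogram."""
    ordering = build_ordering(config)
    bins = hash_bins(config, ordering)
    t0 = time.perf_counter()
    counts = count_all(bins, config.k)
    total = sum(counts.values())
    hist = histogram(counts)
    if config.write_counts:
        out = Path(f"{config.output_prefix}.counts.tsv")
        write_counts_tsv(counts, out, config.min_count)
        config.outputs["counts"] = out
    if config.write_histogram:
        out = Path(f"{config.output_prefix}.hist.tsv")
        write_histogram_tsv(hist, out)
        config.outputs["histogram"] = out
    logger.info(
        "processing: %d total / %d distinct k-mers in %d bins (%.2fs)",
        total,
        len(counts),
        len(bins),
        time.perf_counter() - t0,
    )
    return {
        "ordering": ordering.name,
        "total_kmers": total,
        "distinct_kmers": len(counts),
        "n_bins": len(bins),
    }


def run_stats(config: RunConfig) -> dict:
    """Minimizer-analysis mode: per-bin summaries and the ordering report."""
    ordering = build_ordering(config)
    bins = hash_bins(config, ordering)
    t0 = time.perf_counter()
    summaries = summarize_bins(bins, config.k, config.m)
    report = ordering_report(summaries, config.k, config.top_pct)
    points = density_points(summaries)
    prefix = config.output_prefix
    config.outputs["bins"] = Path(f"{prefix}.bins.tsv")
    config.outputs["report"] = Path(f"{prefix}.report.tsv")
    config.outputs["density"] = Path(f"{prefix}.density.tsv")
    write_bin_stats_tsv(summaries, config.outputs["bins"])
    write_report_tsv(report, config.outputs["report"])
    write_density_tsv(points, config.outputs["density"])
    logger.info(
        "analysis: %d bins, top %.1f%% holds %.2f%% of k-mers (%.2fs)",
        report.n_bins,
        config.top_pct,
        report.top_fraction_pct,
        time.perf_counter() - t0,
    )
    return {
        "ordering": ordering.name,
        "report": report,
        "n_bins": report.n_bins,
        "total_kmers": sum(s.n_total_kmers for s in summaries),
    }
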