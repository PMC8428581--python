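"""Seeded synthetic read generator with controllable composition skew.

Real sequencing data — metagenomes especially — contains low-complexity,
AT-rich repeat content that makes lexicographic minimizer binning very
uneven.  This generator emulates that single property with a simple
i.i.d.-base model into which a fixed motif is stochastically inserted:
each position block of a read is, with probability ``motif_rate``, a copy
of the motif, otherwise one base drawn from the composition weights.
Optional per-position N substitution exercises read sanitization, and a
duplicate-read probability exercises exact-repeat handling.  No attempt
is made to model sequencing errors, paired ends or community structure.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .codec import BASES


@dataclass(frozen=True)
class SynthSpec:
    """Parameters of one synthetic read set.

    Defaults describe a small skewed short-read set: 150 bp reads with 1%
    N positions and an AT-rich motif inserted often enough that a handful
    of A-rich minimizers dominate under lexicographic ordering.
    """

    n_reads: int = 1000
    read_length: int = 150
    seed: int = 0
    motif: str = "AAATAAAT"
    motif_rate: float = 0.0
    n_rate: float = 0.0
    base_weights: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)
    duplicate_rate: float = 0.0

    def __post_init__(self) -> None:
        if self.read_length < 1:
            raise ValueError("read_length must be >= 1")
        for name in ("motif_rate", "n_rate", "duplicate_rate"):
            rate = getattr(self, name)
            if not 0 <= rate <= 1:
                raise ValueError(f"{name} must be in [0, 1]")
        if any(c not in BASES for c in self.motif):
            raise ValueError("motif must be ACGT only")


def skewed_spec(seed: int = 0, n_reads: int = 2000) -> SynthSpec:
    """The canonical motif-skewed condition used for ordering comparisons."""
    return SynthSpec(
        n_reads=n_reads,
        read_length=150,
        seed=seed,
        motif="AAATAAAT",
        motif_rate=0.15,
        n_rate=0.01,
        duplicate_rate=0.02,
    )


def generate_read_list(spec: SynthSpec) -> list[tuple[str, str]]:
    """Generate (read_id, sequence) pairs, reproducible from the seed."""
    rng = np.random.default_rng(spec.seed)
    weights = np.asarray(spec.base_weights, dtype=float)
    weights = weights / weights.sum()
    reads: list[tuple[str, str]] = []
    for i in range(spec.n_reads):
        if reads and rng.random() < spec.duplicate_rate:
            seq = reads[-1][1]
        else:
            length = spec.read_length
            draws = rng.choice(4, size=length, p=weights)
            chars: list[str] = []
            j = 0
            while len(chars) < length:
                if spec.motif_rate and rng.random() < spec.motif_rate:
                    chars.extend(spec.motif)
                else:
                    chars.append(BASES[draws[j % length]])
                    j += 1
            chars = chars[:length]
            if spec.n_rate:
                mask = rng.random(length) < spec.n_rate
                chars = ["N" if mask[p] else c for p, c in enumerate(chars)]
            seq = "".join(chars)
        reads.append((f"read{i}", seq))
    return reads


def generate_reads(
    spec: SynthSpec, path: str | Path, fmt: str = "fasta"
) -> Path:
    """Write a generated read set to a FASTA or FASTQ file."""
    if fmt not in ("fasta", "fastq"):
        raise ValueError("fmt must be 'fasta' or 'fastq'")
    path = Path(path)
    with open(path, "w") as fh:
        for read_id, seq in generate_read_list(spec):
            if fmt == "fasta":
                fh.write(f">{read_id}\n{seq}\n")
            else:
                fh.write(f"@{read_id}\n{seq}\n+\n{'I' * len(seq)}\n")
    return path
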