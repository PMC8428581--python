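"""Universal k-mer hitting sets: loading, verification and construction.

A universal (m, k) hitting set is a set of m-mers such that every possible
ACGT string of length k contains at least one member as a substring.  Such
sets allow minimizer orderings that effectively exclude all non-members:
because every k-window is hit, ranking non-members strictly below members
guarantees the chosen minimizer is always a set member.

Large published sets (e.g. produced by the PASHA or DOCKS tools) are read
from plain-text files, one uppercase m-mer per line.  Two constructors are
provided for offline work: a greedy locally-minimal generator for toy
parameters where exhaustive verification is feasible, and a closed-form
"A-anchored" set that is valid for any m with k >= 2m - 1 and cheap to
build even at realistic minimizer lengths.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product
from pathlib import Path

import numpy as np

from .codec import BASES, decode_mer, encode_mer

_EXHAUSTIVE_K_CAP = 12


@dataclass(frozen=True)
class UniversalSet:
    """A set of m-mer codes declared to hit every k-length ACGT string."""

    members: frozenset[int]
    m: int
    k: int
    source: str = "generated"
    # sorted member codes, shared by vectorized membership tests
    _sorted: np.ndarray = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError("universal set must be nonempty")
        arr = np.fromiter(self.members, dtype=np.uint64, count=len(self.members))
        object.__setattr__(self, "_sorted", np.sort(arr))

    def __len__(self) -> int:
        return len(self.members)

    def __contains__(self, code: int) -> bool:
        return code in self.members

    def contains_array(self, codes: np.ndarray) -> np.ndarray:
        """Vectorized membership test for an array of m-mer codes."""
        idx = np.searchsorted(self._sorted, codes)
        idx = np.minimum(idx, len(self._sorted) - 1)
        return self._sorted[idx] == codes

    def member_strings(self) -> list[str]:
        return sorted(decode_mer(int(c), self.m) for c in self.members)


def load_uhs(path: str | Path, m: int, k: int) -> UniversalSet:
    """Load a plain-text universal set (one m-mer per line, PASHA style).

    Blank lines are ignored and duplicates collapse; a line of the wrong
    length or with a non-ACGT character is rejected with its line number.
    """
    path = Path(path)
    members: set[int] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            word = line.strip()
            if not word:
                continue
            if len(word) != m:
                raise ValueError(
                    f"{path}:{lineno}: expected an m-mer of length {m}, "
                    f"got {word!r}"
                )
            try:
                members.add(encode_mer(word).code)
            except ValueError:
                raise ValueError(
                    f"{path}:{lineno}: non-ACGT character in {word!r}"
                ) from None
    if not members:
        raise ValueError(f"{path}: empty universal set file")
    return UniversalSet(frozenset(members), m, k, source=str(path))


def save_uhs(uhs: UniversalSet, path: str | Path) -> None:
    """Write the set in the same one-m-mer-per-line plain-text format."""
    with open(path, "w") as fh:
        for word in uhs.member_strings():
            fh.write(word + "\n")


def _window_code_arrays(m: int, k: int) -> list[np.ndarray]:
    """For every k-string code 0..4^k-1, the m-mer code at each position."""
    all_k = np.arange(4 ** k, dtype=np.uint64)
    mask = np.uint64(4 ** m - 1)
    return [
        (all_k >> np.uint64(2 * (k - m - pos))) & mask
        for pos in range(k - m + 1)
    ]


def verify_uhs(
    uhs: UniversalSet,
    mode: str = "exhaustive",
    seed: int | None = None,
    n_samples: int = 100_000,
) -> tuple[bool, str | None]:
    """Check the hitting property; returns (ok, first failing k-string).

    ``exhaustive`` enumerates all 4^k strings (k <= 12); ``sampled`` draws
    random k-strings from a seeded generator.
    """
    m, k = uhs.m, uhs.k
    if mode == "exhaustive":
        if k > _EXHAUSTIVE_K_CAP:
            raise ValueError(
                f"exhaustive verification limited to k <= {_EXHAUSTIVE_K_CAP}"
            )
        hit = np.zeros(4 ** k, dtype=bool)
        for win in _window_code_arrays(m, k):
            hit |= uhs.contains_array(win)
        if hit.all():
            return True, None
        witness = int(np.flatnonzero(~hit)[0])
        return False, decode_mer(witness, k)
    if mode == "sampled":
        rng = np.random.default_rng(seed)
        for _ in range(n_samples):
            vals = rng.integers(0, 4, size=k)
            s = "".join(BASES[v] for v in vals)
            if not any(
                encode_mer(s[i : i + m]).code in uhs.members
                for i in range(k - m + 1)
            ):
                return False, s
        return True, None
    raise ValueError(f"unknown verification mode: {mode!r}")


def generate_small_uhs(m: int, k: int, seed: int | None = None) -> UniversalSet:
    """Greedy locally-minimal universal set for toy parameters.

    Starts from all 4^m m-mers and repeatedly removes any member whose
    removal keeps every k-string hit, in a seed-shuffled order, until no
    single removal is possible.  The result always passes exhaustive
    verification and is locally minimal (removing any one member breaks
    the hitting property).  Feasibility requires m <= 6 and k <= 12.
    """
    if m > 6 or k > _EXHAUSTIVE_K_CAP:
        raise ValueError("greedy generation limited to m <= 6, k <= 12")
    if k < m:
        raise ValueError("k must be >= m")
    wins = _window_code_arrays(m, k)
    # per k-string count of member-occurrences; removal of x is legal iff
    # no k-string is covered exclusively by occurrences of x
    cover = np.zeros(4 ** k, dtype=np.int64)
    for win in wins:
        cover += 1  # every m-mer starts as a member
    members = set(range(4 ** m))
    order = np.arange(4 ** m)
    np.random.default_rng(seed).shuffle(order)
    for x in order:
        x64 = np.uint64(int(x))
        occ = np.zeros(4 ** k, dtype=np.int64)
        for win in wins:
            occ += win == x64
        if np.all(cover - occ > 0):
            cover -= occ
            members.discard(int(x))
    return UniversalSet(frozenset(members), m, k, source="generated:greedy")


def anchor_uhs(m: int, k: int) -> UniversalSet:
    """Closed-form universal set: m-mers starting with A, plus A-free m-mers.

    Valid whenever k >= 2m - 1.  Proof sketch: take any k-string.  If some
    m-window of it contains no A, that window is a member.  Otherwise every
    m-window contains an A; in particular the leftmost window does, so the
    leftmost A sits at position p <= m - 1 <= k - m, and the m-mer starting
    at p begins with A and is a member.  Size is 4^(m-1) + 3^m, far from
    optimal but deterministic and instant at any practical m.
    """
    if k < 2 * m - 1:
        raise ValueError("anchored construction requires k >= 2m - 1")
    members: set[int] = set(range(4 ** (m - 1)))  # code < 4^(m-1) <=> leading A
    if m == 1:
        members = {0, 1, 2, 3}
    else:
        for digits in product((1, 2, 3), repeat=m):
            code = 0
            for d in digits:
                code = (code << 2) | d
            members.add(code)
    return UniversalSet(frozenset(members), m, k, source="generated:anchor")
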