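"""Minimizer orderings: class rules, sampling, totality, determinism."""

import numpy as np
import pytest

from kmerbin.codec import encode_mer
from kmerbin.orderings import (
    FrequencyTable,
    ORDERING_TOKENS,
    frequency_ordering,
    lexicographic_ordering,
    make_ordering,
    random_ordering,
    sample_frequencies,
    signature_ordering,
    universal_restriction,
)
from kmerbin.supermers import split_supermers
from kmerbin.synth import SynthSpec, generate_read_list
from kmerbin.uhs import UniversalSet, generate_small_uhs


def rank_of(ordering, s: str) -> int:
    return ordering.rank(encode_mer(s).code)


class TestLexicographic:
    def test_basic_order(self):
        o = lexicographic_ordering(3)
        assert rank_of(o, "AAA") < rank_of(o, "AAC")
        assert max(rank_of(o, x) for x in ("AAA", "CGT", "TTA")) < rank_of(o, "TTT")

    def test_bijective_over_all_mmers(self):
        o = lexicographic_ordering(2)
        ranks = sorted(o.rank(c) for c in range(16))
        assert ranks == list(range(16))

    def test_m_range_enforced(self):
        with pytest.raises(ValueError):
            lexicographic_ordering(0)
        with pytest.raises(ValueError):
            lexicographic_ordering(16)


class TestSignature:
    @pytest.mark.parametrize(
        "mmer", ["AAACG", "ACATG", "CGAAT", "TTTAA", "GGAAG"]
    )
    def test_disallowed_examples(self, mmer):
        """AAA/ACA prefixes and internal AA are demoted."""
        o = signature_ordering(5)
        assert rank_of(o, mmer) > rank_of(o, "TTTTT")

    @pytest.mark.parametrize("mmer", ["AATGC", "ACGTC", "TGCAT", "CACAC"])
    def test_allowed_examples(self, mmer):
        """AA at the very start only is allowed."""
        o = signature_ordering(5)
        assert rank_of(o, mmer) < rank_of(o, "AAACG")

    def test_allowed_class_ranks_before_disallowed(self):
        o = signature_ordering(3)
        codes = np.arange(64, dtype=np.uint64)
        keys = o.rank_array(codes)
        bad = o._disallowed(codes)
        assert keys[bad].min() > keys[~bad].max()

    def test_requires_m_at_least_3(self):
        with pytest.raises(ValueError):
            signature_ordering(2)


class TestRandom:
    def test_zero_constant_degenerates_to_lexicographic(self):
        o = random_ordering(4, seed=0)
        o.constant = 0
        codes = np.arange(256, dtype=np.uint64)
        assert np.array_equal(o.rank_array(codes), codes)

    def test_bijection_and_seed_determinism(self):
        a = random_ordering(3, seed=11)
        b = random_ordering(3, seed=11)
        c = random_ordering(3, seed=12)
        keys = a.rank_array(np.arange(64, dtype=np.uint64))
        assert len(np.unique(keys)) == 64
        assert a.constant == b.constant
        assert c.constant != a.constant

    def test_same_seed_same_supermer_decomposition(self):
        seq = "ACGTTGCAGGATCCATGCAAT"
        sm1 = split_supermers(seq, 7, 3, random_ordering(3, seed=5))
        sm2 = split_supermers(seq, 7, 3, random_ordering(3, seed=5))
        assert sm1 == sm2


class TestSampling:
    def test_full_fraction_counts_every_occurrence(self):
        table = sample_frequencies(["ACGT"], 2, 1.0, seed=0)
        assert table.counts == {
            encode_mer("AC").code: 1,
            encode_mer("CG").code: 1,
            encode_mer("GT").code: 1,
        }

    def test_overlapping_occurrences_counted(self):
        table = sample_frequencies(["AAAA"], 2, 1.0, seed=0)
        assert table.counts == {0: 3}

    def test_full_fraction_matches_naive_oracle(self):
        reads = [seq for _, seq in generate_read_list(
            SynthSpec(n_reads=30, read_length=60, seed=3, n_rate=0.02)
        )]
        m = 3
        table = sample_frequencies(reads, m, 1.0, seed=9)
        from kmerbin.codec import sanitize
        naive = {}
        for seq in reads:
            for seg in sanitize(seq):
                s = seg.letters
                for i in range(len(s) - m + 1):
                    c = encode_mer(s[i : i + m]).code
                    naive[c] = naive.get(c, 0) + 1
        assert table.counts == naive

    def test_seed_determinism_and_fraction_validation(self):
        reads = ["ACGTACGTAA"] * 50
        t1 = sample_frequencies(reads, 2, 0.3, seed=4)
        t2 = sample_frequencies(reads, 2, 0.3, seed=4)
        assert t1.counts == t2.counts
        with pytest.raises(ValueError):
            sample_frequencies(reads, 2, 0.0, seed=1)
        with pytest.raises(ValueError):
            sample_frequencies(reads, 2, 1.5, seed=1)


class TestFrequency:
    def test_rare_before_common_with_lexicographic_ties(self):
        counts = {
            encode_mer("AC").code: 10,
            encode_mer("GG").code: 2,
            encode_mer("TT").code: 10,
        }
        o = frequency_ordering(FrequencyTable(counts, 2, 1.0))
        assert rank_of(o, "GG") < rank_of(o, "AC") < rank_of(o, "TT")

    def test_unseen_rank_before_seen_lexicographically(self):
        counts = {encode_mer("AA").code: 5}
        o = frequency_ordering(FrequencyTable(counts, 2, 1.0))
        unseen = [rank_of(o, s) for s in ("AC", "TT")]
        assert max(unseen) < rank_of(o, "AA")
        assert rank_of(o, "AC") < rank_of(o, "AG") < rank_of(o, "TT")

    def test_equal_counts_degenerate_to_lexicographic(self):
        counts = {c: 7 for c in range(16)}
        o = frequency_ordering(FrequencyTable(counts, 2, 1.0))
        keys = o.rank_array(np.arange(16, dtype=np.uint64))
        assert np.array_equal(np.argsort(keys), np.arange(16))

    def test_rank_nondecreasing_in_sampled_count(self):
        """Sorting m-mers by rank must sort them by count (skewed data)."""
        reads = [seq for _, seq in generate_read_list(
            SynthSpec(n_reads=40, read_length=80, seed=1,
                      motif="AAATAAAT", motif_rate=0.3)
        )]
        table = sample_frequencies(reads, 3, 1.0, seed=0)
        o = frequency_ordering(table)
        codes = np.arange(64, dtype=np.uint64)
        order = np.argsort(o.rank_array(codes))
        cnts = [table.counts.get(int(c), 0) for c in codes[order]]
        assert cnts == sorted(cnts)
        # the dominant motif m-mer has low priority (high rank)
        aaa = encode_mer("AAA").code
        assert o.rank(aaa) > np.median(o.rank_array(codes))


class TestUniversalRestriction:
    def test_full_set_equals_base(self):
        base = lexicographic_ordering(2)
        full = UniversalSet(frozenset(range(16)), 2, 4)
        o = universal_restriction(base, full)
        codes = np.arange(16, dtype=np.uint64)
        assert np.array_equal(o.rank_array(codes), base.rank_array(codes))

    def test_member_always_ranks_before_nonmember(self):
        base = lexicographic_ordering(3)
        uhs = generate_small_uhs(3, 6, seed=0)
        o = universal_restriction(base, uhs)
        keys = o.rank_array(np.arange(64, dtype=np.uint64))
        member = np.array([c in uhs.members for c in range(64)])
        assert keys[member].max() < keys[~member].min()

    def test_m_mismatch_rejected(self):
        with pytest.raises(ValueError):
            universal_restriction(
                lexicographic_ordering(3),
                UniversalSet(frozenset({0}), 2, 4),
            )


class TestTotality:
    @pytest.mark.parametrize("m", [2, 3, 5, 8])
    def test_every_ordering_is_injective_exhaustively(self, m):
        """All 4^m rank keys are distinct for every ordering token."""
        uhs = generate_small_uhs(2, 4, seed=0) if m == 2 else None
        table = FrequencyTable({1: 3, 2: 3, 5: 1}, m, 1.0)
        orderings = [
            lexicographic_ordering(m),
            random_ordering(m, seed=7),
            frequency_ordering(table),
        ]
        if m >= 3:
            orderings.append(signature_ordering(m))
        if uhs is not None:
            orderings.append(universal_restriction(lexicographic_ordering(2), uhs))
        codes = np.arange(4 ** m, dtype=np.uint64)
        for o in orderings:
            assert len(np.unique(o.rank_array(codes))) == 4 ** m, o.name


def test_make_ordering_token_dispatch_and_validation():
    table = FrequencyTable({0: 1}, 3, 1.0)
    uhs = generate_small_uhs(3, 6, seed=1)
    for token in ORDERING_TOKENS:
        o = make_ordering(token, 3, seed=2, freq_table=table, uhs=uhs)
        assert o.m == 3
    with pytest.raises(ValueError):
        make_ordering("freq", 3)
    with pytest.raises(ValueError):
        make_ordering("ulex", 3)
    with pytest.raises(ValueError):
        make_ordering("mystery", 3)
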