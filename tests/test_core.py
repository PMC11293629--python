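"""The chaos-game encoders against hand traces, oracles and invariants."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pcmer import (
    BREAK_SYMBOL,
    SCHEMES,
    WalkState,
    brute_force_binary_kmer_counts,
    cgr_step,
    encode_fcgr,
    encode_pcmer,
    fcgr_feature_count,
    group_collapse,
    pcmer_feature_count,
    transform_sequence,
)
from conftest import random_dna

dna = st.text(alphabet="ACGT", min_size=1, max_size=200)


class TestSchemes:
    def test_three_schemes_partition_acgt_into_pairs(self):
        for scheme in SCHEMES:
            lows = {b for b, s in scheme.nucleotide_map.items() if s == scheme.low_symbol}
            highs = {b for b, s in scheme.nucleotide_map.items() if s == scheme.high_symbol}
            assert len(lows) == len(highs) == 2
            assert lows | highs == set("ACGT")

    @pytest.mark.parametrize(
        "seq,scheme_idx,expected",
        [
            ("ATCGTA", 0, "RYYRYR"),  # ring structure on the worked demo input
            ("AAAA", 1, "MMMM"),
            ("ATCGTA", 1, "MKMKKM"),
            ("ATCGTA", 2, "WWSSWW"),
        ],
    )
    def test_transform_sequence(self, seq, scheme_idx, expected):
        assert transform_sequence(seq, SCHEMES[scheme_idx]) == expected

    def test_ambiguity_codes_become_break_sentinel(self):
        for scheme in SCHEMES:
            out = transform_sequence("ACNGT", scheme)
            assert len(out) == 5
            assert out[2] == BREAK_SYMBOL
            assert BREAK_SYMBOL not in out[:2] + out[3:]


class TestCgrStep:
    @pytest.mark.parametrize(
        "k,index,endpoint,expected",
        [(2, 2, 0, 1), (2, 1, 4, 3), (3, 8, 8, 8), (2, 4, 4, 4)],
    )
    def test_hand_traced_updates(self, k, index, endpoint, expected):
        # independent arithmetic oracle: ceil((index + endpoint)/2)
        assert math.ceil((index + endpoint) / 2) == expected
        assert cgr_step(WalkState(index=index, k=k), endpoint).index == expected

    def test_bad_endpoint_rejected(self):
        with pytest.raises(ValueError):
            cgr_step(WalkState(index=1, k=2), 3)

    @given(st.integers(1, 8), st.data())
    @settings(max_examples=50, deadline=None)
    def test_index_stays_in_range_under_any_walk(self, k, data):
        state = WalkState.initial(k)
        for _ in range(data.draw(st.integers(1, 50))):
            endpoint = data.draw(st.sampled_from([0, 1 << k]))
            state = cgr_step(state, endpoint)
            assert 1 <= state.index <= (1 << k)


class TestEncodePcmer:
    def test_two_base_walk_hand_trace(self):
        prof = encode_pcmer("AC", 2, "all_positions")
        assert [c.tolist() for c in prof.counts] == [
            [1, 0, 1, 0],  # purine-pyrimidine: A lands cell 1, C cell 3
            [2, 0, 0, 0],  # amino-keto: both symbols low, absorbing cell 1
            [0, 1, 1, 0],  # weak-strong: A high (cell 3) then C low (cell 2)
        ]

    def test_homopolymer_saturates_absorbing_cell(self):
        prof = encode_pcmer("AAAA", 1, "all_positions")
        assert [c.tolist() for c in prof.counts] == [[4, 0], [4, 0], [0, 4]]

    def test_demo_sequence_matches_binary_kmer_counts(self):
        prof = encode_pcmer("ATCGTA", 2, "kmer_only")
        for i, scheme in enumerate(SCHEMES):
            transformed = transform_sequence("ATCGTA", scheme)
            expected = brute_force_binary_kmer_counts(transformed, 2)
            np.testing.assert_array_equal(prof.counts[i], expected)

    @pytest.mark.parametrize("k", range(1, 9))
    def test_oracle_equivalence_kmer_only(self, rng, k):
        """Chaos-game cells are exactly binary k-mer counts, all schemes."""
        for _ in range(20):
            seq = random_dna(rng, int(rng.integers(50, 501)))
            prof = encode_pcmer(seq, k, "kmer_only")
            for i, scheme in enumerate(SCHEMES):
                oracle = brute_force_binary_kmer_counts(
                    transform_sequence(seq, scheme), k
                )
                np.testing.assert_array_equal(prof.counts[i], oracle)

    @given(dna, st.integers(1, 8))
    @settings(max_examples=60, deadline=None)
    def test_conservation(self, seq, k):
        """Each vector sums to l_S (all_positions) or l_S-k+1 (kmer_only)."""
        full = encode_pcmer(seq, k, "all_positions")
        assert all(c.sum() == len(seq) for c in full.counts)
        assert full.positions_counted == len(seq)
        km = encode_pcmer(seq, k, "kmer_only")
        expected = max(len(seq) - k + 1, 0)
        assert all(c.sum() == expected for c in km.counts)
        assert km.positions_counted == expected

    def test_break_splits_sequence_and_restarts_walk(self):
        # "ACGT" + N + "ACGT" must count k-mers of the two halves only
        prof = encode_pcmer("ACGTNACGT", 3, "kmer_only")
        halves = encode_pcmer("ACGT", 3, "kmer_only")
        for a, b in zip(prof.counts, halves.counts):
            np.testing.assert_array_equal(a, 2 * b)
        assert prof.positions_counted == 4  # 2 segments x (4 - 3 + 1)

    def test_all_positions_skips_ambiguous_positions(self):
        prof = encode_pcmer("ACNGT", 2, "all_positions")
        assert prof.positions_counted == 4

    def test_determinism(self, rng):
        seq = random_dna(rng, 300)
        a, b = encode_pcmer(seq, 5), encode_pcmer(seq, 5)
        for x, y in zip(a.concat(), b.concat()):
            assert x == y

    def test_rejects_bad_inputs(self):
        with pytest.raises(ValueError):
            encode_pcmer("", 3)
        with pytest.raises(ValueError):
            encode_pcmer("ACGT", 0)
        with pytest.raises(ValueError):
            encode_pcmer("ACGT", 25)


class TestBruteForceOracle:
    def test_exhaustive_k2_enumeration(self):
        """All four 2-symbol walks land where the window formula says."""
        # (prev, last) -> cell: LL->1, HL->2, LH->3, HH->4
        expected_cell = {"RR": 1, "YR": 2, "RY": 3, "YY": 4}
        for word, cell in expected_cell.items():
            counts = brute_force_binary_kmer_counts(word, 2)
            assert counts[cell - 1] == 1 and counts.sum() == 1
            # cross-check against the walk itself
            state = WalkState.initial(2)
            for ch in word:
                state = cgr_step(state, 4 if ch == "Y" else 0)
            assert state.index == cell

    def test_uniform_window_count(self):
        counts = brute_force_binary_kmer_counts("RRRR", 2)
        assert counts[0] == 3 and counts.sum() == 3

    def test_short_string_gives_zero_vector(self):
        assert brute_force_binary_kmer_counts("R", 3).sum() == 0

    @given(st.text(alphabet="MK", min_size=1, max_size=100), st.integers(1, 6))
    @settings(max_examples=50, deadline=None)
    def test_total_equals_window_count(self, s, k):
        assert brute_force_binary_kmer_counts(s, k).sum() == max(len(s) - k + 1, 0)


class TestFcgrAndCollapse:
    def test_single_bases_k1(self):
        prof = encode_fcgr("ACGT", 1)
        assert prof.counts.tolist() == [1, 1, 1, 1]

    def test_counts_match_naive_dictionary(self, rng):
        seq = random_dna(rng, 200)
        k = 3
        prof = encode_fcgr(seq, k, "kmer_only")
        naive = np.zeros(4**k, dtype=int)
        for j in range(len(seq) - k + 1):
            naive[prof.kmer_index(seq[j : j + k])] += 1
        np.testing.assert_array_equal(prof.counts, naive)

    def test_kmer_index_is_bijective(self):
        prof = encode_fcgr("ACGT", 2)
        from itertools import product

        indices = {prof.kmer_index("".join(w)) for w in product("ACGT", repeat=2)}
        assert indices == set(range(16))

    def test_k1_collapse_is_pairwise_base_sum(self, rng):
        seq = random_dna(rng, 150)
        collapsed = group_collapse(encode_fcgr(seq, 1, "kmer_only"))
        count = {b: seq.count(b) for b in "ACGT"}
        assert collapsed.counts[0].tolist() == [
            count["A"] + count["G"], count["C"] + count["T"]]
        assert collapsed.counts[1].tolist() == [
            count["A"] + count["C"], count["G"] + count["T"]]
        # weak_strong low symbol is S = {C,G}, so the low cell comes first
        assert collapsed.counts[2].tolist() == [
            count["C"] + count["G"], count["A"] + count["T"]]

    @pytest.mark.parametrize("k", range(1, 7))
    def test_collapse_equals_direct_encoding(self, rng, k):
        """Summing grouped 4-letter k-mers reproduces the binary encoding."""
        for _ in range(5):
            seq = random_dna(rng, 500)
            collapsed = group_collapse(encode_fcgr(seq, k, "kmer_only"))
            direct = encode_pcmer(seq, k, "kmer_only")
            for a, b in zip(collapsed.counts, direct.counts):
                np.testing.assert_array_equal(a, b)

    def test_all_zero_fcgr_collapses_to_zero(self):
        prof = encode_fcgr("ACG", 4, "kmer_only")  # shorter than k: zero counts
        assert prof.counts.sum() == 0
        collapsed = group_collapse(prof)
        assert all(c.sum() == 0 for c in collapsed.counts)

    def test_collapse_requires_kmer_only(self):
        with pytest.raises(ValueError):
            group_collapse(encode_fcgr("ACGT", 2, "all_positions"))


class TestFeatureSizeLaw:
    def test_concatenated_profile_lengths(self):
        assert len(encode_pcmer("ACGT", 4).concat()) == 3 * 2**4
        assert len(encode_fcgr("ACGT", 4).counts) == 4**4

    @pytest.mark.parametrize("k", [1, 4, 7, 12, 24])
    def test_size_accounting(self, k):
        assert pcmer_feature_count(k) == 3 * 2**k
        if k <= 12:
            assert fcgr_feature_count(k) == 4**k

    def test_normalized_profile_sums_to_three(self):
        prof = encode_pcmer("ACGTACGT", 3).normalize()
        assert prof.normalized
        assert np.isclose(prof.concat().sum(), 3.0)
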