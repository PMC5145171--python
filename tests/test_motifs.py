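"""Common-pattern discovery: enumeration, search strategies, classification."""

import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from chemseq import (
    STANDARD_RESIDUES,
    classify_patterns,
    encode_sequence,
    enumerate_norepeat_patterns,
    find_common_patterns,
    locate_pattern,
    maximal_common_pattern,
)
from conftest import brute_force_common

proteins = st.lists(
    st.text(alphabet=sorted(STANDARD_RESIDUES), min_size=5, max_size=200),
    min_size=1, max_size=10)


def _encs(strings):
    return [encode_sequence(f"s{i}", s) for i, s in enumerate(strings)]


class TestEnumerateNorepeat:
    @pytest.mark.parametrize("L", range(1, 9))
    def test_count_is_falling_factorial(self, L):
        pats = enumerate_norepeat_patterns(L)
        assert len(pats) == math.perm(8, L)
        assert len(set(pats)) == len(pats)
        assert pats == sorted(pats)  # lexicographic
        assert all(len(set(p)) == L for p in pats)

    @pytest.mark.parametrize("L", [0, 9, -3])
    def test_impossible_lengths_rejected(self, L):
        with pytest.raises(ValueError):
            enumerate_norepeat_patterns(L)


class TestFindCommonPatterns:
    def test_shared_trimer_with_positions(self):
        cps = find_common_patterns(_encs(["DRS", "ADRS"]), 3, "norepeat")
        assert cps.patterns == ["127"]
        assert cps.hits["127"] == {"s0": [1], "s1": [2]}

    def test_repeat_mode_finds_repeated_digits(self):
        cps = find_common_patterns(_encs(["DDRD", "ADDRD"]), 4, "repeat")
        assert cps.patterns == ["1121"]
        assert cps.hits["1121"] == {"s0": [1], "s1": [2]}

    @pytest.mark.parametrize("mode", ["norepeat", "repeat"])
    def test_disjoint_pairs_share_nothing(self, mode):
        cps = find_common_patterns(_encs(["DR", "RD"]), 2, mode)
        assert len(cps) == 0

    def test_length_beyond_shortest_sequence_is_empty(self):
        cps = find_common_patterns(_encs(["DRS", "ADRS"]), 10, "repeat")
        assert len(cps) == 0

    def test_norepeat_rejects_length_over_eight(self):
        with pytest.raises(ValueError):
            find_common_patterns(_encs(["DRS"]), 9, "norepeat")

    def test_overlapping_occurrences_all_reported(self):
        # DDD -> 111: '11' occurs at 1 and 2
        cps = find_common_patterns(_encs(["DDD"]), 2, "repeat")
        assert cps.hits["11"] == {"s0": [1, 2]}

    @given(proteins, st.integers(min_value=2, max_value=6))
    @settings(max_examples=40)
    def test_oracle_equivalence_all_strategies(self, strings, L):
        """Every search strategy returns exactly the brute-force
        substring-intersection set, filtered by the mode constraint."""
        encs = _encs(strings)
        oracle = brute_force_common([e.digits for e in encs], L)
        repeat = find_common_patterns(encs, L, "repeat")
        assert set(repeat.patterns) == oracle
        norepeat = find_common_patterns(encs, L, "norepeat")
        assert set(norepeat.patterns) == {p for p in oracle
                                          if len(set(p)) == L}
        enum = find_common_patterns(encs, L, "norepeat",
                                    strategy="enumerate")
        assert set(enum.patterns) == set(norepeat.patterns)
        if L >= 4:
            grown = find_common_patterns(encs, L, "repeat", strategy="grow")
            assert set(grown.patterns) == oracle

    def test_seeded_growth_with_remainder_matches_oracle(self):
        # L = 7 exercises q = 1 growth round plus an r = 3 tail
        strings = ["MDDRDKSSTDDRDKS", "ADDRDKSSTQ", "DDRDKSSTW"]
        encs = _encs(strings)
        oracle = brute_force_common([e.digits for e in encs], 7)
        grown = find_common_patterns(encs, 7, "repeat", strategy="grow")
        assert set(grown.patterns) == oracle and oracle

    @given(proteins, st.integers(min_value=2, max_value=5))
    @settings(max_examples=30)
    def test_apriori_prefix_and_suffix_of_longer_patterns(self, strings, L):
        encs = _encs(strings)
        shorter = set(find_common_patterns(encs, L, "repeat").patterns)
        longer = find_common_patterns(encs, L + 1, "repeat").patterns
        for p in longer:
            assert p[:-1] in shorter and p[1:] in shorter

    @given(proteins, st.integers(min_value=2, max_value=6))
    @settings(max_examples=30)
    def test_norepeat_nested_in_repeat(self, strings, L):
        encs = _encs(strings)
        nr = set(find_common_patterns(encs, L, "norepeat").patterns)
        rep = set(find_common_patterns(encs, L, "repeat").patterns)
        assert nr <= rep


class TestMaximalCommonPattern:
    def test_single_sequence_is_its_own_maximal_pattern(self):
        L, cps = maximal_common_pattern(_encs(["DRSMYI"]), "norepeat")
        assert L == 6
        assert cps.patterns == ["127634"]

    def test_norepeat_capped_at_eight(self):
        s = "DRSMYIPQ"  # 12763458, all eight digits once
        L, cps = maximal_common_pattern(_encs([s + s]), "norepeat")
        assert L == 8

    def test_no_shared_digit_gives_zero(self):
        L, cps = maximal_common_pattern(_encs(["DDD", "KKK"]), "repeat")
        assert L == 0 and len(cps) == 0

    @pytest.mark.parametrize("mode", ["norepeat", "repeat"])
    def test_monotonicity_nothing_common_above_lmax(self, mode, rng):
        from conftest import random_protein
        encs = _encs([random_protein(rng, 60) for _ in range(4)])
        L, cps = maximal_common_pattern(encs, mode)
        assert (len(cps) > 0) == (L > 0)
        for above in (L + 1, L + 2):
            if mode == "norepeat" and above > 8:
                continue
            assert len(find_common_patterns(encs, above, mode)) == 0


class TestLocatePattern:
    def test_overlap_scan_with_residue_blocks(self):
        hits = locate_pattern("127", encode_sequence("s", "ADRSDRS"))
        assert [(h.position, h.residue_block) for h in hits] == \
            [(2, "DRS"), (5, "DRS")]

    def test_absent_pattern_empty(self):
        assert locate_pattern("88", encode_sequence("s", "DRSMYI")) == []

    def test_empty_pattern_rejected(self):
        with pytest.raises(ValueError):
            locate_pattern("", encode_sequence("s", "DRS"))

    def test_hits_reencode_to_pattern(self):
        enc = encode_sequence("s", "MDDRDKSSTDDRDK")
        for h in locate_pattern("112", enc):
            assert encode_sequence("x", h.residue_block).digits == "112"


class TestClassifyPatterns:
    def test_two_mer_toy_partition(self):
        encs = _encs(["DRS", "ADRS", "RSD"])  # digits 127, 4127, 271
        res = classify_patterns(encs, ["s0", "s1"], ["s2"], 2, "norepeat")
        assert res.common_all.patterns == ["27"]
        assert res.a_only.patterns == ["12"]
        assert res.b_only.patterns == ["71"]

    def test_three_sets_pairwise_disjoint(self, rng):
        from conftest import random_protein
        encs = _encs([random_protein(rng, 80) for _ in range(6)])
        ids = [e.seq_id for e in encs]
        res = classify_patterns(encs, ids[:3], ids[3:], 2, "repeat")
        sets = [set(res.common_all.patterns), set(res.a_only.patterns),
                set(res.b_only.patterns)]
        assert not (sets[0] & sets[1] or sets[0] & sets[2]
                    or sets[1] & sets[2])

    @pytest.mark.parametrize("a, b", [
        (["s0"], ["s0", "s1"]),   # overlap
        (["s0"], ["s1"]),         # does not cover s2
        ([], ["s0", "s1", "s2"]),  # empty subset
    ])
    def test_invalid_partition_rejected(self, a, b):
        encs = _encs(["DRS", "ADRS", "RSD"])
        with pytest.raises(ValueError):
            classify_patterns(encs, a, b, 2, "norepeat")
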