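"""The search layer: per-centre enumeration and the full exhaustive search."""

import itertools

import pytest
from hypothesis import given, settings, strategies as st

import invrep as iv
from naive_oracles import (
    is_maximal,
    mirror_ir,
    naive_mismatch_offsets,
    validate_ir,
)


def _params(m=1, M=100, g=100, k=0, scheme="degenerate"):
    return iv.SearchParams(m, M, g, k, scheme)


def test_single_perfect_palindrome():
    irs = iv.find_inverted_repeats("AAATTT", _params(m=3))
    assert irs == [iv.InvertedRepeat(0, 3, 3, 6, 0)]


def test_self_reverse_complementary_tetramer():
    irs = iv.find_inverted_repeats("ACGT", _params(m=2, g=0))
    assert irs == [iv.InvertedRepeat(0, 2, 2, 4, 0)]


def test_homopolymer_has_no_irs():
    # A never complements A, under either scheme
    for scheme in ("simple", "degenerate"):
        assert iv.find_inverted_repeats("A" * 40, _params(scheme=scheme)) == []


def test_mismatch_offsets_match_naive_scan_on_every_centre():
    seq = iv.DegenerateSequence("printed", "CTCGCAGTCACCGGA")
    idx = iv.IndexedSequence(seq)
    for scheme in ("simple", "degenerate"):
        matrix = iv.build_match_matrix(scheme)
        for tc in range(2 * len(seq) - 1):
            expected = naive_mismatch_offsets(seq.symbols, tc, matrix)
            for needed in (1, 2, 6):
                got = iv.mismatch_pairs_for_centre(idx, tc, needed, matrix)
                assert got == expected[:needed], (scheme, tc, needed)


def test_mismatch_offsets_empty_on_perfect_palindromic_centre():
    seq = iv.DegenerateSequence("pal", "ACGCGT")  # rc of itself
    idx = iv.IndexedSequence(seq)
    assert iv.mismatch_pairs_for_centre(idx, 2 * 3 - 1, 6) == []


def test_gap_swallowing_yields_three_irs_at_one_centre():
    """Mismatches at pair offsets 1 and 3 of the central axis, one allowed
    mismatch: the gap swallows them one at a time, giving three maximal IRs
    with growing gaps at the same centre."""
    seq = iv.DegenerateSequence("toy", "AAAAAATATATT")
    params = _params(m=1, k=1)
    idx = iv.IndexedSequence(seq)
    at_centre = iv.enumerate_irs_at_centre(idx, 11, params)
    assert [ir.gap_len for ir in at_centre] == [0, 4, 8]
    assert at_centre == [
        iv.InvertedRepeat(3, 6, 6, 9, 1),
        iv.InvertedRepeat(0, 4, 8, 12, 1),
        iv.InvertedRepeat(0, 2, 10, 12, 0),
    ]
    # and the full search agrees with the brute-force enumerator
    assert iv.find_inverted_repeats(seq, params) == iv.brute_force_find_irs(seq, params)


def test_invalid_parameters_are_rejected_before_search():
    with pytest.raises(iv.ParameterError):
        iv.SearchParams(min_arm=20, max_arm=10)
    with pytest.raises(iv.ParameterError):
        iv.SearchParams(min_arm=0)
    with pytest.raises(iv.ParameterError):
        iv.SearchParams(max_gap=-1)
    with pytest.raises(iv.ParameterError):
        iv.SearchParams(max_mismatch=-2)
    with pytest.raises(iv.ParameterError):
        iv.SearchParams(scheme="nope")


def test_index_for_other_sequence_is_rejected():
    idx = iv.IndexedSequence(iv.DegenerateSequence("a", "ACGTACGT"))
    with pytest.raises(iv.ParameterError):
        iv.find_inverted_repeats("TTTTAAAA", _params(), index=idx)


def _small_fixtures():
    out = []
    for seed in (11, 12):
        for n, sf in ((40, 1.0), (60, 0.8), (80, 0.9)):
            out.append(
                iv.random_iupac_sequence(
                    iv.GeneratorConfig(length=n, solid_fraction=sf, seed=seed)
                )
            )
    return out


def test_search_equals_brute_force_on_small_random_grid():
    grid = [
        _params(m, M, g, k, sc)
        for m, M, g, k, sc in itertools.product(
            (1, 3), (6, 100), (0, 4, 100), (0, 1, 3), ("simple", "degenerate")
        )
    ]
    for seq in _small_fixtures():
        idx = iv.IndexedSequence(seq)
        for params in grid:
            fast = iv.find_inverted_repeats(seq, params, index=idx)
            assert fast == iv.brute_force_find_irs(seq, params), (seq.name, params)


def test_reported_irs_are_valid_and_maximal():
    params = _params(m=2, M=30, g=20, k=2)
    matrix = iv.build_match_matrix(params.scheme)
    for seq in _small_fixtures():
        for ir in iv.find_inverted_repeats(seq, params):
            assert validate_ir(seq.symbols, ir, params, matrix) == []
            assert is_maximal(seq.symbols, ir, params, matrix)


def test_output_is_sorted_and_duplicate_free():
    seq = _small_fixtures()[2]
    irs = iv.find_inverted_repeats(seq, _params(m=2, k=2))
    keys = [(ir.left_start, -ir.right_end, ir.gap_len) for ir in irs]
    assert keys == sorted(keys)
    arms = {ir.arms() for ir in irs}
    assert len(arms) == len(irs)


def test_reverse_complement_mirror_symmetry_small():
    params = _params(m=2, k=1)
    for seq in _small_fixtures()[:3]:
        n = len(seq)
        fwd = iv.find_inverted_repeats(seq, params)
        rev = iv.find_inverted_repeats(seq.reverse_complement(), params)
        assert {mirror_ir(ir, n) for ir in fwd} == set(rev)


@settings(max_examples=75, deadline=None, derandomize=True)
@given(
    symbols=st.text(alphabet="ACGTRYSWKMBDHVN", min_size=2, max_size=40),
    min_arm=st.integers(1, 3),
    max_arm=st.integers(3, 50),
    max_gap=st.integers(0, 20),
    max_mismatch=st.integers(0, 3),
    scheme=st.sampled_from(["simple", "degenerate"]),
)
def test_search_equals_brute_force_property(
    symbols, min_arm, max_arm, max_gap, max_mismatch, scheme
):
    params = iv.SearchParams(min_arm, max_arm, max_gap, max_mismatch, scheme)
    seq = iv.DegenerateSequence("hyp", symbols)
    assert iv.find_inverted_repeats(seq, params) == iv.brute_force_find_irs(seq, params)
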