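"""The IUPAC alphabet layer: normalization, complements, match matrices."""

import itertools

import pytest

import invrep as iv
from invrep.core import _SCHEME_PREDICATES, _match_table_numpy

WC_PAIRS = {("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")}


@pytest.mark.parametrize(
    "raw, code, bases",
    [
        ("U", "T", {"T"}),
        ("u", "T", {"T"}),
        ("*", "N", {"A", "C", "G", "T"}),
        ("n", "N", {"A", "C", "G", "T"}),
        ("a", "A", {"A"}),
        ("b", "B", {"C", "G", "T"}),
    ],
)
def test_normalize_symbol_folds_aliases_and_case(raw, code, bases):
    sym = iv.normalize_symbol(raw)
    assert sym.code == code
    assert sym.base_set == frozenset(bases)


@pytest.mark.parametrize("raw", ["X", "J", "-", " ", "É", ""])
def test_normalize_symbol_rejects_non_iupac(raw):
    with pytest.raises(iv.InvalidSymbolError):
        iv.normalize_symbol(raw)


def test_normalize_sequence_names_offender_and_position():
    with pytest.raises(iv.InvalidSymbolError, match=r"'J' at position 3 in rec1"):
        iv.normalize_sequence("ACJGT", name="rec1")


def test_normalize_sequence_strict_mode_rejects_aliases():
    assert iv.normalize_sequence("acgu*") == "ACGTN"
    with pytest.raises(iv.InvalidSymbolError):
        iv.normalize_sequence("acgu*", strict=True)


def test_code_set_mapping_is_bijective_over_nonempty_subsets():
    assert len(iv.IUPAC_SETS) == 15
    assert len(set(iv.IUPAC_SETS.values())) == 15
    assert all(s and s <= frozenset("ACGT") for s in iv.IUPAC_SETS.values())


def test_simple_complement_is_elementwise_and_involutive():
    comp = {"A": "T", "T": "A", "C": "G", "G": "C"}
    for code, bases in iv.IUPAC_SETS.items():
        c = iv.simple_complement(code)
        assert iv.IUPAC_SETS[c] == frozenset(comp[b] for b in bases)
        assert iv.simple_complement(c) == code
    assert iv.simple_complement("B") == "V"
    assert iv.simple_complement("R") == "Y"
    assert iv.simple_complement("N") == "N"
    sym = iv.normalize_symbol("B")
    assert iv.simple_complement(sym) == iv.IupacSymbol("V", frozenset("ACG"))


@pytest.mark.parametrize("scheme", ["simple", "degenerate"])
def test_matrix_equals_exhaustive_setwise_definition(scheme):
    """All 225 cells recomputed straight from the base-set definitions."""
    matrix = iv.build_match_matrix(scheme)
    comp = {"A": "T", "T": "A", "C": "G", "G": "C"}
    for a, b in itertools.product(iv.IUPAC_SETS, repeat=2):
        if scheme == "simple":
            expected = b == iv.simple_complement(a)
        else:
            expected = any(
                s1 == comp[s2]
                for s1 in iv.IUPAC_SETS[a]
                for s2 in iv.IUPAC_SETS[b]
            )
        assert matrix.match(a, b) == expected, (a, b)


@pytest.mark.parametrize("scheme", ["simple", "degenerate"])
def test_matrix_is_symmetric(scheme):
    matrix = iv.build_match_matrix(scheme)
    for a, b in itertools.product(iv.IUPAC_SETS, repeat=2):
        assert matrix.match(a, b) == matrix.match(b, a)


def test_simple_scheme_is_subset_of_degenerate():
    simple = iv.build_match_matrix("simple")
    degen = iv.build_match_matrix("degenerate")
    assert simple.pairs < degen.pairs
    # headline examples: R pairs C only degenerately, B pairs V under both
    assert degen.match("R", "C") and not simple.match("R", "C")
    assert degen.match("B", "V") and simple.match("B", "V")


@pytest.mark.parametrize("scheme", ["simple", "degenerate"])
def test_solid_restriction_is_watson_crick(scheme):
    matrix = iv.build_match_matrix(scheme)
    solid = {
        (a, b)
        for a, b in itertools.product("ACGT", repeat=2)
        if matrix.match(a, b)
    }
    assert solid == WC_PAIRS


def test_n_matches_every_symbol_degenerately():
    degen = iv.build_match_matrix("degenerate")
    assert all(degen.match("N", s) for s in iv.IUPAC_SETS)


def test_literal_complement_equality_implies_degenerate_match():
    """Soundness base of the kangaroo walk: a literal hit in the rc text is
    always a scheme match."""
    degen = iv.build_match_matrix("degenerate")
    for b in iv.IUPAC_SETS:
        assert degen.match(iv.simple_complement(b), b)


def test_unknown_scheme_is_rejected():
    with pytest.raises(iv.ParameterError, match="unknown matching scheme"):
        iv.build_match_matrix("bogus")


def test_alternative_schemes_can_be_registered():
    """A custom scheme (G.T wobble pairing on top of Watson-Crick) plugs into
    the search unchanged."""
    partners = {"A": {"T"}, "C": {"G"}, "G": {"C", "T"}, "T": {"A", "G"}}

    def wobble(sa, sb):
        return any(x in partners[y] for x in sa for y in sb)

    iv.register_matching_scheme("wobble", wobble)
    try:
        params = iv.SearchParams(1, 10, 10, 0, scheme="wobble")
        got = iv.find_inverted_repeats("GT", params)
        assert got == [iv.InvertedRepeat(0, 1, 1, 2, 0)]
        assert got == iv.brute_force_find_irs("GT", params)
        assert iv.find_inverted_repeats(
            "GT", iv.SearchParams(1, 10, 10, 0, scheme="degenerate")
        ) == []
    finally:
        _SCHEME_PREDICATES.pop("wobble")
        iv.build_match_matrix.cache_clear()
        _match_table_numpy.cache_clear()


def test_schemes_missing_literal_complements_are_rejected():
    """The indexed walk crosses literal complement hits for free, so a scheme
    that rejected them would be unsound; the matrix builder refuses it."""
    iv.register_matching_scheme("never", lambda a, b: False)
    try:
        with pytest.raises(iv.ParameterError, match="simple-complement"):
            iv.build_match_matrix("never")
    finally:
        _SCHEME_PREDICATES.pop("never")
        iv.build_match_matrix.cache_clear()
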