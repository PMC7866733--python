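"""Exhaustive detection of gapped inverted repeats in IUPAC-encoded DNA.

An *inverted repeat* (IR) is a stretch of DNA of the form ``W G comp(W)[::-1]``:
a segment ``W`` (the left *arm*), an arbitrary central *gap* (spacer) ``G`` of
length >= 0, and then the reverse complement of ``W`` (the right arm).  Up to
``k`` of the equidistant-from-centre symbol pairs may fail to complement (a
*mismatch* budget, i.e. Hamming distance between the arms).  IRs can extrude
into cruciform secondary structures and are associated with rearrangement
hotspots, which makes their exhaustive annotation a standard genome-analysis
task.

This module works on *degenerate* sequences: each position is one of the 15
IUPAC nucleotide codes, i.e. a nonempty subset of {A, C, G, T} (``R`` = {A,G},
``N`` = all four, ...).  Such sequences arise when a reference genome is
combined with population variant calls.  Two complement-matching schemes over
the IUPAC alphabet are provided:

* ``simple``     - every code has one unique complement code (the elementwise
                   complement of its base set); two codes match only if one is
                   the other's complement code.  This is the convention used by
                   EMBOSS ``palindrome``.
* ``degenerate`` - two codes match iff some base of one is the Watson-Crick
                   complement of some base of the other (set intersection with
                   the complemented set).  This is the default and finds a
                   superset of the ``simple`` results.

The search itself is exact and exhaustive: every one of the ``2n - 1``
half-integer centres of an ``n``-symbol sequence is examined, and all maximal
IRs within the arm-length range ``[m, M]``, gap bound ``g`` and mismatch budget
``k`` are reported.  Mismatch positions around a centre are located with
budgeted longest-common-extension (LCE) queries -- the "kangaroo" method --
over a generalized index (suffix array + LCP array + sparse-table range-minimum
structure) built once over ``X . sentinel . reverse_complement(X) . sentinel``.
Per centre, a minimal initial gap is grown to swallow leading mismatches one at
a time, each time extending the arms outward to the position adjacent to the
next mismatch beyond the budget (so every reported IR is maximal and its
outermost pair matches).

Output is EMBOSS-``palindrome``-style text (1-based coordinates, three-line
blocks with an alignment-bar line), so the tool can replace EMBOSS in existing
pipelines.  A brute-force reference implementation and a seeded random IUPAC
sequence generator are included for verification.

Layout of this file, in the order the method runs:

1. configuration, logging, errors
2. IUPAC alphabet: codes, complements, match matrices      (alphabet layer)
3. degenerate sequences and FASTA input
4. suffix array / LCP / RMQ index and kangaroo LCE         (index layer)
5. inverted-repeat search                                  (search layer)
6. brute-force oracle and random sequence generator        (verification)
7. EMBOSS-style output, parsing, comparison                (io layer)
8. command-line interface
"""

from __future__ import annotations

import argparse
import json
import logging
import sys
import time
from bisect import bisect_left
from dataclasses import dataclass, field
from functools import lru_cache
from pathlib import Path
from typing import Callable, Iterable, Mapping, NamedTuple, Sequence

import numpy as np
from Bio import SeqIO

__all__ = [
    "InvrepError",
    "InvalidSymbolError",
    "ParameterError",
    "SequenceNotFoundError",
    "OutputParseError",
    "IUPAC_SETS",
    "IUPAC_ALPHABET",
    "IupacSymbol",
    "normalize_symbol",
    "normalize_sequence",
    "simple_complement",
    "reverse_complement",
    "MatchMatrix",
    "build_match_matrix",
    "register_matching_scheme",
    "DegenerateSequence",
    "read_fasta",
    "KangarooResult",
    "IndexedSequence",
    "SearchParams",
    "InvertedRepeat",
    "mismatch_pairs_for_centre",
    "enumerate_irs_at_centre",
    "find_inverted_repeats",
    "brute_force_find_irs",
    "GeneratorConfig",
    "DEFAULT_DEGENERATE_WEIGHTS",
    "random_iupac_sequence",
    "ci_fixture_sequences",
    "ci_parameter_grid",
    "format_ir_block",
    "write_palindrome_output",
    "parse_palindrome_output",
    "write_ir_table",
    "parse_ir_table",
    "ComparisonReport",
    "compare_outputs",
    "run_cli",
    "main",
]

# --------------------------------------------------------------------------
# 1. Configuration, logging, errors
# --------------------------------------------------------------------------

logger = logging.getLogger("invrep")

#: Sentinel characters separating the forward text from its reverse complement
#: in the generalized index.  Both sort below every IUPAC code, so no suffix
#: comparison extends meaningfully across a segment boundary, and the one at
#: the very end is unique, which makes all suffixes of the text distinct.
_SENTINEL_MID = "\x01"
_SENTINEL_END = "\x02"

#: Field separator used in the EMBOSS-style output blocks (fixed width so the
#: three lines of a block stay column-aligned and output is byte-reproducible).
_FIELD_SEP = "    "

_DEFAULT_MIN_ARM = 10
_DEFAULT_MAX_ARM = 100
_DEFAULT_MAX_GAP = 100
_DEFAULT_MAX_MISMATCH = 0


class InvrepError(Exception):
    """Base class for all errors raised by this package."""


class InvalidSymbolError(InvrepError, ValueError):
    """A character outside the IUPAC nucleotide alphabet was encountered."""


class ParameterError(InvrepError, ValueError):
    """Search or generator parameters are inconsistent or out of range."""


class SequenceNotFoundError(InvrepError, KeyError):
    """The requested record name is absent from the FASTA file."""


class OutputParseError(InvrepError, ValueError):
    """An inverted-repeat output file could not be parsed."""


# --------------------------------------------------------------------------
# 2. IUPAC alphabet, complements, match matrices
# --------------------------------------------------------------------------

#: The 15 IUPAC nucleotide codes mapped to the nonempty subsets of {A,C,G,T}
#: they denote.  The mapping is a bijection onto the 15 nonempty subsets.
IUPAC_SETS: dict[str, frozenset[str]] = {
    "A": frozenset("A"),
    "C": frozenset("C"),
    "G": frozenset("G"),
    "T": frozenset("T"),
    "R": frozenset("AG"),
    "Y": frozenset("CT"),
    "S": frozenset("CG"),
    "W": frozenset("AT"),
    "K": frozenset("GT"),
    "M": frozenset("AC"),
    "B": frozenset("CGT"),
    "D": frozenset("AGT"),
    "H": frozenset("ACT"),
    "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}

IUPAC_ALPHABET: frozenset[str] = frozenset(IUPAC_SETS)

#: Watson-Crick complement over the solid DNA alphabet.
_BASE_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

#: Input aliases normalized away before any processing: RNA-style U for T, and
#: * for N.  They never appear internally.
_ALIASES = {"U": "T", "*": "N"}

_SET_TO_CODE = {bases: code for code, bases in IUPAC_SETS.items()}

#: Unique complement code of each IUPAC code (elementwise complement of its
#: base set, mapped back through the code<->set bijection).  An involution.
_SIMPLE_COMPLEMENT = {
    code: _SET_TO_CODE[frozenset(_BASE_COMPLEMENT[b] for b in bases)]
    for code, bases in IUPAC_SETS.items()
}

_NORMALIZE_TABLE = str.maketrans(
    "acgtryswkmbdhvnuU*", "ACGTRYSWKMBDHVNTTN"
)
_RC_TABLE = str.maketrans(_SIMPLE_COMPLEMENT)


class IupacSymbol(NamedTuple):
    """A canonical IUPAC nucleotide code with its underlying base set."""

    code: str
    base_set: frozenset[str]


def normalize_symbol(raw: str) -> IupacSymbol:
    """Normalize one character to a canonical IUPAC symbol.

    Lowercase is folded to uppercase, ``U`` becomes ``T`` and ``*`` becomes
    ``N`` before validation.

    Raises
    ------
    InvalidSymbolError
        If the normalized character is not one of the 15 IUPAC codes.
    """
    if not isinstance(raw, str) or len(raw) != 1:
        raise InvalidSymbolError(f"expected a single character, got {raw!r}")
    code = _ALIASES.get(raw.upper(), raw.upper())
    bases = IUPAC_SETS.get(code)
    if bases is None:
        raise InvalidSymbolError(f"{raw!r} is not an IUPAC nucleotide code")
    return IupacSymbol(code, bases)


def normalize_sequence(raw: str, *, name: str = "sequence", strict: bool = False) -> str:
    """Normalize a whole nucleotide string to canonical IUPAC codes.

    Parameters
    ----------
    raw
        Input characters; lowercase and the ``U``/``*`` aliases are accepted
        (and folded) unless ``strict`` is set.
    name
        Used in error messages to identify the offending record.
    strict
        Reject lowercase letters and the ``U``/``*`` aliases instead of
        folding them.

    Raises
    ------
    InvalidSymbolError
        On the first character that is not (after folding) an IUPAC code.
        The message names the character and its 1-based position.
    """
    if strict:
        out = raw
    else:
        out = raw.translate(_NORMALIZE_TABLE)
    if set(out) - IUPAC_ALPHABET:
        for i, ch in enumerate(out):
            if ch not in IUPAC_ALPHABET:
                raise InvalidSymbolError(
                    f"invalid nucleotide {raw[i]!r} at position {i + 1} in {name}"
                )
    return out


def simple_complement(symbol: "IupacSymbol | str") -> "IupacSymbol | str":
    """Unique complement of a canonical IUPAC symbol (an involution).

    The complement's base set is the elementwise Watson-Crick complement of
    the input's base set; the code<->set bijection guarantees the result is
    again a single IUPAC code (e.g. ``B`` <-> ``V``, ``N`` <-> ``N``).
    Accepts either a one-character code or an :class:`IupacSymbol` and
    returns the same kind.
    """
    code = symbol.code if isinstance(symbol, IupacSymbol) else symbol
    comp = _SIMPLE_COMPLEMENT.get(code)
    if comp is None:
        raise InvalidSymbolError(f"{code!r} is not a canonical IUPAC code")
    if isinstance(symbol, IupacSymbol):
        return IupacSymbol(comp, IUPAC_SETS[comp])
    return comp


def reverse_complement(symbols: str) -> str:
    """Reverse complement of a canonical IUPAC string under the unique
    (simple) per-symbol complement."""
    return symbols.translate(_RC_TABLE)[::-1]


def _simple_pred(a: frozenset[str], b: frozenset[str]) -> bool:
    return a == frozenset(_BASE_COMPLEMENT[x] for x in b)


def _degenerate_pred(a: frozenset[str], b: frozenset[str]) -> bool:
    return bool(a & frozenset(_BASE_COMPLEMENT[x] for x in b))


#: Registry of matching schemes: name -> predicate on (base_set, base_set).
#: The search algorithm is matrix-agnostic, so additional schemes can be
#: registered without touching it.
_SCHEME_PREDICATES: dict[str, Callable[[frozenset[str], frozenset[str]], bool]] = {
    "simple": _simple_pred,
    "degenerate": _degenerate_pred,
}


class MatchMatrix:
    """Precomputed boolean complement-match relation over the IUPAC alphabet.

    ``match(a, b)`` answers whether codes ``a`` and ``b`` are considered
    complementary under the chosen scheme.  Both built-in schemes are
    symmetric, and ``simple`` implies ``degenerate``.
    """

    __slots__ = ("scheme", "_pairs", "_ord_table")

    def __init__(self, scheme: str, pairs: frozenset[tuple[str, str]]):
        self.scheme = scheme
        self._pairs = pairs
        # Dense ord-indexed table for the hot search loop.
        table = [[False] * 128 for _ in range(128)]
        for a, b in pairs:
            table[ord(a)][ord(b)] = True
        self._ord_table = table

    def match(self, a: str, b: str) -> bool:
        """Whether canonical codes ``a`` and ``b`` complement-match."""
        return (a, b) in self._pairs

    @property
    def pairs(self) -> frozenset[tuple[str, str]]:
        return self._pairs

    def to_numpy(self) -> np.ndarray:
        """The relation as a 128x128 boolean array indexed by ``ord``."""
        return np.array(self._ord_table, dtype=bool)

    def __repr__(self) -> str:  # pragma: no cover
        return f"MatchMatrix(scheme={self.scheme!r}, n_pairs={len(self._pairs)})"


def register_matching_scheme(
    name: str, predicate: Callable[[frozenset[str], frozenset[str]], bool]
) -> None:
    """Register a new complement-matching scheme under ``name``.

    ``predicate`` receives the two base sets and returns whether they match.
    The relation must contain the simple-complement relation (every code
    matches its unique complement code): the indexed search skips literal
    complement hits without consulting the matrix, so a scheme that rejected
    them would be applied unsoundly.  Violations are reported when the
    matrix is built.
    """
    _SCHEME_PREDICATES[name] = predicate
    build_match_matrix.cache_clear()


@lru_cache(maxsize=None)
def build_match_matrix(scheme: str = "degenerate") -> MatchMatrix:
    """Build (and cache) the 15x15 match matrix for a named scheme.

    Raises
    ------
    ParameterError
        If ``scheme`` has not been registered.
    """
    pred = _SCHEME_PREDICATES.get(scheme)
    if pred is None:
        raise ParameterError(
            f"unknown matching scheme {scheme!r}; "
            f"known schemes: {sorted(_SCHEME_PREDICATES)}"
        )
    pairs = frozenset(
        (a, b)
        for a, sa in IUPAC_SETS.items()
        for b, sb in IUPAC_SETS.items()
        if pred(sa, sb)
    )
    missing = [
        b for b in IUPAC_SETS if (_SIMPLE_COMPLEMENT[b], b) not in pairs
    ]
    if missing:
        raise ParameterError(
            f"scheme {scheme!r} rejects unique-complement pairs for {missing}; "
            "matching schemes must contain the simple-complement relation"
        )
    return MatchMatrix(scheme, pairs)


@lru_cache(maxsize=None)
def _match_table_numpy(scheme: str) -> np.ndarray:
    return build_match_matrix(scheme).to_numpy()


# --------------------------------------------------------------------------
# 3. Degenerate sequences and FASTA input
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class DegenerateSequence:
    """A named, validated IUPAC nucleotide sequence.

    ``symbols`` is stored as a canonical uppercase string over the 15-code
    alphabet; aliases and case are folded on construction.
    """

    name: str
    symbols: str

    def __post_init__(self) -> None:
        norm = normalize_sequence(self.symbols, name=self.name or "sequence")
        if not norm:
            raise ParameterError(f"sequence {self.name!r} is empty")
        object.__setattr__(self, "symbols", norm)

    def __len__(self) -> int:
        return len(self.symbols)

    def __str__(self) -> str:
        return self.symbols

    def base_set(self, i: int) -> frozenset[str]:
        """Base set denoted by the symbol at 0-based position ``i``."""
        return IUPAC_SETS[self.symbols[i]]

    def reverse_complement(self) -> "DegenerateSequence":
        return DegenerateSequence(f"{self.name}|rc", reverse_complement(self.symbols))


def read_fasta(path: "str | Path", name: "str | None" = None) -> DegenerateSequence:
    """Read one record from a (possibly multi-record, line-wrapped) FASTA file.

    Parameters
    ----------
    path
        FASTA file path.
    name
        Record identifier: the first whitespace-delimited token of the header.
        ``None`` selects the first record.

    Raises
    ------
    FileNotFoundError
        If ``path`` does not exist.
    SequenceNotFoundError
        If no record matches ``name``; the message lists available names.
    InvalidSymbolError
        If the record contains a non-IUPAC character (names the character,
        its 1-based position and the record).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"FASTA file not found: {path}")
    seen: list[str] = []
    for rec in SeqIO.parse(str(path), "fasta"):
        if name is None or rec.id == name:
            return DegenerateSequence(rec.id, str(rec.seq))
        seen.append(rec.id)
    raise SequenceNotFoundError(
        f"sequence {name!r} not found in {path}; available: {seen}"
    )


# --------------------------------------------------------------------------
# 4. Suffix array / LCP / RMQ index and kangaroo LCE
# --------------------------------------------------------------------------


def _suffix_array(codes: np.ndarray) -> np.ndarray:
    """Suffix array by prefix doubling (O(n log^2 n) with numpy sorts).

    ``codes`` is the text as small integers.  Ties are resolved by doubling
    the compared prefix length each round; the unique terminal sentinel
    guarantees all suffixes are distinct, so the loop terminates with a full
    permutation.
    """
    n = codes.size
    if n == 1:
        return np.zeros(1, dtype=np.intp)
    rank = np.unique(codes, return_inverse=True)[1].astype(np.int64)
    k = 1
    while True:
        key2 = np.full(n, -1, dtype=np.int64)
        key2[: n - k] = rank[k:]
        sa = np.lexsort((key2, rank))
        r1 = rank[sa]
        r2 = key2[sa]
        change = np.empty(n, dtype=np.int64)
        change[0] = 0
        change[1:] = (r1[1:] != r1[:-1]) | (r2[1:] != r2[:-1])
        new_sorted = np.cumsum(change)
        if new_sorted[-1] == n - 1 or k >= n:
            return sa
        rank = np.empty(n, dtype=np.int64)
        rank[sa] = new_sorted
        k *= 2


def _kasai_lcp(text: str, sa: list[int]) -> tuple[list[int], list[int]]:
    """LCP array via Kasai's algorithm; also returns the inverse permutation.

    ``lcp[r]`` is the longest-common-prefix length of the suffixes of ranks
    ``r-1`` and ``r`` (``lcp[0] = 0``).
    """
    n = len(sa)
    inv = [0] * n
    for r, p in enumerate(sa):
        inv[p] = r
    lcp = [0] * n
    h = 0
    for i in range(n):
        r = inv[i]
        if r > 0:
            j = sa[r - 1]
            while i + h < n and j + h < n and text[i + h] == text[j + h]:
                h += 1
            lcp[r] = h
            if h:
                h -= 1
        else:
            h = 0
    return lcp, inv


def _sparse_table(lcp: list[int]) -> tuple[list[list[int]], list[int]]:
    """Sparse min-table over ``lcp`` plus a floor-log lookup table.

    Levels are built with numpy and converted to plain lists: range-minimum
    queries are answered millions of times per search and Python list
    indexing is the fastest scalar access available.
    """
    m = len(lcp)
    log = [0] * (m + 1)
    for i in range(2, m + 1):
        log[i] = log[i >> 1] + 1
    arr = np.asarray(lcp, dtype=np.int64)
    levels_np = [arr]
    j = 1
    while (1 << j) <= m:
        prev = levels_np[-1]
        half = 1 << (j - 1)
        size = m - (1 << j) + 1
        levels_np.append(np.minimum(prev[:size], prev[half : half + size]))
        j += 1
    return [lev.tolist() for lev in levels_np], log


class KangarooResult(NamedTuple):
    """Result of a mismatch-budgeted LCE walk.

    ``matched_length`` is the longest pair-prefix containing at most the
    requested budget of true mismatches (capped by ``max_pairs`` / segment
    ends); ``mismatch_offsets`` lists every true mismatch encountered, in
    increasing offset order.  If the walk was stopped by the budget, the last
    offset equals ``matched_length`` (the first mismatch *outside* the
    matched prefix); hence at most ``budget + 1`` offsets.
    """

    matched_length: int
    mismatch_offsets: tuple[int, ...]


class IndexedSequence:
    """Generalized LCE index over a sequence and its reverse complement.

    The indexed text is ``X . s1 . rc(X) . s2`` where ``rc(X)[i]`` is the
    unique (simple) complement of ``X[n-1-i]`` and ``s1``/``s2`` are distinct
    sentinels sorting below the alphabet.  Literal equality of a forward
    symbol with a reverse-complement-text symbol is then exactly a
    simple-scheme complement match of the underlying symbols -- a sound
    under-approximation of both schemes, so literal LCE jumps never skip a
    true mismatch; degenerate matches that literal equality misses are
    adjudicated per stop with the active :class:`MatchMatrix`.

    Attributes ``sa``, ``lcp`` and ``inv_sa`` expose the suffix array, LCP
    array and inverse permutation of the concatenated text as plain lists;
    all coordinates are 0-based.
    """

    def __init__(self, seq: DegenerateSequence):
        if not isinstance(seq, DegenerateSequence):
            seq = DegenerateSequence("seq", str(seq))
        self.source = seq
        x = seq.symbols
        self._sym = x
        self._n = len(x)
        self.text = x + _SENTINEL_MID + reverse_complement(x) + _SENTINEL_END
        codes = np.frombuffer(self.text.encode("ascii"), dtype=np.uint8)
        self.sa: list[int] = _suffix_array(codes).tolist()
        self.lcp, self.inv_sa = _kasai_lcp(self.text, self.sa)
        self._st, self._log = _sparse_table(self.lcp)

    @property
    def n(self) -> int:
        """Length of the source sequence (the text is ``2n + 2`` long)."""
        return self._n

    def rc_text_pos(self, rc_pos: int) -> int:
        """Map a position in the rc(X) segment to its position in the text."""
        return self._n + 1 + rc_pos

    def lce_literal(self, i: int, j: int) -> int:
        """Longest literal common extension of text positions ``i`` and ``j``.

        Answered as the range minimum of the LCP array between the two
        suffix ranks; O(1) after preprocessing.  ``i == j`` returns the
        remaining suffix length.
        """
        text_len = len(self.text)
        if not (0 <= i < text_len and 0 <= j < text_len):
            raise IndexError(f"text positions out of range: {i}, {j}")
        if i == j:
            return text_len - i
        ri = self.inv_sa[i]
        rj = self.inv_sa[j]
        if ri > rj:
            ri, rj = rj, ri
        lo = ri + 1
        k = self._log[rj - lo + 1]
        lev = self._st[k]
        a = lev[lo]
        b = lev[rj - (1 << k) + 1]
        return a if a < b else b

    def kangaroo_lce(
        self,
        fwd_pos: int,
        rc_pos: int,
        budget: int,
        matrix: MatchMatrix,
        max_pairs: int,
    ) -> KangarooResult:
        """Budgeted LCE between ``X[fwd_pos..]`` and ``rc(X)[rc_pos..]``.

        Walks by repeated literal LCE jumps.  At each literal-inequality
        stop the active matrix adjudicates the underlying symbol pair: a
        scheme match that literal equality missed is crossed for free, a
        true mismatch consumes budget.  Stops after ``budget + 1`` true
        mismatches, at ``max_pairs`` compared pairs, or at a segment end.
        """
        n = self._n
        if not 0 <= fwd_pos < n:
            raise IndexError(f"forward position {fwd_pos} outside X (n={n})")
        if not 0 <= rc_pos < n:
            raise IndexError(f"rc position {rc_pos} outside rc(X) (n={n})")
        limit = min(max_pairs, n - fwd_pos, n - rc_pos)
        if limit < 0:
            limit = 0
        sym = self._sym
        tbl = matrix._ord_table
        inv = self.inv_sa
        st = self._st
        log = self._log
        j0 = n + 1 + rc_pos
        mism: list[int] = []
        s = 0
        while s < limit:
            ri = inv[fwd_pos + s]
            rj = inv[j0 + s]
            if ri > rj:
                ri, rj = rj, ri
            lo = ri + 1
            k = log[rj - lo + 1]
            lev = st[k]
            a = lev[lo]
            b = lev[rj - (1 << k) + 1]
            s += a if a < b else b
            if s >= limit:
                s = limit
                break
            if tbl[ord(sym[fwd_pos + s])][ord(sym[n - 1 - rc_pos - s])]:
                s += 1  # degenerate match literal equality missed: free
                continue
            mism.append(s)
            if len(mism) > budget:
                break
            s += 1
        matched = mism[-1] if len(mism) > budget else s
        return KangarooResult(matched, tuple(mism))


# --------------------------------------------------------------------------
# 5. Inverted-repeat search
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class SearchParams:
    """Search constraints: arm-length range, gap bound, mismatch budget, scheme.

    ``min_arm <= arm length <= max_arm``, ``gap <= max_gap``, at most
    ``max_mismatch`` non-complementary pairs per IR.
    """

    min_arm: int = _DEFAULT_MIN_ARM
    max_arm: int = _DEFAULT_MAX_ARM
    max_gap: int = _DEFAULT_MAX_GAP
    max_mismatch: int = _DEFAULT_MAX_MISMATCH
    scheme: str = "degenerate"

    def __post_init__(self) -> None:
        for name in ("min_arm", "max_arm", "max_gap", "max_mismatch"):
            v = getattr(self, name)
            if not isinstance(v, int) or isinstance(v, bool):
                raise ParameterError(f"{name} must be an integer, got {v!r}")
        if self.min_arm < 1:
            raise ParameterError(f"min_arm must be >= 1, got {self.min_arm}")
        if self.max_arm < self.min_arm:
            raise ParameterError(
                f"max_arm ({self.max_arm}) must be >= min_arm ({self.min_arm})"
            )
        if self.max_gap < 0:
            raise ParameterError(f"max_gap must be >= 0, got {self.max_gap}")
        if self.max_mismatch < 0:
            raise ParameterError(
                f"max_mismatch must be >= 0, got {self.max_mismatch}"
            )
        if self.scheme not in _SCHEME_PREDICATES:
            raise ParameterError(
                f"unknown matching scheme {self.scheme!r}; "
                f"known schemes: {sorted(_SCHEME_PREDICATES)}"
            )


@dataclass(frozen=True)
class InvertedRepeat:
    """A maximal gapped inverted repeat, in 0-based half-open coordinates.

    The left arm is ``[left_start, left_end)``, the right arm
    ``[right_start, right_end)``; both have length :attr:`arm_len` and the
    unpaired spacer between them has length :attr:`gap_len`.  Pair ``i``
    (counted from the outside in) aligns ``X[left_start + i]`` with
    ``X[right_end - 1 - i]``; :attr:`mismatches` of those pairs fail the
    match matrix, and the outermost pair always matches.
    """

    left_start: int
    left_end: int
    right_start: int
    right_end: int
    mismatches: int

    @property
    def arm_len(self) -> int:
        return self.left_end - self.left_start

    @property
    def gap_len(self) -> int:
        return self.right_start - self.left_end

    @property
    def twice_centre(self) -> int:
        """Twice the (half-integer) centre position of the IR."""
        return self.left_start + self.right_end - 1

    def arms(self) -> tuple[tuple[int, int], tuple[int, int]]:
        return (
            (self.left_start, self.left_end),
            (self.right_start, self.right_end),
        )


def _sort_key(ir: InvertedRepeat) -> tuple[int, int, int]:
    # Fixed output order: left start ascending, longer IR first, then gap.
    return (ir.left_start, -ir.right_end, ir.gap_len)


def _centre_geometry(twice_centre: int, n: int) -> tuple[int, int, int, int]:
    """Innermost pair positions (lo, hi), minimal gap and pair count at a centre.

    A centre is identified by ``twice_centre`` in ``0..2n-2``; even values sit
    on a symbol (the central symbol stays unpaired, minimal gap 1), odd values
    sit between symbols (minimal gap 0).  Pair ``t`` aligns ``X[lo - t]`` with
    ``X[hi + t]``; ``T`` is the number of pairs that fit inside the sequence.
    """
    if twice_centre % 2 == 0:
        c = twice_centre // 2
        lo, hi, gap0 = c - 1, c + 1, 1
    else:
        lo = twice_centre // 2
        hi = lo + 1
        gap0 = 0
    T = min(lo + 1, n - hi)
    return lo, hi, gap0, T


class _MismatchStream:
    """Lazily discovered true-mismatch pair offsets at one centre.

    Backed by kangaroo LCE restarts; only as many mismatches as the enclosing
    gap-swallowing loop actually needs are ever computed.  A stream may be
    shared across parameter sets (same centre, same scheme) via the optional
    cache in :func:`find_inverted_repeats`.
    """

    __slots__ = ("_idx", "_matrix", "_fwd0", "_rc0", "_T", "offsets", "_next_t")

    def __init__(self, idx: IndexedSequence, matrix: MatchMatrix, lo: int, hi: int, T: int):
        self._idx = idx
        self._matrix = matrix
        self._fwd0 = hi
        self._rc0 = idx.n - 1 - lo
        self._T = T
        self.offsets: list[int] = []
        self._next_t = 0

    def ensure(self, count: int) -> list[int]:
        """Extend the offset list to at least ``count`` entries if possible."""
        offs = self.offsets
        while len(offs) < count and self._next_t < self._T:
            need = count - len(offs)
            res = self._idx.kangaroo_lce(
                self._fwd0 + self._next_t,
                self._rc0 + self._next_t,
                need - 1,
                self._matrix,
                self._T - self._next_t,
            )
            base = self._next_t
            offs.extend(base + o for o in res.mismatch_offsets)
            if len(res.mismatch_offsets) < need:
                self._next_t = self._T  # boundary reached: exhausted
            else:
                self._next_t = offs[-1] + 1
        return offs


def mismatch_pairs_for_centre(
    idx: IndexedSequence,
    twice_centre: int,
    needed: int,
    matrix: "MatchMatrix | None" = None,
) -> list[int]:
    """First ``needed`` truly-mismatching pair offsets at a centre.

    Offsets count pairs outward from the innermost possible pair (``t = 0``),
    in increasing distance from the centre; fewer than ``needed`` are returned
    if the sequence boundary intervenes.  Computed lazily with kangaroo-LCE
    restarts.
    """
    if needed < 1:
        raise ParameterError(f"needed must be >= 1, got {needed}")
    if matrix is None:
        matrix = build_match_matrix()
    lo, hi, _, T = _centre_geometry(twice_centre, idx.n)
    if T <= 0:
        return []
    stream = _MismatchStream(idx, matrix, lo, hi, T)
    return list(stream.ensure(needed)[:needed])


def _irs_at_centre(
    idx: IndexedSequence,
    twice_centre: int,
    params: SearchParams,
    matrix: MatchMatrix,
    cache: "dict | None" = None,
) -> list[InvertedRepeat]:
    """Gap-swallowing enumeration of all maximal IRs at one centre.

    For ``j = 0, 1, 2, ...`` the arm starts just outside the first ``j``
    mismatching pairs (the minimal gap of the centre's parity that excludes
    them) and extends outward to the position adjacent to the ``(k+1)``-th
    remaining mismatch, the arm-length cap or the boundary, then is trimmed
    inward so the outermost pair matches.
    """
    n = idx.n
    lo, hi, gap0, T = _centre_geometry(twice_centre, n)
    out: list[InvertedRepeat] = []
    m = params.min_arm
    if T < m or gap0 > params.max_gap:
        return out
    stream = None
    if cache is not None:
        stream = cache.get(twice_centre)
    if stream is None:
        stream = _MismatchStream(idx, matrix, lo, hi, T)
        if cache is not None:
            cache[twice_centre] = stream
    M = params.max_arm
    g = params.max_gap
    k = params.max_mismatch
    j = 0
    while True:
        if j == 0:
            t_start = 0
        else:
            offs = stream.ensure(j)
            if len(offs) < j:
                break  # no j-th mismatch inside the boundary
            t_start = offs[j - 1] + 1
            if t_start >= T:
                break  # no symbols remain outside the swallowed gap
        gap = gap0 + 2 * t_start
        if gap > g:
            break
        offs = stream.ensure(j + k + 1)
        t_end = offs[j + k] if len(offs) > j + k else T
        cap = t_start + M
        if t_end > cap:
            t_end = cap
        i_lo = bisect_left(offs, t_start)
        i_hi = bisect_left(offs, t_end)
        # Trim inward so the outermost pair matches.
        while i_hi > i_lo and offs[i_hi - 1] == t_end - 1:
            t_end -= 1
            i_hi -= 1
        if t_end - t_start >= m:
            out.append(
                InvertedRepeat(
                    left_start=lo - t_end + 1,
                    left_end=lo - t_start + 1,
                    right_start=hi + t_start,
                    right_end=hi + t_end,
                    mismatches=i_hi - i_lo,
                )
            )
        j += 1
    return out


def enumerate_irs_at_centre(
    idx: IndexedSequence, twice_centre: int, params: SearchParams
) -> list[InvertedRepeat]:
    """All maximal IRs whose centre is ``twice_centre / 2``, given ``params``."""
    if not 0 <= twice_centre <= 2 * idx.n - 2:
        raise IndexError(
            f"twice_centre {twice_centre} outside 0..{2 * idx.n - 2}"
        )
    return _irs_at_centre(idx, twice_centre, params, build_match_matrix(params.scheme))


def find_inverted_repeats(
    seq: "DegenerateSequence | str",
    params: SearchParams,
    *,
    index: "IndexedSequence | None" = None,
    mismatch_cache: "dict | None" = None,
) -> list[InvertedRepeat]:
    """All maximal gapped inverted repeats of ``seq`` satisfying ``params``.

    Examines every one of the ``2n - 1`` centres, deduplicates on the arm
    intervals and sorts by (left start, right end descending, gap).  Every
    returned IR satisfies all constraints; none can be enlarged at its centre
    and gap without exceeding the mismatch budget, the arm cap or the
    sequence boundary.

    ``index`` allows reusing a prebuilt :class:`IndexedSequence` across
    parameter sets; ``mismatch_cache`` (a plain dict, one per scheme) lets
    repeated searches share per-centre mismatch discovery.
    """
    if isinstance(seq, str):
        seq = DegenerateSequence("seq", seq)
    if index is None:
        index = IndexedSequence(seq)
    elif index.source.symbols != seq.symbols:
        raise ParameterError("supplied index was built over a different sequence")
    matrix = build_match_matrix(params.scheme)
    found: dict[tuple[int, int, int, int], InvertedRepeat] = {}
    for tc in range(2 * index.n - 1):
        for ir in _irs_at_centre(index, tc, params, matrix, mismatch_cache):
            found.setdefault(
                (ir.left_start, ir.left_end, ir.right_start, ir.right_end), ir
            )
    return sorted(found.values(), key=_sort_key)


# --------------------------------------------------------------------------
# 6. Brute-force oracle and random sequence generator
# --------------------------------------------------------------------------


def brute_force_find_irs(
    seq: "DegenerateSequence | str", params: SearchParams
) -> list[InvertedRepeat]:
    """Reference implementation by direct outward pairwise scanning.

    For every centre the full pair-match profile is evaluated directly from
    the match matrix (no suffix-array machinery), and for every swallowed
    mismatch prefix the arm end is the largest extension whose prefix holds
    at most ``k`` mismatches and whose outermost pair matches.  Maximality,
    trimming, uniqueness and ordering semantics are the same as
    :func:`find_inverted_repeats`; the computational route is disjoint.
    Intended for sequences up to a few hundred symbols.
    """
    if isinstance(seq, str):
        seq = DegenerateSequence("seq", seq)
    s = seq.symbols
    n = len(s)
    m, M, g, k = params.min_arm, params.max_arm, params.max_gap, params.max_mismatch
    tbl = _match_table_numpy(params.scheme)
    codes = np.frombuffer(s.encode("ascii"), dtype=np.uint8)
    rev = codes[::-1]
    found: dict[tuple[int, int, int, int], InvertedRepeat] = {}
    for tc in range(2 * n - 1):
        if tc % 2 == 0:
            lo = tc // 2 - 1
            hi = tc // 2 + 1
            gap0 = 1
        else:
            lo = tc // 2
            hi = lo + 1
            gap0 = 0
        T = min(lo + 1, n - hi)
        if T < m or gap0 > g:
            continue
        left = rev[n - 1 - lo : n - 1 - lo + T]  # s[lo], s[lo-1], ...
        right = codes[hi : hi + T]
        pair_ok = tbl[left, right]
        mism = np.flatnonzero(~pair_ok)
        match_pos = np.flatnonzero(pair_ok)
        if match_pos.size == 0:
            continue
        n_mis = mism.size
        for j in range(n_mis + 1):
            t_start = 0 if j == 0 else int(mism[j - 1]) + 1
            if t_start >= T:
                break
            gap = gap0 + 2 * t_start
            if gap > g:
                break
            bound = int(mism[j + k]) if j + k < n_mis else T
            e_cap = min(bound, t_start + M)
            p = int(np.searchsorted(match_pos, e_cap)) - 1
            if p < 0:
                continue
            pe = int(match_pos[p])
            if pe < t_start:
                continue
            t_end = pe + 1
            if t_end - t_start < m:
                continue
            nm = int(np.searchsorted(mism, t_end) - np.searchsorted(mism, t_start))
            key = (lo - t_end + 1, lo - t_start + 1, hi + t_start, hi + t_end)
            found.setdefault(key, InvertedRepeat(*key, mismatches=nm))
    return sorted(
        found.values(),
        key=lambda ir: (ir.left_start, -ir.right_end, ir.gap_len),
    )


#: Non-solid symbol mix emulating variant-derived IUPAC genomes, where nearly
#: all ambiguity codes come from biallelic SNPs (two-base codes); three-base
#: codes and N are rare.
DEFAULT_DEGENERATE_WEIGHTS: Mapping[str, float] = {
    "R": 0.15,
    "Y": 0.15,
    "S": 0.15,
    "W": 0.15,
    "K": 0.15,
    "M": 0.15,
    "B": 0.02,
    "D": 0.02,
    "H": 0.02,
    "V": 0.02,
    "N": 0.02,
}

_NON_SOLID = frozenset("RYSWKMBDHVN")


@dataclass(frozen=True)
class GeneratorConfig:
    """Configuration for the seeded random IUPAC sequence generator.

    ``solid_fraction`` is the probability that a position is a solid
    A/C/G/T (drawn uniformly); the rest are drawn from
    ``degenerate_weights``.  The same config always yields the same
    sequence.
    """

    length: int
    solid_fraction: float = 0.9
    degenerate_weights: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_DEGENERATE_WEIGHTS)
    )
    seed: int = 0


def random_iupac_sequence(cfg: GeneratorConfig, name: "str | None" = None) -> DegenerateSequence:
    """Generate a reproducible random IUPAC sequence from ``cfg``."""
    if cfg.length < 1:
        raise ParameterError(f"length must be >= 1, got {cfg.length}")
    if not 0.0 <= cfg.solid_fraction <= 1.0:
        raise ParameterError(
            f"solid_fraction must be in [0, 1], got {cfg.solid_fraction}"
        )
    weights = dict(cfg.degenerate_weights)
    if set(weights) - _NON_SOLID:
        raise ParameterError(
            f"degenerate_weights keys must be non-solid IUPAC codes, "
            f"got extras {sorted(set(weights) - _NON_SOLID)}"
        )
    if any(w < 0 for w in weights.values()):
        raise ParameterError("degenerate_weights must be nonnegative")
    total = sum(weights.values())
    if cfg.solid_fraction < 1.0:
        if not weights or abs(total - 1.0) > 1e-6:
            raise ParameterError(
                f"degenerate_weights must sum to 1, got {total!r}"
            )
    rng = np.random.default_rng(cfg.seed)
    n = cfg.length
    solid = rng.random(n) < cfg.solid_fraction
    bases = rng.choice(np.array(list("ACGT")), size=n)
    if weights and total > 0:
        syms = np.array(sorted(weights))
        probs = np.array([weights[c] for c in syms])
        degs = rng.choice(syms, size=n, p=probs / probs.sum())
        symbols = np.where(solid, bases, degs)
    else:
        symbols = bases
    if name is None:
        name = f"random_n{n}_s{cfg.solid_fraction:g}_seed{cfg.seed}"
    return DegenerateSequence(name, "".join(symbols.tolist()))


def ci_fixture_sequences(
    seeds: Sequence[int] = (1, 2, 3),
    lengths: Sequence[int] = (50, 120, 300),
    solid_fractions: Sequence[float] = (1.0, 0.9),
) -> list[DegenerateSequence]:
    """The fixture sequences of the default verification grid."""
    return [
        random_iupac_sequence(GeneratorConfig(length=n, solid_fraction=sf, seed=sd))
        for n in lengths
        for sf in solid_fractions
        for sd in seeds
    ]


def ci_parameter_grid(
    min_arms: Sequence[int] = (2, 3, 10),
    max_arms: Sequence[int] = (20, 100),
    max_gaps: Sequence[int] = (0, 5, 100),
    max_mismatches: Sequence[int] = (0, 1, 2, 4),
    schemes: Sequence[str] = ("simple", "degenerate"),
) -> list[SearchParams]:
    """The search-parameter combinations of the default verification grid."""
    return [
        SearchParams(min_arm=m, max_arm=M, max_gap=g, max_mismatch=k, scheme=sc)
        for m in min_arms
        for M in max_arms
        for g in max_gaps
        for k in max_mismatches
        for sc in schemes
        if M >= m
    ]


# --------------------------------------------------------------------------
# 7. EMBOSS-style output, parsing, comparison
# --------------------------------------------------------------------------


def format_ir_block(symbols: str, ir: InvertedRepeat, matrix: MatchMatrix) -> str:
    """One three-line output block for an IR, EMBOSS ``palindrome`` style.

    Line 1: left-arm 1-based start, the left-arm symbols, left-arm end.
    Line 2: alignment bars, ``|`` where the pair complement-matches.
    Line 3: the right arm written 3'-most coordinate first, i.e. its 1-based
    end coordinate, the symbols in reverse order, then its start coordinate —
    so each column of lines 1 and 3 holds a pairwise-partner symbol.
    """
    left = symbols[ir.left_start : ir.left_end]
    right = symbols[ir.right_start : ir.right_end]
    bars = "".join(
        "|" if matrix.match(left[i], symbols[ir.right_end - 1 - i]) else " "
        for i in range(ir.arm_len)
    )
    a1 = ir.left_start + 1
    b1 = ir.left_end
    a3 = ir.right_end
    b3 = ir.right_start + 1
    w = max(len(str(a1)), len(str(a3)))
    line1 = f"{a1:<{w}}{_FIELD_SEP}{left}{_FIELD_SEP}{b1}"
    line2 = (" " * (w + len(_FIELD_SEP)) + bars).rstrip()
    line3 = f"{a3:<{w}}{_FIELD_SEP}{right[::-1]}{_FIELD_SEP}{b3}"
    return "\n".join((line1, line2, line3))


def write_palindrome_output(
    seq: DegenerateSequence,
    irs: Sequence[InvertedRepeat],
    matrix: MatchMatrix,
    path: "str | Path",
    params: "SearchParams | None" = None,
) -> None:
    """Write the EMBOSS-``palindrome``-style result file.

    A free-form preamble (sequence name, length, parameter echo) precedes the
    blocks; blocks are separated by blank lines.  Output is fully
    deterministic: no timestamps, fixed field widths.
    """
    n = len(seq)
    head = [
        f"Palindromes of: {seq.name}",
        f"Sequence length is: {n}",
        "Start at position: 1",
        f"End at position: {n}",
    ]
    if params is not None:
        head += [
            f"Minimum length of Palindromes is: {params.min_arm}",
            f"Maximum length of Palindromes is: {params.max_arm}",
            f"Maximum gap between elements is: {params.max_gap}",
            f"Number of mismatches allowed in Palindrome: {params.max_mismatch}",
        ]
    head += ["", "Palindromes:"]
    blocks = [format_ir_block(seq.symbols, ir, matrix) for ir in irs]
    text = "\n".join(head) + "\n"
    if blocks:
        text += "\n\n".join(blocks) + "\n"
    Path(path).write_text(text)


def parse_palindrome_output(path: "str | Path") -> list[tuple[int, int, int, int]]:
    """Parse a block-format result file back to 1-based coordinate tuples.

    Returns ``(left_start, left_end, right_start, right_end)`` per block,
    all 1-based inclusive.  Raises :class:`OutputParseError` (citing the
    line number) on malformed blocks.
    """
    lines = Path(path).read_text().splitlines()
    start = 0
    for i, line in enumerate(lines):
        if line.strip() == "Palindromes:":
            start = i + 1
            break
    entries: list[tuple[int, str, list[str]]] = []  # (lineno, text)
    block: list[tuple[int, str]] = []
    out: list[tuple[int, int, int, int]] = []

    def flush(block: list[tuple[int, str]]) -> None:
        if not block:
            return
        if len(block) != 3:
            raise OutputParseError(
                f"line {block[0][0]}: expected a 3-line block, got {len(block)} lines"
            )
        (ln1, l1), (_, _), (ln3, l3) = block
        t1 = l1.split()
        t3 = l3.split()
        if len(t1) != 3 or not (t1[0].isdigit() and t1[2].isdigit()):
            raise OutputParseError(f"line {ln1}: malformed arm line {l1!r}")
        if len(t3) != 3 or not (t3[0].isdigit() and t3[2].isdigit()):
            raise OutputParseError(f"line {ln3}: malformed arm line {l3!r}")
        ls, le = int(t1[0]), int(t1[2])
        re_, rs = int(t3[0]), int(t3[2])
        if not (ls <= le < rs <= re_):
            raise OutputParseError(
                f"line {ln1}: inconsistent coordinates {(ls, le, rs, re_)}"
            )
        if len(t1[1]) != le - ls + 1 or len(t3[1]) != re_ - rs + 1:
            raise OutputParseError(
                f"line {ln1}: arm text length disagrees with coordinates"
            )
        out.append((ls, le, rs, re_))

    for lineno, line in enumerate(lines[start:], start=start + 1):
        if line.strip():
            block.append((lineno, line))
            if len(block) == 3:
                flush(block)
                block = []
        elif block:
            raise OutputParseError(
                f"line {lineno}: blank line inside a block"
            )
    if block:
        raise OutputParseError(
            f"line {block[0][0]}: truncated block at end of file"
        )
    return out


_TABLE_HEADER = "left_start\tleft_end\tright_start\tright_end\tgap\tmismatches"


def write_ir_table(irs: Sequence[InvertedRepeat], path: "str | Path") -> None:
    """Machine-readable sidecar: tab-separated, 1-based inclusive coordinates."""
    rows = [_TABLE_HEADER]
    for ir in irs:
        rows.append(
            "\t".join(
                str(v)
                for v in (
                    ir.left_start + 1,
                    ir.left_end,
                    ir.right_start + 1,
                    ir.right_end,
                    ir.gap_len,
                    ir.mismatches,
                )
            )
        )
    Path(path).write_text("\n".join(rows) + "\n")


def parse_ir_table(path: "str | Path") -> list[tuple[int, int, int, int]]:
    """Parse the tab-separated sidecar back to 1-based coordinate tuples."""
    lines = Path(path).read_text().splitlines()
    out = []
    for lineno, line in enumerate(lines, start=1):
        if lineno == 1:
            if not line.startswith("left_start"):
                raise OutputParseError(f"line 1: missing table header")
            continue
        if not line.strip():
            continue
        parts = line.split("\t")
        if len(parts) < 4:
            raise OutputParseError(f"line {lineno}: malformed row {line!r}")
        try:
            ls, le, rs, re_ = (int(p) for p in parts[:4])
        except ValueError as exc:
            raise OutputParseError(f"line {lineno}: {exc}") from exc
        out.append((ls, le, rs, re_))
    return out


@dataclass(frozen=True)
class ComparisonReport:
    """Set comparison of two result files (coordinate tuples, 1-based)."""

    common: frozenset[tuple[int, int, int, int]]
    only_a: frozenset[tuple[int, int, int, int]]
    only_b: frozenset[tuple[int, int, int, int]]

    @property
    def identical(self) -> bool:
        return not self.only_a and not self.only_b

    def summary(self) -> str:
        lines = [
            f"common: {len(self.common)}",
            f"only in A: {len(self.only_a)}",
            f"only in B: {len(self.only_b)}",
        ]
        for label, group in (("A", self.only_a), ("B", self.only_b)):
            for tup in sorted(group):
                lines.append(f"  only {label}: {tup}")
        return "\n".join(lines)


def _load_ir_file(path: "str | Path") -> set[tuple[int, int, int, int]]:
    first = ""
    with open(path) as fh:
        for line in fh:
            if line.strip():
                first = line
                break
    if first.startswith("left_start"):
        return set(parse_ir_table(path))
    return set(parse_palindrome_output(path))


def compare_outputs(path_a: "str | Path", path_b: "str | Path") -> ComparisonReport:
    """Compare two result files (block format or sidecar table) as IR sets."""
    a = _load_ir_file(path_a)
    b = _load_ir_file(path_b)
    return ComparisonReport(
        common=frozenset(a & b),
        only_a=frozenset(a - b),
        only_b=frozenset(b - a),
    )


# --------------------------------------------------------------------------
# 8. Command-line interface
# --------------------------------------------------------------------------


def _build_parser() -> argparse.ArgumentParser:
    p = argparse.ArgumentParser(
        prog="invrep",
        description=(
            "Exhaustively find maximal gapped inverted repeats in an "
            "IUPAC-encoded DNA sequence."
        ),
        epilog="Use 'invrep compare FILE_A FILE_B' to diff two result files.",
    )
    p.add_argument("-f", "--file", required=True, help="input FASTA file")
    p.add_argument(
        "-s", "--seq", default=None,
        help="sequence name (first header token); default: first record",
    )
    p.add_argument("-o", "--out", required=True, help="output file")
    p.add_argument(
        "-m", "--min-len", type=int, default=_DEFAULT_MIN_ARM,
        help=f"minimum arm length (default {_DEFAULT_MIN_ARM})",
    )
    p.add_argument(
        "-M", "--max-len", type=int, default=_DEFAULT_MAX_ARM,
        help=f"maximum arm length (default {_DEFAULT_MAX_ARM})",
    )
    p.add_argument(
        "-g", "--max-gap", type=int, default=_DEFAULT_MAX_GAP,
        help=f"maximum gap between arms (default {_DEFAULT_MAX_GAP})",
    )
    p.add_argument(
        "-x", "--mismatches", type=int, default=_DEFAULT_MAX_MISMATCH,
        help=f"maximum mismatches (default {_DEFAULT_MAX_MISMATCH})",
    )
    p.add_argument(
        "--scheme", choices=sorted(_SCHEME_PREDICATES), default="degenerate",
        help="complement-matching scheme (default: degenerate)",
    )
    p.add_argument(
        "--tsv", default=None, metavar="PATH",
        help="also write a machine-readable tab-separated table to PATH",
    )
    return p


def _run_compare(argv: list[str]) -> int:
    p = argparse.ArgumentParser(
        prog="invrep compare",
        description="Compare two inverted-repeat result files as sets.",
    )
    p.add_argument("file_a")
    p.add_argument("file_b")
    args = p.parse_args(argv)
    try:
        report = compare_outputs(args.file_a, args.file_b)
    except (OSError, OutputParseError) as exc:
        print(f"error: {exc}", file=sys.stderr)
        return 1
    print(report.summary())
    return 0


def run_cli(argv: "list[str] | None" = None) -> int:
    """Entry point; returns a process exit status instead of raising."""
    if argv is None:
        argv = sys.argv[1:]
    if not logging.getLogger().handlers and not logger.handlers:
        handler = logging.StreamHandler(sys.stderr)
        handler.setFormatter(logging.Formatter("%(levelname)s: %(message)s"))
        logger.addHandler(handler)
        logger.setLevel(logging.INFO)
    if argv and argv[0] == "compare":
        return _run_compare(argv[1:])
    parser = _build_parser()
    try:
        args = parser.parse_args(argv)
    except SystemExit as exc:  # argparse reports its own diagnostic
        return int(exc.code or 0)
    try:
        params = SearchParams(
            min_arm=args.min_len,
            max_arm=args.max_len,
            max_gap=args.max_gap,
            max_mismatch=args.mismatches,
            scheme=args.scheme,
        )
    except ParameterError as exc:
        print(f"error: {exc}", file=sys.stderr)
        return 2
    try:
        seq = read_fasta(args.file, args.seq)
    except (FileNotFoundError, SequenceNotFoundError, InvalidSymbolError) as exc:
        print(f"error: {exc}", file=sys.stderr)
        return 1
    t0 = time.perf_counter()
    irs = find_inverted_repeats(seq, params)
    elapsed = time.perf_counter() - t0
    matrix = build_match_matrix(params.scheme)
    try:
        write_palindrome_output(seq, irs, matrix, args.out, params=params)
        if args.tsv:
            write_ir_table(irs, args.tsv)
    except OSError as exc:
        print(f"error: cannot write output: {exc}", file=sys.stderr)
        return 1
    logger.info("sequence %s: %d symbols", seq.name, len(seq))
    logger.info(
        "parameters: min_arm=%d max_arm=%d max_gap=%d max_mismatch=%d scheme=%s",
        params.min_arm, params.max_arm, params.max_gap,
        params.max_mismatch, params.scheme,
    )
    logger.info("found %d inverted repeats in %.2f s", len(irs), elapsed)
    return 0


def main() -> None:  # pragma: no cover - console-script shim
    sys.exit(run_cli())
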