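# invrep

Exhaustive, exact detection of **gapped inverted repeats** in
**IUPAC-encoded DNA** sequences, with mismatches, at scale.

## The problem

An inverted repeat (IR) is a stretch of DNA of the form *W G W̄ᴿ*: an arm
*W*, an optional central spacer *G* (length ≥ 0), and the reverse complement
of *W*.  Allowing up to *k* of the equidistant-from-centre base pairs to fail
complementarity gives an *IR within k mismatches*, i.e. δ_H(W, W̄ᴿ) ≤ k.
IRs can extrude into cruciform secondary structures and are associated with
chromosomal rearrangement hotspots, replication and transcription regulation,
so exhaustively annotating them is a routine genome-analysis task.

Population resequencing projects produce *degenerate* genome representations:
each position is one of the 15 IUPAC codes, a nonempty subset of {A,C,G,T}
(`R` = {A,G}, `B` = {C,G,T}, `N` = all four, …), encoding the variation
observed across individuals.  `invrep` searches such sequences directly.  Two
complement-matching schemes over the IUPAC alphabet are built in:

* **simple** — every code has a unique complement code (elementwise
  complement of its base set, e.g. `B` ↔ `V`); two codes match only if one
  is the other's complement.  This is the EMBOSS `palindrome` convention.
* **degenerate** (default) — codes *I₁*, *I₂* match iff some σ₁ ∈ I₁ and
  σ₂ ∈ I₂ satisfy σ₁ ↔ σ₂ under Watson–Crick pairing.  `R` matches `C`
  (R contains G, the complement of C); the simple scheme misses this.

On purely solid A/C/G/T input the two schemes coincide.  Additional schemes
(e.g. G·T wobble pairing) can be registered as a match matrix without touching
the search.

## The algorithm

For a sequence *X* of length *n*, all 2n − 1 half-integer centres are
examined.  Mismatch positions around a centre are located with
mismatch-budgeted longest-common-extension queries — the *kangaroo method* —
over one generalized index built on `X · $ · rc(X) · #` (suffix array, LCP
array via Kasai's algorithm, sparse-table range-minimum structure; literal
LCE in O(1)).  Because `rc(X)` is written with the unique per-symbol
complement, a literal character hit is always a scheme match, so LCE jumps
never skip a true mismatch; at each literal stop the match matrix adjudicates
whether the pair is a free degenerate match or consumes budget.

Per centre, a minimal initial gap (0 between symbols, 1 on a symbol) is grown
to *swallow* leading mismatches one at a time; after each swallow the arms
extend outward to the position adjacent to the next mismatch beyond the
budget, the arm-length cap, or the boundary, then are trimmed so the
outermost pair matches.  Every reported IR is therefore *maximal*, and only
as many mismatch locations as the parameters require are ever computed.
Reported IRs satisfy m ≤ |W| ≤ M, |G| ≤ g and δ_H(W, W̄ᴿ) ≤ k.

A definition-level brute-force enumerator (`brute_force_find_irs`) and a
seeded random IUPAC sequence generator ship with the package; the test suite
proves the indexed search set-identical to the enumerator across ~2,600
sequence × parameter combinations.

## Worked example

```sh
$ cat demo.fasta
>demo population-consensus fragment
AAASTACRAAAAAAACGRAG
$ invrep -f demo.fasta -s demo -o demo.out -m 5 -M 20 -g 10 -x 1
INFO: sequence demo: 20 symbols
INFO: parameters: min_arm=5 max_arm=20 max_gap=10 max_mismatch=1 scheme=degenerate
INFO: found 1 inverted repeats in 0.00 s
$ cat demo.out
Palindromes of: demo
Sequence length is: 20
Start at position: 1
End at position: 20
Minimum length of Palindromes is: 5
Maximum length of Palindromes is: 20
Maximum gap between elements is: 10
Number of mismatches allowed in Palindrome: 1

Palindromes:
4     STACR    8
      || ||
20    GARGC    16
```

The block reads: left arm `STACR` at 1-based positions 4–8; right arm at
16–20, printed 3'-first (`GARGC` is positions 20→16), so each column pairs
partner symbols.  The bars mark matching pairs under the active scheme —
`S`·`G` match (S = {C,G} contains C, the complement of G), `A`·`R` at the
third column do not (R = {A,G} contains no complement of A), which is the one
mismatch spent.  The gap between the arms here is 7.

Flags mirror EMBOSS `palindrome` usage: `-f` input FASTA, `-s` sequence name,
`-o` output file, `-m`/`-M` arm-length range, `-g` maximum gap, `-x` allowed
mismatches (default 0), plus `--scheme {simple,degenerate}` and `--tsv PATH`
for a machine-readable sidecar.  `invrep compare A B` diffs two result files
as IR sets.

Library use:

```python
import invrep as iv
seq = iv.read_fasta("demo.fasta", "demo")
irs = iv.find_inverted_repeats(seq, iv.SearchParams(5, 20, 10, 1))
# [InvertedRepeat(left_start=3, left_end=8, right_start=15, right_end=20, mismatches=1)]
```

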