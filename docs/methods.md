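# Methods

## Model

A gapped inverted repeat (IR) within *k* mismatches is a substring of the
form *W G W̄ᴿ* with δ_H(W, W̄ᴿ) ≤ k, where the complement is the Watson–Crick
bijection A↔T, C↔G extended to the IUPAC alphabet.  An IR is identified by
its two arm intervals; the gap length is derived (`right_start − left_end`),
not an independent degree of freedom.  Internally all coordinates are 0-based
half-open; the 1-based inclusive convention appears only at the output layer.

Degenerate symbols are modelled as base sets.  Matching schemes are boolean
relations over the 15 × 15 code pairs, precomputed as data (a `MatchMatrix`)
so the search stays scheme-agnostic:

* *simple*: `a` matches `b` iff `a` is the unique complement code of `b`
  (elementwise complement of the base set; an involution, e.g. B↔V, N↔N).
* *degenerate*: `a` matches `b` iff `base_set(a)` intersects the elementwise
  complement of `base_set(b)`.  Strictly contains the simple relation.

Any registered scheme must contain the simple relation.  This is a soundness
precondition, not a stylistic one: the indexed walk crosses literal
complement-text hits without consulting the matrix (see below), so a scheme
rejecting some unique-complement pair would be applied unsoundly.  The matrix
builder verifies the precondition and refuses violating schemes.  The
`U` → `T` and `*` → `N` aliases and lowercase are folded at input time and
never appear internally.

## Search procedure

One generalized index is built over `X · s1 · rc(X) · s2`, where
`rc(X)[i] = simple_complement(X[n−1−i])` and the sentinels are two distinct
control characters sorting below the alphabet.  The suffix array is computed
by numpy prefix doubling, the LCP array by Kasai's algorithm, and range
minima by a sparse table, giving O(1) literal longest-common-extension (LCE)
between any forward position and any reverse-complement position.  Building
one concatenated index rather than two separate ones changes nothing
semantically: the same LCE queries are answered with a single RMQ structure.

Writing `rc(X)` with the *unique* complement makes literal equality exactly a
simple-scheme match of the underlying symbols — an under-approximation of
every admissible scheme.  The mismatch-budgeted (kangaroo) walk therefore
chains literal LCE jumps and adjudicates each literal stop with the match
matrix: a degenerate match that literal equality missed is crossed free of
charge; a true mismatch consumes budget.  No false match is ever silently
accepted, and per query the number of LCE jumps is at most
`budget + 1 + (number of degenerate adjudications in the walked region)`.
Degenerate positions are rare in variant-derived sequences, so the extra
stops are cheap.

Centres are the 2n − 1 half-integer positions; pair *t* at a centre aligns
`X[lo − t]` with `X[hi + t]` where (`lo`, `hi`) are the innermost pair
positions.  Gap parity is fixed by centre parity: a centre on a symbol leaves
that symbol unpaired (minimal gap 1, odd gaps), a centre between symbols has
minimal gap 0 (even gaps).  Per centre, for j = 0, 1, 2, … the gap grows to
the smallest value of the right parity excluding the first *j* mismatching
pairs; the arm then starts just outside the gap and extends to the position
adjacent to the (k+1)-th remaining mismatch, the arm cap M, or the boundary,
and is trimmed inward so the outermost pair matches (candidates trimmed below
the minimum arm length m are discarded).  Mismatch offsets are discovered
lazily — only as many as the gap bound and budget require — and may be shared
across parameter sets through an optional per-centre cache.  Uniqueness key
is the arm-interval pair; output order is (left start ascending, right end
descending, gap ascending), fixed for reproducible diffs.

Only the minimal gap per swallowed-mismatch count is emitted: intermediate
gap values would yield arms extendable inward, i.e. non-maximal IRs.
Maximality of an emitted IR is definitional: no strictly larger valid arm
(outermost pair matching, ≤ k mismatches, ≤ M) exists at its centre and gap.
Note the naive phrasing "adding one more outward pair exceeds the budget" is
weaker and not always true for trimmed arms — the next outward pair may be a
within-budget mismatch that merely violates the outermost-match rule; tests
and the acceptance script check the definitional form.

### Scheme relations

The degenerate scheme finds at least what the simple scheme finds, but *as
coverage, not as tuple equality*: when a simple-mismatch pair is a free
degenerate match, the maximal degenerate IR extends past it, so its arm
intervals differ from those of the simple IR it contains.  The precise
relation checked is: for every simple-scheme IR with pair range
[t_s, t_e) at a centre, the degenerate-scheme IR starting at the largest
degenerate swallow candidate ≤ t_s contains its pairs, unless
`t_start + M < t_e` (the arm cap blocks the covering arm; never observed on
the default grid).  On solid input the schemes produce identical output.

## Parameters

| parameter | meaning | default |
|---|---|---|
| `min_arm` (m) | minimum arm length, symbols | 10 |
| `max_arm` (M) | maximum arm length, symbols | 100 |
| `max_gap` (g) | maximum spacer length, symbols | 100 |
| `max_mismatch` (k) | mismatch budget per IR | 0 |
| `scheme` | complement-matching relation | `degenerate` |

The arm/gap defaults are the conventional settings for genome-scale IR scans
and are what the CLI uses when flags are omitted; the mismatch default is the
most conservative choice.  `min_arm ≥ 1`, `max_arm ≥ min_arm`,
`max_gap ≥ 0`, `max_mismatch ≥ 0` are validated before any search.

## Synthetic data

`random_iupac_sequence` draws i.i.d. positions: solid with probability
`solid_fraction` (uniform over A/C/G/T), otherwise from a weight table over
the 11 ambiguity codes.  The default table puts 90% of the non-solid mass on
the six two-base codes (R,Y,S,W,K,M) — the signature of biallelic SNPs, which
dominate variant-derived IUPAC genomes — and 2% each on B/D/H/V/N.  The
default non-solid rate is 10%.

What this emulates: the symbol composition of a reference-plus-variants
consensus.  What it does not: positional structure of real genomes —
repeats, GC skew, clustered variation, long homopolymers.  Passing tests
therefore certify algorithmic correctness (the properties hold for *any*
input, and the oracle comparison is exact), not biological realism of IR
density; reported IR counts on generated sequences characterise random
sequence, not chromosomes.

## Verification

* **Oracle equivalence.** `brute_force_find_irs` re-derives every centre's
  pair-match profile directly from the match matrix and picks each arm end
  by a definition-level "largest valid extension" rule; it never touches the
  index machinery.  The default grid pairs 18 generated sequences (lengths
  50/120/300; fully solid and 10% degenerate; three seeds) with 144
  parameter combinations (m ∈ {2,3,10}, M ∈ {20,100}, g ∈ {0,5,100},
  k ∈ {0,1,2,4}, both schemes) — 2,592 runs compared for set identity, plus
  a derandomized property test over random short sequences.
* **Per-IR revalidation.** Every reported IR is re-checked pair-by-pair by
  an independent scanner in the tests (bounds, gap, mismatch count,
  outermost match, definitional maximality).
* **Index layer.** Suffix array, LCP, literal LCE and kangaroo walks are
  compared against full naive sorts/scans on all fixture sequences up to
  200 symbols.
* **Invariants.** Reverse-complement mirror symmetry, budget monotonicity
  (each IR grows, at its centre and gap, when k increases by one),
  scheme coverage and solid-input scheme equality hold across the grid.
* **Scale.** A 100,000-symbol generated sequence at the default parameters
  with k = 2 completes in well under a minute with modest memory; sampled
  results revalidate.  Problem sizes throughout (grid dimensions, query
  sample counts, the 100 kb length) are the package's chosen verification
  conditions.

## Numerical and degenerate-input choices

* Ties in the suffix sort are broken by rank doubling; distinctness is
  guaranteed by the unique terminal sentinel, so no comparator tie-break is
  needed.
* Sequences shorter than `2 · min_arm` yield an empty result by
  construction; the empty sequence is rejected at validation.
* Centres whose maximal pair count is below `min_arm`, and on-symbol centres
  when `max_gap = 0`, are skipped outright.
* A search may reuse a prebuilt index and per-centre mismatch cache across
  parameter sets; results are independent of whether a cache is supplied.
* Output is byte-deterministic; the preamble's exact layout is this
  package's own documented format (the three-line blocks are the
  EMBOSS-compatible contract).

## Known limitations

* The brute-force oracle is quadratic and intended for sequences up to a few
  hundred symbols.
* Arm-interval uniqueness means IRs that EMBOSS might merge or suppress by
  its own (undocumented) conventions are all reported individually; no
  clustering or overlap merging is performed.
* Weighted/scored IR models (match/mismatch scoring with indel-tolerant
  arms) are out of scope, as are protein/RNA alphabets and quality-aware
  matching.
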