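"""Independent naive reference computations used only by the test suite.

Everything here recomputes results straight from definitions (direct scans,
full sorts), deliberately sharing no code with the indexed implementation.
"""

from invrep import InvertedRepeat, MatchMatrix, SearchParams


def naive_suffix_array(text: str) -> list[int]:
    return sorted(range(len(text)), key=lambda i: text[i:])


def naive_lcp(text: str, sa: list[int]) -> list[int]:
    out = [0] * len(sa)
    for r in range(1, len(sa)):
        a, b = text[sa[r - 1]:], text[sa[r]:]
        h = 0
        while h < len(a) and h < len(b) and a[h] == b[h]:
            h += 1
        out[r] = h
    return out


def naive_lce(text: str, i: int, j: int) -> int:
    h = 0
    while i + h < len(text) and j + h < len(text) and text[i + h] == text[j + h]:
        h += 1
    return h


def naive_kangaroo(
    symbols: str,
    fwd_pos: int,
    rc_pos: int,
    budget: int,
    matrix: MatchMatrix,
    max_pairs: int,
) -> tuple[int, tuple[int, ...]]:
    """Pair-by-pair scan with the same pairing and stop rules as the index."""
    n = len(symbols)
    limit = max(0, min(max_pairs, n - fwd_pos, n - rc_pos))
    mism: list[int] = []
    matched = limit
    for s in range(limit):
        if not matrix.match(symbols[fwd_pos + s], symbols[n - 1 - rc_pos - s]):
            mism.append(s)
            if len(mism) > budget:
                matched = s
                break
    return matched, tuple(mism)


def centre_geometry(twice_centre: int, n: int) -> tuple[int, int, int, int]:
    if twice_centre % 2 == 0:
        lo, hi, gap0 = twice_centre // 2 - 1, twice_centre // 2 + 1, 1
    else:
        lo = twice_centre // 2
        hi, gap0 = lo + 1, 0
    return lo, hi, gap0, min(lo + 1, n - hi)


def naive_mismatch_offsets(
    symbols: str, twice_centre: int, matrix: MatchMatrix
) -> list[int]:
    """All truly-mismatching pair offsets at a centre, by outward scanning."""
    n = len(symbols)
    lo, hi, _, T = centre_geometry(twice_centre, n)
    return [
        t for t in range(T) if not matrix.match(symbols[lo - t], symbols[hi + t])
    ]


def validate_ir(
    symbols: str, ir: InvertedRepeat, params: SearchParams, matrix: MatchMatrix
) -> list[str]:
    """Re-validate one reported IR from scratch; returns failure descriptions."""
    n = len(symbols)
    errs = []
    ls, le, rs, re = ir.left_start, ir.left_end, ir.right_start, ir.right_end
    if not (0 <= ls < le <= rs < re <= n):
        errs.append(f"bad interval bounds {(ls, le, rs, re)}")
        return errs
    if le - ls != re - rs:
        errs.append("arms differ in length")
        return errs
    arm = le - ls
    if not params.min_arm <= arm <= params.max_arm:
        errs.append(f"arm length {arm} outside [{params.min_arm}, {params.max_arm}]")
    gap = rs - le
    if not 0 <= gap <= params.max_gap:
        errs.append(f"gap {gap} outside [0, {params.max_gap}]")
    bad = [
        i for i in range(arm) if not matrix.match(symbols[ls + i], symbols[re - 1 - i])
    ]
    if len(bad) != ir.mismatches:
        errs.append(f"stored mismatches {ir.mismatches} != recomputed {len(bad)}")
    if len(bad) > params.max_mismatch:
        errs.append(f"{len(bad)} mismatches exceed budget {params.max_mismatch}")
    if bad and bad[0] == 0:
        errs.append("outermost pair does not match")
    return errs


def is_maximal(
    symbols: str, ir: InvertedRepeat, params: SearchParams, matrix: MatchMatrix
) -> bool:
    """No strictly larger valid arm exists at the same centre and gap.

    Larger means extending outward to any end whose outermost pair matches
    while staying within the mismatch budget and the arm cap.  The mismatch
    count is nondecreasing in the extension, so the scan stops as soon as the
    budget is exceeded.
    """
    n = len(symbols)
    lo, hi, _, T = centre_geometry(ir.left_start + ir.right_end - 1, n)
    t_start = ir.right_start - hi
    t_end = ir.right_end - hi
    count = ir.mismatches
    for e in range(t_end + 1, min(t_start + params.max_arm, T) + 1):
        if not matrix.match(symbols[lo - (e - 1)], symbols[hi + e - 1]):
            count += 1
            if count > params.max_mismatch:
                return True
        elif count <= params.max_mismatch:
            return False
    return True


def mirror_ir(ir: InvertedRepeat, n: int) -> InvertedRepeat:
    """Coordinate image of an IR under reverse complementation of the sequence."""
    return InvertedRepeat(
        left_start=n - ir.right_end,
        left_end=n - ir.right_start,
        right_start=n - ir.left_end,
        right_end=n - ir.left_start,
        mismatches=ir.mismatches,
    )
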