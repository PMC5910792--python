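"""Independent brute-force oracles used only by the test suite.

The alignment oracle re-implements the package's identity definition from
scratch as an explicit three-state affine-gap dynamic program with full
traceback enumeration.  It shares nothing with the implementation path
(which delegates to Biopython) beyond the scoring constants, and is only
feasible for short sequences.
"""

from __future__ import annotations

from functools import lru_cache

MATCH = 1.0
MISMATCH = -2.0
OPEN = -10.0
EXTEND = -1.0
END = -1.0  # terminal gap, per position

NEG = float("-inf")

# states: 0 = M (column consumes both), 1 = D (gap in b, consumes a),
#         2 = I (gap in a, consumes b)


def _dp(a: str, b: str):
    n, m = len(a), len(b)

    @lru_cache(maxsize=None)
    def best(i: int, j: int, state: int) -> float:
        if i == 0 and j == 0:
            return 0.0 if state == 0 else NEG
        if state == 0:
            if i == 0 or j == 0:
                return NEG
            sub = MATCH if a[i - 1] == b[j - 1] else MISMATCH
            return max(best(i - 1, j - 1, s) for s in range(3)) + sub
        if state == 1:  # gap in b at column consuming a[i-1]
            if i == 0:
                return NEG
            if j == 0 or j == m:  # terminal for b
                return max(best(i - 1, j, s) for s in range(3)) + END
            return max(best(i - 1, j, 1) + EXTEND,
                       max(best(i - 1, j, 0), best(i - 1, j, 2)) + OPEN)
        if j == 0:
            return NEG
        if i == 0 or i == n:  # terminal for a
            return max(best(i, j - 1, s) for s in range(3)) + END
        return max(best(i, j - 1, 2) + EXTEND,
                   max(best(i, j - 1, 0), best(i, j - 1, 1)) + OPEN)

    return best


def oracle_global(a: str, b: str, max_paths: int = 100000) -> tuple[float, set[float]]:
    """Optimal score and the set of identities over all optimal alignments.

    Identity is 100 * matches / columns with leading and trailing gap
    columns stripped, exactly the package's definition.
    """
    n, m = len(a), len(b)
    best = _dp(a, b)
    score = max(best(n, m, s) for s in range(3))

    identities: set[float] = set()
    paths = 0

    def backtrack(i: int, j: int, state: int, cols: list[tuple[str, str]]) -> None:
        nonlocal paths
        if paths >= max_paths:
            return
        if i == 0 and j == 0:
            if state == 0:
                paths += 1
                identities.add(_identity(cols))
            return
        target = best(i, j, state)
        if target == NEG:
            return
        if state == 0:
            sub = MATCH if a[i - 1] == b[j - 1] else MISMATCH
            for s in range(3):
                if best(i - 1, j - 1, s) + sub == target:
                    backtrack(i - 1, j - 1, s, [(a[i - 1], b[j - 1])] + cols)
        elif state == 1:
            col = [(a[i - 1], "-")]
            if j == 0 or j == m:
                for s in range(3):
                    if best(i - 1, j, s) + END == target:
                        backtrack(i - 1, j, s, col + cols)
            else:
                if best(i - 1, j, 1) + EXTEND == target:
                    backtrack(i - 1, j, 1, col + cols)
                for s in (0, 2):
                    if best(i - 1, j, s) + OPEN == target:
                        backtrack(i - 1, j, s, col + cols)
        else:
            col = [("-", b[j - 1])]
            if i == 0 or i == n:
                for s in range(3):
                    if best(i, j - 1, s) + END == target:
                        backtrack(i, j - 1, s, col + cols)
            else:
                if best(i, j - 1, 2) + EXTEND == target:
                    backtrack(i, j - 1, 2, col + cols)
                for s in (0, 1):
                    if best(i, j - 1, s) + OPEN == target:
                        backtrack(i, j - 1, s, col + cols)

    for s in range(3):
        if best(n, m, s) == score:
            backtrack(n, m, s, [])
    return score, identities


def _identity(cols: list[tuple[str, str]]) -> float:
    lo, hi = 0, len(cols)
    while lo < hi and ("-" in cols[lo]):
        lo += 1
    while hi > lo and ("-" in cols[hi - 1]):
        hi -= 1
    window = cols[lo:hi]
    if not window:
        return 0.0
    matches = sum(1 for x, y in window if x == y and x != "-")
    return 100.0 * matches / len(window)


def oracle_lcr_counts(records, rank_order):
    """Brute-force LCR table counts from (identity_int, names_a, names_b) triples.

    ``records`` is an iterable of (d, names_a, names_b) where names are name
    tuples aligned to the rank order.  Re-derives the lowest common rank by
    direct comparison, independently of the package.
    """
    counts: dict[int, dict] = {}
    for d, na, nb in records:
        shared = None
        for idx in range(min(len(na), len(nb)) - 1, -1, -1):
            if na[idx] == nb[idx]:
                shared = rank_order[idx]
                break
        row = counts.setdefault(d, {})
        row[shared] = row.get(shared, 0) + 1
    return counts
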