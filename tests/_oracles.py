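"""Independent test oracles, kept deliberately separate from the package.

``levenshtein_dp`` is a plain quadratic dynamic program; the package's
edit-distance engine is a global aligner, so the two routes are independent.
``best_matching_enum`` enumerates every matching of a score matrix and
returns the lexicographically largest one (pairs compared by descending
score); with distinct scores this is exactly what a greedy best-first sweep
must produce.
"""

from __future__ import annotations

from itertools import combinations


def levenshtein_dp(a: str, b: str) -> int:
    """Textbook two-row DP for unit-cost edit distance."""
    if len(a) < len(b):
        a, b = b, a
    if not b:
        return len(a)
    prev = list(range(len(b) + 1))
    for i, ca in enumerate(a, 1):
        cur = [i]
        for j, cb in enumerate(b, 1):
            cur.append(min(prev[j] + 1,          # deletion
                           cur[j - 1] + 1,       # insertion
                           prev[j - 1] + (ca != cb)))  # substitution
        prev = cur
    return prev[-1]


def _all_matchings(pairs: list):
    """Yield every (possibly empty) set of pairwise-disjoint pairs."""
    yield []
    for r in range(1, len(pairs) + 1):
        for combo in combinations(pairs, r):
            rows = [p[0] for p in combo]
            cols = [p[1] for p in combo]
            if len(set(rows)) == len(rows) and len(set(cols)) == len(cols):
                yield list(combo)


def best_matching_enum(scores: dict) -> list:
    """Exhaustive-enumeration assignment oracle.

    ``scores`` maps (row, col) -> score for the *passing* pairs only.
    Returns the matching whose descending-sorted score tuple is
    lexicographically largest, as a sorted list of (row, col) pairs.
    Assumes all scores are distinct so the optimum is unique.
    """
    best_key: tuple = ()
    best: list = []
    for matching in _all_matchings(list(scores)):
        key = tuple(sorted((scores[p] for p in matching), reverse=True))
        if key > best_key:
            best_key = key
            best = matching
    return sorted(best)
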