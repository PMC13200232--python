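"""Independent scoring oracles used to validate the production aligner.

Two formulations, neither sharing code with the package:

* ``enumerate_local_score`` — literal enumeration of every local alignment
  path (exponential; only usable on very short strings).  Alignments start
  with a match column; gap runs cost open for their first residue and extend
  afterwards, with a fresh open when the gap switches sides.
* ``recursive_local_score`` — top-down memoised recursion over (i, j, state)
  cell states.  Polynomial, usable for the large pair sweeps.
"""

from __future__ import annotations

import sys
from functools import lru_cache

from Bio.Align import substitution_matrices

_MATRICES: dict[str, object] = {}


def sub_score(a: str, b: str, matrix_name: str = "BLOSUM62") -> float:
    if matrix_name not in _MATRICES:
        _MATRICES[matrix_name] = substitution_matrices.load(matrix_name)
    return float(_MATRICES[matrix_name][a, b])


def enumerate_local_score(
    q: str, t: str, open_gap: float = -20.0, extend_gap: float = -5.0,
    matrix_name: str = "BLOSUM62",
) -> float:
    """Best local score by enumerating all alignment paths (tiny inputs only)."""
    n, m = len(q), len(t)
    best = 0.0

    def rec(i: int, j: int, score: float, last: str) -> None:
        nonlocal best
        if score > best:
            best = score
        if i < n and j < m:
            rec(i + 1, j + 1, score + sub_score(q[i], t[j], matrix_name), "M")
        # gap columns never start an alignment
        if i < n:
            cost = extend_gap if last == "Q" else open_gap
            rec(i + 1, j, score + cost, "Q")
        if j < m:
            cost = extend_gap if last == "T" else open_gap
            rec(i, j + 1, score + cost, "T")

    for i0 in range(n):
        for j0 in range(m):
            rec(i0 + 1, j0 + 1, sub_score(q[i0], t[j0], matrix_name), "M")
    return best


def recursive_local_score(
    q: str, t: str, open_gap: float = -20.0, extend_gap: float = -5.0,
    matrix_name: str = "BLOSUM62",
) -> float:
    """Best local score via memoised recursion over alignment end states."""
    NEG = float("-inf")
    sys.setrecursionlimit(10000)

    @lru_cache(maxsize=None)
    def end(i: int, j: int, state: str) -> float:
        # best score of a local alignment whose last column ends at (i, j)
        # (1-based inclusive) in the given state
        if state == "M":
            if i < 1 or j < 1:
                return NEG
            here = sub_score(q[i - 1], t[j - 1], matrix_name)
            prev = max(0.0, end(i - 1, j - 1, "M"), end(i - 1, j - 1, "Q"),
                       end(i - 1, j - 1, "T"))
            return here + prev
        if state == "Q":  # gap in target, consumes q[i-1]
            if i < 2 or j < 1:
                return NEG
            return max(
                end(i - 1, j, "M") + open_gap,
                end(i - 1, j, "Q") + extend_gap,
                end(i - 1, j, "T") + open_gap,
            )
        # state == "T": gap in query, consumes t[j-1]
        if j < 2 or i < 1:
            return NEG
        return max(
            end(i, j - 1, "M") + open_gap,
            end(i, j - 1, "Q") + extend_gap,
            end(i, j - 1, "T") + open_gap,
        )

    best = 0.0
    for i in range(1, len(q) + 1):
        for j in range(1, len(t) + 1):
            s = end(i, j, "M")
            if s > best:
                best = s
    return best
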