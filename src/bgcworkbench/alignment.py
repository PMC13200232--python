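"""Pairwise local protein alignment with affine gaps, and the homology predicate.

The comparison engine decides whether two genes are homologous from a single
Smith-Waterman-style local alignment under an affine gap model: the first
residue of a gap costs ``open_gap_score`` and every further residue costs
``extend_gap_score`` (a gap of length L costs ``open + (L-1) * extend``).
Defaults follow the tool's published configuration: BLOSUM62, open gap -20,
extend gap -5, identity cutoff 40% (inclusive) and query coverage strictly
above 50%.

Identity is counted over *all* alignment columns, gap columns included; this
is the conservative choice (gappy matches are penalised) and is centralised
here so it can be revisited in one place.  Coverage is always relative to the
query, which by convention is the anchor gene (reference CBG, known VSTG or
bench gene).

Tie-breaking is deterministic: among equal-scoring local alignments the one
ending at the smallest query position, then the smallest target position, is
returned; within the traceback, match columns are preferred over query-gap
columns over target-gap columns, and restarting the alignment is preferred
when the running score ties zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
from Bio.Align import substitution_matrices
from numba import njit

#: residues accepted in protein sequences (20 canonical amino acids plus X)
PROTEIN_ALPHABET = "ACDEFGHIKLMNPQRSTVWYX"

_NEG_INF = -1.0e30

# traceback states
_STATE_MATCH = 0  # column consumes one query and one target residue
_STATE_QGAP = 1   # gap in target: column consumes one query residue
_STATE_TGAP = 2   # gap in query: column consumes one target residue


@dataclass(frozen=True)
class AlignmentParams:
    """Scoring scheme and homology thresholds.

    matrix_name: name of a packaged substitution matrix (e.g. BLOSUM62).
    open_gap_score / extend_gap_score: affine gap scores (non-positive;
        opening must not be milder than extending).
    identity_threshold: minimum identity fraction for homology (inclusive).
    coverage_threshold: query-coverage fraction that must be exceeded
        (strict) for homology.
    """

    matrix_name: str = "BLOSUM62"
    open_gap_score: float = -20.0
    extend_gap_score: float = -5.0
    identity_threshold: float = 0.40
    coverage_threshold: float = 0.50

    def __post_init__(self) -> None:
        if not (self.open_gap_score <= self.extend_gap_score <= 0):
            raise ValueError(
                "gap scores must satisfy open_gap_score <= extend_gap_score <= 0, "
                f"got open={self.open_gap_score}, extend={self.extend_gap_score}"
            )
        for name in ("identity_threshold", "coverage_threshold"):
            value = getattr(self, name)
            if not (0.0 <= value <= 1.0):
                raise ValueError(f"{name} must be in [0, 1], got {value}")


@dataclass(frozen=True)
class AlignmentResult:
    """Outcome of one pairwise local alignment.

    ``trace`` holds the two aligned strings (query row, target row) with
    ``-`` for gaps; both are empty for an empty alignment.
    """

    score: float
    n_columns: int
    n_identical: int
    identity: float
    query_aligned: int
    query_coverage: float
    trace: tuple[str, str] = field(default=("", ""))

    @property
    def is_empty(self) -> bool:
        return self.n_columns == 0


@lru_cache(maxsize=8)
def _load_matrix(matrix_name: str) -> tuple[np.ndarray, dict[str, int]]:
    """Load a named substitution matrix as a dense array over PROTEIN_ALPHABET."""
    mat = substitution_matrices.load(matrix_name)
    n = len(PROTEIN_ALPHABET)
    dense = np.zeros((n, n), dtype=np.float64)
    for i, a in enumerate(PROTEIN_ALPHABET):
        for j, b in enumerate(PROTEIN_ALPHABET):
            dense[i, j] = mat[a, b]
    index = {aa: i for i, aa in enumerate(PROTEIN_ALPHABET)}
    return dense, index


def _encode(seq: str, index: dict[str, int], role: str) -> np.ndarray:
    if not seq:
        raise ValueError(f"{role} sequence is empty")
    try:
        return np.array([index[c] for c in seq], dtype=np.int64)
    except KeyError as exc:
        raise ValueError(
            f"{role} sequence contains residue {exc.args[0]!r} outside the "
            f"alphabet {PROTEIN_ALPHABET}"
        ) from None


@njit(cache=False)
def _sw_affine(q, t, S, gap_open, gap_extend):  # pragma: no cover - numba
    """Affine-gap Smith-Waterman over encoded sequences.

    Returns (best score, end_i, end_j, end_state, pointer matrices).
    Pointer codes: 0 = start (M only), 1 = from M, 2 = from Q-gap state,
    3 = from T-gap state.
    """
    m = q.shape[0]
    n = t.shape[0]
    M = np.full((m + 1, n + 1), _NEG_INF)
    QG = np.full((m + 1, n + 1), _NEG_INF)  # gap in target (consumes query)
    TG = np.full((m + 1, n + 1), _NEG_INF)  # gap in query (consumes target)
    PM = np.zeros((m + 1, n + 1), dtype=np.int8)
    PQ = np.zeros((m + 1, n + 1), dtype=np.int8)
    PT = np.zeros((m + 1, n + 1), dtype=np.int8)

    best = 0.0
    best_i = 0
    best_j = 0
    best_state = _STATE_MATCH

    for i in range(1, m + 1):
        for j in range(1, n + 1):
            sub = S[q[i - 1], t[j - 1]]
            # match state: fresh start preferred on ties, then M, QG, TG
            b = 0.0
            p = 0
            if M[i - 1, j - 1] > b:
                b = M[i - 1, j - 1]
                p = 1
            if QG[i - 1, j - 1] > b:
                b = QG[i - 1, j - 1]
                p = 2
            if TG[i - 1, j - 1] > b:
                b = TG[i - 1, j - 1]
                p = 3
            M[i, j] = sub + b
            PM[i, j] = p

            # gap in target (vertical, consumes query residue i)
            b = M[i - 1, j] + gap_open
            p = 1
            if QG[i - 1, j] + gap_extend > b:
                b = QG[i - 1, j] + gap_extend
                p = 2
            if TG[i - 1, j] + gap_open > b:
                b = TG[i - 1, j] + gap_open
                p = 3
            QG[i, j] = b
            PQ[i, j] = p

            # gap in query (horizontal, consumes target residue j)
            b = M[i, j - 1] + gap_open
            p = 1
            if QG[i, j - 1] + gap_open > b:
                b = QG[i, j - 1] + gap_open
                p = 2
            if TG[i, j - 1] + gap_extend > b:
                b = TG[i, j - 1] + gap_extend
                p = 3
            TG[i, j] = b
            PT[i, j] = p

            # end-cell bookkeeping: strict > keeps the smallest (i, j) on ties;
            # optimal local alignments end in a match column.
            if M[i, j] > best:
                best = M[i, j]
                best_i = i
                best_j = j
                best_state = _STATE_MATCH

    return best, best_i, best_j, best_state, PM, PQ, PT


def align_local(query: str, target: str, params: AlignmentParams | None = None) -> AlignmentResult:
    """Optimal local alignment of ``query`` against ``target``.

    Raises ValueError for empty sequences or residues outside the 20+X
    alphabet.  An all-negative scoring landscape yields the empty alignment
    (score 0, identity 0, coverage 0).
    """
    if params is None:
        params = AlignmentParams()
    S, index = _load_matrix(params.matrix_name)
    q = _encode(query, index, "query")
    t = _encode(target, index, "target")

    score, end_i, end_j, state, PM, PQ, PT = _sw_affine(
        q, t, S, float(params.open_gap_score), float(params.extend_gap_score)
    )
    if score <= 0.0:
        return AlignmentResult(0.0, 0, 0, 0.0, 0, 0.0, ("", ""))

    # traceback
    cols_q: list[str] = []
    cols_t: list[str] = []
    i, j = end_i, end_j
    while True:
        if state == _STATE_MATCH:
            pred = PM[i, j]
            cols_q.append(query[i - 1])
            cols_t.append(target[j - 1])
            i -= 1
            j -= 1
            if pred == 0:
                break
        elif state == _STATE_QGAP:
            pred = PQ[i, j]
            cols_q.append(query[i - 1])
            cols_t.append("-")
            i -= 1
        else:
            pred = PT[i, j]
            cols_q.append("-")
            cols_t.append(target[j - 1])
            j -= 1
        state = pred - 1  # 1,2,3 -> _STATE_MATCH,_STATE_QGAP,_STATE_TGAP

    aligned_q = "".join(reversed(cols_q))
    aligned_t = "".join(reversed(cols_t))
    n_columns = len(aligned_q)
    n_identical = sum(1 for a, b in zip(aligned_q, aligned_t) if a == b and a != "-")
    query_aligned = sum(1 for a in aligned_q if a != "-")
    return AlignmentResult(
        score=float(score),
        n_columns=n_columns,
        n_identical=n_identical,
        identity=n_identical / n_columns,
        query_aligned=query_aligned,
        query_coverage=query_aligned / len(query),
        trace=(aligned_q, aligned_t),
    )


def is_homologue(result: AlignmentResult, params: AlignmentParams | None = None) -> bool:
    """Homology decision: identity >= threshold AND coverage > threshold.

    The identity bound is inclusive ("at least 40%"); the coverage bound is
    strict ("over 50%").
    """
    if params is None:
        params = AlignmentParams()
    return (
        result.identity >= params.identity_threshold
        and result.query_coverage > params.coverage_threshold
    )
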