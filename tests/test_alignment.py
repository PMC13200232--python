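"""Local aligner: oracle equivalence, cross-checks, and the homology predicate."""

import random

import pytest
from Bio.Align import PairwiseAligner, substitution_matrices
from hypothesis import given, settings
from hypothesis import strategies as st

from bgcworkbench import AlignmentParams, AlignmentResult, align_local, is_homologue

from _oracles import enumerate_local_score, recursive_local_score

AA4 = "ACDW"  # four residues spanning strongly positive and negative scores


def _all_seqs(alphabet: str, max_len: int):
    seqs = []
    frontier = [""]
    for _ in range(max_len):
        frontier = [s + a for s in frontier for a in alphabet]
        seqs.extend(frontier)
    return seqs


class TestScoreCorrectness:
    def test_path_enumeration_agrees_with_recursive_oracle_and_aligner(self):
        """On every pair of length <= 3 over a 4-letter alphabet, the literal
        path enumeration, the recursive cell-state oracle, and the production
        aligner give the same optimal local score."""
        seqs = _all_seqs(AA4, 3)
        for q in seqs:
            for t in seqs:
                brute = enumerate_local_score(q, t)
                rec = recursive_local_score(q, t)
                mine = align_local(q, t).score
                assert brute == rec == mine, (q, t, brute, rec, mine)

    def test_random_pairs_match_recursive_oracle(self):
        rng = random.Random(11)
        seqs = _all_seqs(AA4, 6)
        for _ in range(1500):
            q, t = rng.choice(seqs), rng.choice(seqs)
            assert align_local(q, t).score == recursive_local_score(q, t)

    def test_agrees_with_biopython_pairwise_aligner_on_proteins(self):
        aligner = PairwiseAligner()
        aligner.mode = "local"
        aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
        aligner.open_gap_score = -20
        aligner.extend_gap_score = -5
        rng = random.Random(5)
        aas = "ACDEFGHIKLMNPQRSTVWYX"
        for _ in range(120):
            q = "".join(rng.choice(aas) for _ in range(rng.randint(5, 80)))
            t = "".join(rng.choice(aas) for _ in range(rng.randint(5, 80)))
            assert align_local(q, t).score == max(0.0, aligner.score(q, t))

    def test_known_example_scores(self):
        assert align_local("MKT", "MKT").score == 5 + 5 + 5
        res = align_local("HEAGAWGHEE", "PAWHEAE")
        assert res.score == recursive_local_score("HEAGAWGHEE", "PAWHEAE")


class TestResultGeometry:
    def test_self_alignment_is_perfect(self):
        res = align_local("MKTAYIAKQR", "MKTAYIAKQR")
        assert res.identity == 1.0 and res.query_coverage == 1.0
        assert res.trace == ("MKTAYIAKQR", "MKTAYIAKQR")

    def test_all_negative_landscape_gives_empty_alignment(self):
        # every W<->G substitution scores negative in BLOSUM62
        mat = substitution_matrices.load("BLOSUM62")
        assert mat["W", "G"] < 0
        res = align_local("WWWW", "GGGG")
        assert res == AlignmentResult(0.0, 0, 0, 0.0, 0, 0.0, ("", ""))

    def test_identity_counts_gap_columns_in_denominator(self):
        # force a gap: query has an extra residue inside a conserved block
        q = "MKTAYIAKQRQISFVKSHFSRQ"
        t = q[:10] + q[11:]
        res = align_local(q, t)
        assert "-" in res.trace[1]
        assert res.n_columns == len(res.trace[0])
        assert res.identity == res.n_identical / res.n_columns
        assert res.n_identical < res.n_columns

    def test_coverage_is_query_relative(self):
        # target embeds only half of the query
        q = "MKTAYIAKQRWWNDPC"
        t = "GGG" + q[:8] + "GGG"
        res = align_local(q, t)
        assert res.query_aligned <= 8 + 3
        assert res.query_coverage == res.query_aligned / len(q)

    @pytest.mark.parametrize("q,t", [("", "MKT"), ("MKT", ""), ("M1T", "MKT"), ("MKT", "mkt")])
    def test_invalid_inputs_raise(self, q, t):
        with pytest.raises(ValueError):
            align_local(q, t)

    def test_determinism(self):
        res1 = align_local("MKTWYHEAGAWGHEE", "PAWHEAEKTWY")
        res2 = align_local("MKTWYHEAGAWGHEE", "PAWHEAEKTWY")
        assert res1 == res2


@settings(max_examples=150, deadline=None, derandomize=True)
@given(
    q=st.text(alphabet=AA4, min_size=1, max_size=12),
    t=st.text(alphabet=AA4, min_size=1, max_size=12),
)
def test_score_symmetry(q, t):
    """score(a, b) == score(b, a) under a symmetric matrix."""
    assert align_local(q, t).score == align_local(t, q).score


@settings(max_examples=100, deadline=None, derandomize=True)
@given(seq=st.text(alphabet="ACDEFGHIKLMNPQRSTVWY", min_size=1, max_size=30))
def test_self_alignment_property(seq):
    """Any sequence with positive diagonal scores aligns perfectly to itself."""
    res = align_local(seq, seq)
    assert res.identity == 1.0 and res.query_coverage == 1.0


class TestHomologyPredicate:
    def _result(self, identity, coverage):
        n = 100
        return AlignmentResult(
            score=50.0,
            n_columns=n,
            n_identical=int(identity * n),
            identity=identity,
            query_aligned=int(coverage * n),
            query_coverage=coverage,
        )

    @pytest.mark.parametrize(
        "identity,coverage,expected",
        [
            (0.40, 0.60, True),    # identity bound inclusive
            (0.39, 0.90, False),   # below identity cutoff
            (0.80, 0.50, False),   # coverage bound strict: exactly 50% fails
            (0.80, 0.51, True),
            (1.0, 1.0, True),
            (0.0, 0.0, False),
        ],
    )
    def test_threshold_semantics(self, identity, coverage, expected):
        assert is_homologue(self._result(identity, coverage)) is expected

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(
        identity=st.floats(0, 1), coverage=st.floats(0, 1),
        id_thr=st.floats(0, 1), cov_thr=st.floats(0, 1),
        bump=st.floats(0, 0.5),
    )
    def test_raising_thresholds_is_monotone(self, identity, coverage, id_thr, cov_thr, bump):
        """Raising either threshold never turns a non-homologue into a homologue."""
        res = self._result(identity, coverage)
        lo = AlignmentParams(identity_threshold=id_thr, coverage_threshold=cov_thr)
        hi_id = AlignmentParams(
            identity_threshold=min(1.0, id_thr + bump), coverage_threshold=cov_thr
        )
        hi_cov = AlignmentParams(
            identity_threshold=id_thr, coverage_threshold=min(1.0, cov_thr + bump)
        )
        if not is_homologue(res, lo):
            assert not is_homologue(res, hi_id)
            assert not is_homologue(res, hi_cov)


class TestParams:
    def test_defaults_match_published_configuration(self):
        p = AlignmentParams()
        assert p.matrix_name == "BLOSUM62"
        assert p.open_gap_score == -20
        assert p.extend_gap_score == -5
        assert p.identity_threshold == 0.40
        assert p.coverage_threshold == 0.50

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"open_gap_score": -5, "extend_gap_score": -20},  # open milder than extend
            {"extend_gap_score": 1.0},
            {"identity_threshold": 1.2},
            {"coverage_threshold": -0.1},
        ],
    )
    def test_invalid_params_rejected(self, kwargs):
        with pytest.raises(ValueError):
            AlignmentParams(**kwargs)
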