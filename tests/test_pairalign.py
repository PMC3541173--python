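"""Local alignment, the 60/50 rescue rule, MSA, and distance computations."""
import math

import numpy as np
import pytest
from Bio.Align import substitution_matrices

from oracles import local_align_enumerate
from plantsdr.errors import InvalidInputError, SaturationError
from plantsdr.pairalign import (
    DistanceMatrix,
    MultipleAlignment,
    PairwiseAlignment,
    evalue,
    local_align,
    p_distance,
    poisson_correct,
    poisson_matrix,
    progressive_msa,
    segment_identity_pass,
)

B62 = substitution_matrices.load("BLOSUM62")
AAS = "ACDEFGHIKLMNPQRSTVWY"


class TestLocalAlign:
    def test_self_alignment_scores_sum_of_diagonal(self):
        a = "HEAGAWGHEE"
        aln = local_align(a, a)
        assert aln.identity == 1.0
        assert aln.aligned_length == 10
        assert aln.score == pytest.approx(sum(B62[c, c] for c in a))

    def test_matches_exhaustive_enumeration(self, rng):
        sub = lambda x, y: float(B62[x, y])
        for _ in range(120):
            a = "".join(AAS[k] for k in rng.integers(0, 20, size=rng.integers(1, 9)))
            b = "".join(AAS[k] for k in rng.integers(0, 20, size=rng.integers(1, 9)))
            assert local_align(a, b).score == pytest.approx(
                local_align_enumerate(a, b, sub), abs=1e-9
            )

    def test_all_negative_scores_give_empty_alignment(self):
        aln = local_align("AAAA", "TTTT" .replace("T", "W"))
        # A vs W scores -3 under BLOSUM62: no positive segment exists
        assert aln.score == 0.0
        assert aln.aligned_length == 0

    def test_empty_input_rejected(self):
        with pytest.raises(InvalidInputError):
            local_align("", "ACD")

    def test_degapped_rows_are_substrings(self, rng):
        for _ in range(20):
            a = "".join(AAS[k] for k in rng.integers(0, 20, size=30))
            b = "".join(AAS[k] for k in rng.integers(0, 20, size=30))
            aln = local_align(a, b)
            assert aln.aligned_a.replace("-", "") in a
            assert aln.aligned_b.replace("-", "") in b


def _aln(matches: int, total: int) -> PairwiseAlignment:
    """Alignment of `total` columns with exactly `matches` identities."""
    a = "A" * matches + "C" * (total - matches)
    b = "A" * matches + "D" * (total - matches)
    return PairwiseAlignment(a, b, 0.0, matches / total, total)


class TestSegmentIdentityPass:
    def test_long_perfect_alignment_passes(self):
        assert segment_identity_pass(_aln(80, 80))

    def test_alignment_shorter_than_window_fails(self):
        assert not segment_identity_pass(_aln(50, 50))
        assert not segment_identity_pass(_aln(59, 59))

    def test_strictly_more_than_half_boundary(self):
        assert not segment_identity_pass(_aln(30, 60))  # exactly 50%: fails
        assert segment_identity_pass(_aln(31, 60))

    def test_dual_gap_columns_disqualify_a_window(self):
        a = "A" * 30 + "-" + "A" * 30
        b = "A" * 30 + "-" + "A" * 30
        aln = PairwiseAlignment(a, b, 0.0, 1.0, 61)
        # every 60-column window spans the dual-gap column
        assert not segment_identity_pass(aln, window=60)

    def test_monotone_in_identities(self, rng):
        # upgrading a mismatch to a match never flips pass -> fail
        for _ in range(30):
            total = int(rng.integers(60, 100))
            matches = int(rng.integers(0, total))
            before = segment_identity_pass(_aln(matches, total))
            after = segment_identity_pass(_aln(min(matches + 5, total), total))
            assert after or not before


class TestProgressiveMsa:
    def test_identical_sequences_align_gap_free(self):
        msa = progressive_msa(["ACDEFGHIK"] * 3)
        assert msa.rows == ["ACDEFGHIK"] * 3

    def test_single_gap_insertion(self):
        msa = progressive_msa(["ACDE", "ACE", "ACDE"])
        assert [r.replace("-", "") for r in msa.rows] == ["ACDE", "ACE", "ACDE"]
        assert msa.rows[0] == "ACDE"
        assert len(msa.rows[1]) == 4 and msa.rows[1].count("-") == 1

    def test_degap_recovers_inputs(self, rng):
        seqs = [
            "".join(AAS[k] for k in rng.integers(0, 20, size=rng.integers(20, 40)))
            for _ in range(5)
        ]
        msa = progressive_msa(seqs)
        assert [r.replace("-", "") for r in msa.rows] == seqs

    def test_input_order_only_changes_row_order(self):
        rng = np.random.default_rng(3)
        base = "".join(AAS[k] for k in rng.integers(0, 20, size=40))
        seqs = {
            "a": base,
            "b": base[:20] + "WWWW" + base[20:],
            "c": "".join(AAS[k] for k in rng.integers(0, 20, size=40)),
        }
        ids = list(seqs)
        ref = progressive_msa([seqs[i] for i in ids], ids)
        by_id_ref = dict(zip(ref.ids, ref.rows))
        for perm in (["b", "a", "c"], ["c", "b", "a"]):
            out = progressive_msa([seqs[i] for i in perm], perm)
            assert dict(zip(out.ids, out.rows)) == by_id_ref

    def test_fewer_than_two_sequences_rejected(self):
        with pytest.raises(InvalidInputError):
            progressive_msa(["ACDE"])


class TestDistances:
    def test_p_distance_simple_mismatch_fraction(self):
        msa = MultipleAlignment(["a", "b"], ["AAAA", "AAAT"])
        assert p_distance(msa).values[0, 1] == pytest.approx(0.25)

    def test_pairwise_deletion_ignores_gapped_columns(self):
        msa = MultipleAlignment(["a", "b"], ["A-CD", "ABCD"])
        assert p_distance(msa).values[0, 1] == 0.0

    def test_no_comparable_columns_is_undefined(self):
        msa = MultipleAlignment(["a", "b"], ["A---", "-CCC"])
        dm = p_distance(msa)
        assert math.isnan(dm.values[0, 1])
        assert dm.undefined_pairs() == [("a", "b")]

    def test_symmetry_and_zero_diagonal(self, rng):
        seqs = [
            "".join(AAS[k] for k in rng.integers(0, 20, size=30)) for _ in range(4)
        ]
        dm = p_distance(progressive_msa(seqs))
        np.testing.assert_array_equal(dm.values, dm.values.T)
        assert np.all(np.diag(dm.values) == 0)

    def test_poisson_correction_values(self):
        assert poisson_correct(0.0) == 0.0
        assert poisson_correct(0.25) == pytest.approx(-math.log(0.75))
        with pytest.raises(SaturationError):
            poisson_correct(1.0)

    def test_poisson_dominates_p(self, rng):
        for p in rng.uniform(0.0, 0.99, size=50):
            assert poisson_correct(float(p)) >= p

    def test_poisson_matrix_propagates_nan(self):
        dm = DistanceMatrix(["a", "b"], np.array([[0.0, float("nan")],
                                                  [float("nan"), 0.0]]),
                            "p_distance")
        out = poisson_matrix(dm)
        assert out.kind == "poisson"
        assert math.isnan(out.values[0, 1])

    def test_distance_matrix_tsv_roundtrip(self, tmp_path):
        vals = np.array([[0.0, 0.25, float("nan")],
                         [0.25, 0.0, 0.5],
                         [float("nan"), 0.5, 0.0]])
        dm = DistanceMatrix(["a", "b", "c"], vals, "p_distance")
        path = tmp_path / "d.tsv"
        dm.to_tsv(path)
        back = DistanceMatrix.from_tsv(path, "p_distance")
        assert back.ids == dm.ids
        np.testing.assert_allclose(back.values, dm.values)


class TestEvalue:
    def test_zero_score_closed_form(self):
        assert evalue(0.0, 100, 200, K=0.1, lam=0.3) == pytest.approx(0.1 * 100 * 200)

    def test_linear_in_database_length(self):
        assert evalue(50, 100, 400) == pytest.approx(2 * evalue(50, 100, 200))

    def test_karlin_altschul_closed_form(self):
        got = evalue(350, 250, 250, K=0.041, lam=0.267)
        assert got == pytest.approx(0.041 * 250 * 250 * math.exp(-0.267 * 350))

    def test_monotone_decreasing_in_score(self):
        assert evalue(100, 250, 250) > evalue(101, 250, 250)

    def test_invalid_parameters_rejected(self):
        with pytest.raises(InvalidInputError):
            evalue(10, 250, 250, K=0.0)
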