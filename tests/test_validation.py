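"""Structural (Kabsch, TM-score) and sequence (Smith-Waterman) validation."""

import numpy as np
import pytest
from Bio import Align
from Bio.Align import substitution_matrices
from scipy.optimize import minimize
from scipy.spatial.transform import Rotation

from koassign.records import CATrace
from koassign.validation import (
    AlignmentResult,
    TMScoreInput,
    d0_scale,
    identity_distribution,
    kabsch_superpose,
    smith_waterman,
    tm_score,
)
from koassign.validation import _score_from_distances

AA = "ACDEFGHIKLMNPQRSTVWY"


def random_trace(rng, n):
    steps = rng.standard_normal((n - 1, 3))
    steps = 3.8 * steps / np.linalg.norm(steps, axis=1, keepdims=True)
    return np.vstack([np.zeros(3), np.cumsum(steps, axis=0)])


class TestKabsch:
    def test_identical_sets_give_identity_transform(self):
        rng = np.random.default_rng(0)
        P = rng.standard_normal((10, 3))
        R, t, rmsd = kabsch_superpose(P, P)
        assert np.allclose(R, np.eye(3), atol=1e-9)
        assert np.allclose(t, 0.0, atol=1e-9)
        assert rmsd == pytest.approx(0.0, abs=1e-9)

    def test_recovers_exact_rigid_motion(self):
        rng = np.random.default_rng(1)
        P = rng.standard_normal((20, 3))
        R0 = Rotation.from_rotvec([0.0, 0.0, np.pi / 2]).as_matrix()
        t0 = np.array([1.0, 2.0, 3.0])
        Q = P @ R0.T + t0
        R, t, rmsd = kabsch_superpose(P, Q)
        assert rmsd == pytest.approx(0.0, abs=1e-9)
        assert np.allclose(R, R0, atol=1e-9)
        assert np.allclose(t, t0, atol=1e-9)
        assert np.linalg.det(R) == pytest.approx(1.0)

    def test_rmsd_matches_numerical_optimizer_over_rotations(self):
        rng = np.random.default_rng(2)
        P = rng.standard_normal((50, 3))
        Q = rng.standard_normal((50, 3))
        _, _, rmsd = kabsch_superpose(P, Q)

        Pc = P - P.mean(axis=0)
        Qc = Q - Q.mean(axis=0)

        def objective(rotvec):
            M = Rotation.from_rotvec(rotvec).as_matrix()
            return np.sqrt(np.mean(np.sum((Pc @ M.T - Qc) ** 2, axis=1)))

        best = min(
            minimize(objective, x0, method="Nelder-Mead",
                     options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 5000}).fun
            for x0 in rng.standard_normal((8, 3))
        )
        assert rmsd == pytest.approx(best, abs=1e-6)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            kabsch_superpose(np.zeros((2, 3)), np.zeros((2, 3)))


class TestD0:
    def test_printed_formula_at_100(self):
        assert d0_scale(100) == pytest.approx(1.24 * 85 ** (1 / 3) - 1.8, abs=1e-3)
        assert d0_scale(100) == pytest.approx(3.652, abs=1e-3)

    def test_floor_for_short_targets(self):
        assert d0_scale(15) == 0.5
        assert d0_scale(1) == 0.5
        # formula is negative just above 15, must still floor
        assert d0_scale(20) == 0.5

    def test_monotone_non_decreasing_sweep(self):
        values = [d0_scale(n) for n in range(16, 1001)]
        assert all(a <= b for a, b in zip(values, values[1:]))

    def test_non_positive_length_rejected(self):
        with pytest.raises(ValueError):
            d0_scale(0)


class TestTMScore:
    def test_identical_traces_score_exactly_one(self):
        rng = np.random.default_rng(3)
        trace = CATrace("t", random_trace(rng, 50))
        inputs = TMScoreInput(trace, trace, tuple((i, i) for i in range(50)))
        assert tm_score(inputs) == 1.0

    def test_invariant_under_common_rigid_motion(self):
        rng = np.random.default_rng(4)
        target = random_trace(rng, 40)
        template = target + rng.standard_normal(target.shape) * 1.5
        pairs = tuple((i, i) for i in range(40))
        base = tm_score(TMScoreInput(CATrace("a", target), CATrace("b", template),
                                     pairs))
        R = Rotation.from_rotvec(rng.standard_normal(3)).as_matrix()
        t = rng.standard_normal(3) * 20
        moved = tm_score(TMScoreInput(
            CATrace("a", target @ R.T + t), CATrace("b", template @ R.T + t), pairs
        ))
        assert moved == pytest.approx(base, abs=1e-9)

    def test_single_pair_at_d0_gives_half_term(self):
        l_target = 20
        target = CATrace("t", np.arange(60, dtype=float).reshape(l_target, 3))
        template = CATrace(
            "p", target.coords[:1] + np.array([d0_scale(l_target), 0.0, 0.0])
        )
        score = tm_score(TMScoreInput(target, template, ((0, 0),)))
        assert score == pytest.approx(0.5 / l_target)

    def test_strictly_decreasing_in_any_single_distance(self):
        d = np.array([0.5, 1.0, 2.0, 4.0])
        base = _score_from_distances(d, 10, d0_scale(10))
        for i in range(len(d)):
            bumped = d.copy()
            bumped[i] += 0.25
            assert _score_from_distances(bumped, 10, d0_scale(10)) < base

    def test_partial_correspondence_bounded_by_coverage(self):
        rng = np.random.default_rng(5)
        trace = CATrace("t", random_trace(rng, 60))
        pairs = tuple((i, i) for i in range(0, 60, 2))  # half the residues
        score = tm_score(TMScoreInput(trace, trace, pairs))
        assert score == pytest.approx(30 / 60)

    def test_refinement_recovers_score_with_outlier_pairs(self):
        """A few displaced pairs must not drag down the superposition of the
        well-matching core."""
        rng = np.random.default_rng(6)
        target = random_trace(rng, 80)
        template = target.copy()
        template[:4] += 30.0  # gross outliers
        pairs = tuple((i, i) for i in range(80))
        score = tm_score(TMScoreInput(CATrace("a", target),
                                      CATrace("b", template), pairs))
        assert score > 0.9  # 76/80 residues align perfectly after refinement

    def test_validates_correspondence(self):
        trace = CATrace("t", np.zeros((5, 3)) + np.arange(5)[:, None])
        with pytest.raises(ValueError):
            TMScoreInput(trace, trace, ())
        with pytest.raises(ValueError):
            TMScoreInput(trace, trace, ((3, 0), (1, 1)))
        with pytest.raises(ValueError):
            TMScoreInput(trace, trace, ((0, 7),))


class TestSmithWaterman:
    def test_identical_sequences_full_identity(self):
        result = smith_waterman("MKVLWAADYQ", "MKVLWAADYQ")
        assert result.identity_percent == 100.0
        assert result.aligned_query == "MKVLWAADYQ"

    def test_unrelated_sequences_empty_alignment(self):
        result = smith_waterman("MKV", "AAA")
        assert result.score == 0.0
        assert result.identity_percent == 0.0
        assert result.aligned_query == ""

    def test_score_matches_biopython_oracle(self):
        aligner = Align.PairwiseAligner(mode="local")
        aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
        aligner.open_gap_score = -10.0
        aligner.extend_gap_score = -0.5
        rng = np.random.default_rng(7)
        for _ in range(50):
            a = "".join(rng.choice(list(AA), size=30))
            b = "".join(rng.choice(list(AA), size=30))
            assert smith_waterman(a, b).score == pytest.approx(
                aligner.score(a, b)
            )

    def test_symmetric_score_under_argument_swap(self):
        rng = np.random.default_rng(8)
        for _ in range(10):
            a = "".join(rng.choice(list(AA), size=25))
            b = "".join(rng.choice(list(AA), size=25))
            assert smith_waterman(a, b).score == smith_waterman(b, a).score

    def test_gap_columns_count_in_default_denominator(self):
        # One residue deleted from the middle forces a gap column.
        query = "MKVLWAADYQGHILKM"
        ref = query[:8] + query[9:]
        result = smith_waterman(query, ref)
        assert "-" in result.aligned_ref
        columns = len(result.aligned_query)
        identical = sum(
            a == b and a != "-"
            for a, b in zip(result.aligned_query, result.aligned_ref)
        )
        assert result.identity_percent == pytest.approx(100 * identical / columns)
        assert result.identity_percent < 100.0
        aligned_only = smith_waterman(query, ref,
                                      identity_denominator="aligned_columns")
        assert aligned_only.identity_percent == 100.0

    def test_invalid_letters_rejected(self):
        with pytest.raises(ValueError):
            smith_waterman("MKX", "MKV")


class TestIdentityDistribution:
    def test_all_top_bin(self):
        table = identity_distribution({f"g{i}": 100.0 for i in range(5)})
        top = table[(table.bin_lo == 90)]
        assert top["count"].iloc[0] == 5
        assert table["count"].sum() == 5

    def test_half_open_bins_except_final(self):
        table = identity_distribution({"a": 10.0, "b": 9.999, "c": 90.0, "d": 100.0})
        counts = {(lo, hi): c for lo, hi, c in
                  zip(table.bin_lo, table.bin_hi, table["count"])}
        assert counts[(0, 10)] == 1  # 9.999
        assert counts[(10, 20)] == 1  # 10.0 belongs to [10, 20)
        assert counts[(90, 100)] == 2  # 90 and 100 inclusive

    def test_uniform_fixture_roughly_flat(self):
        rng = np.random.default_rng(9)
        table = identity_distribution(
            {f"g{i}": float(v) for i, v in enumerate(rng.uniform(0, 100, 2000))}
        )
        assert table["count"].sum() == 2000
        assert table["count"].min() > 140 and table["count"].max() < 260

    def test_missing_outcome_ids_error(self):
        with pytest.raises(ValueError, match="g1"):
            identity_distribution({"g1": 50.0}, outcomes={})

    def test_grouped_by_category(self):
        table = identity_distribution(
            {"a": 95.0, "b": 15.0}, outcomes={"a": "match", "b": "unmatch"}
        )
        assert set(table.category) == {"match", "unmatch"}


def test_alignment_result_validates_equal_lengths():
    with pytest.raises(ValueError):
        AlignmentResult("AB-", "AB", 1.0, 50.0)
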