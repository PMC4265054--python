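"""First-SVD-mode signature extraction, scoring and removal."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from _oracles import first_triplet_power_iteration
from popshift.io import ExpressionMatrix
from popshift.signature import (
    correlate_with_signature,
    extract_signature,
    remove_first_mode,
    remove_signature_from_profile,
    robust_strain_filter,
    similarity_scores,
    variance_explained,
)


def _matrix(vals, prefix="g"):
    vals = np.asarray(vals, dtype=float)
    return ExpressionMatrix(
        [f"{prefix}{i}" for i in range(vals.shape[0])],
        [f"s{j}" for j in range(vals.shape[1])],
        vals,
    )


def _align_sign(a, b):
    return a if a @ b >= 0 else -a


class TestExtraction:
    def test_exact_rank_one(self):
        rng = np.random.default_rng(0)
        u = rng.normal(size=20)
        u /= np.linalg.norm(u)
        v = rng.normal(size=8)
        v /= np.linalg.norm(v)
        model = extract_signature(_matrix(5.0 * np.outer(u, v)))
        assert model.s1 == pytest.approx(5.0, abs=1e-10)
        assert variance_explained(model) == pytest.approx(1.0, abs=1e-12)
        cos = abs(model.u1 @ u)
        assert cos == pytest.approx(1.0, abs=1e-10)
        # signature profile collinear with u1
        prof = model.signature_profile
        assert abs(abs(prof @ model.u1) - np.linalg.norm(prof)) < 1e-10

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_power_iteration_oracle(self, seed):
        rng = np.random.default_rng(seed)
        shape = rng.integers(2, 11, size=2)
        M = rng.integers(-5, 6, size=shape).astype(float)
        if not M.any():
            M[0, 0] = 1.0
        model = extract_signature(_matrix(M))
        u_o, s_o, v_o = first_triplet_power_iteration(M)
        assert model.s1 == pytest.approx(s_o, abs=1e-8)
        np.testing.assert_allclose(
            model.u1, _align_sign(u_o, model.u1), atol=1e-8
        )
        np.testing.assert_allclose(
            model.v1, _align_sign(v_o, model.v1), atol=1e-8
        )

    def test_two_equal_singular_values_split_variance(self):
        M = np.diag([3.0, 3.0, 0.0])
        model = extract_signature(_matrix(M))
        assert variance_explained(model) == pytest.approx(0.5, abs=1e-12)

    def test_sign_rule_largest_gene_loading_positive(self):
        rng = np.random.default_rng(9)
        M = rng.normal(size=(15, 6))
        model = extract_signature(_matrix(M))
        assert model.u1[np.argmax(np.abs(model.u1))] > 0

    def test_scale_equivariance(self):
        rng = np.random.default_rng(4)
        M = rng.normal(size=(12, 5))
        a = extract_signature(_matrix(M))
        b = extract_signature(_matrix(-2.5 * M))
        assert b.s1 == pytest.approx(2.5 * a.s1, rel=1e-12)
        np.testing.assert_allclose(np.abs(b.u1), np.abs(a.u1), atol=1e-10)
        assert b.variance_fraction == pytest.approx(a.variance_fraction, abs=1e-12)

    def test_incomplete_or_zero_matrix_rejected(self):
        vals = np.array([[1.0, np.nan], [0.0, 2.0]])
        with pytest.raises(ValueError, match="impute"):
            extract_signature(_matrix(vals))
        with pytest.raises(ValueError, match="signature"):
            extract_signature(_matrix(np.zeros((3, 3))))


class TestScoring:
    def test_projection_of_u1_is_unit(self):
        rng = np.random.default_rng(2)
        M = rng.normal(size=(30, 6))
        model = extract_signature(_matrix(M))
        probe = _matrix(np.column_stack([model.u1, np.zeros(30)]))
        scores = similarity_scores(probe, model)
        assert scores[0] == pytest.approx(1.0, abs=1e-10)
        assert scores[1] == pytest.approx(0.0, abs=1e-12)

    def test_correlation_endpoints(self):
        rng = np.random.default_rng(3)
        M = rng.normal(size=(25, 5))
        model = extract_signature(_matrix(M))
        probe = _matrix(
            np.column_stack([model.signature_profile, -model.signature_profile])
        )
        r = correlate_with_signature(probe, model)
        assert r[0] == pytest.approx(1.0, abs=1e-10)
        assert r[1] == pytest.approx(-1.0, abs=1e-10)

    def test_independent_column_uncorrelated(self):
        rng = np.random.default_rng(11)
        M = rng.normal(size=(1000, 5))
        model = extract_signature(_matrix(M))
        probe = _matrix(rng.normal(size=(1000, 1)))
        r = correlate_with_signature(probe, model)
        assert abs(r[0]) < 0.1

    def test_gene_matching_is_by_id_not_position(self):
        rng = np.random.default_rng(13)
        M = rng.normal(size=(40, 6))
        m = _matrix(M)
        model = extract_signature(m)
        perm = rng.permutation(40)
        shuffled = ExpressionMatrix(
            [m.gene_ids[i] for i in perm], ["q"], M[perm, 0][:, None]
        )
        scores = similarity_scores(shuffled, model)
        assert scores[0] == pytest.approx(M[:, 0] @ model.u1, abs=1e-10)

    def test_zero_overlap_rejected(self):
        rng = np.random.default_rng(1)
        model = extract_signature(_matrix(rng.normal(size=(10, 4))))
        foreign = _matrix(rng.normal(size=(5, 1)), prefix="x")
        with pytest.raises(ValueError, match="shared"):
            similarity_scores(foreign, model)


class TestRemoval:
    @pytest.mark.parametrize("seed", range(5))
    def test_reconstruction_and_orthogonality(self, seed):
        rng = np.random.default_rng(seed)
        m_rows = int(rng.integers(3, 101))
        n_cols = int(rng.integers(2, 31))
        M = rng.normal(size=(m_rows, n_cols))
        mat = _matrix(M)
        model = extract_signature(mat)
        star = remove_first_mode(mat, model)
        rank1 = model.s1 * np.outer(model.u1, model.v1)
        np.testing.assert_allclose(star.values + rank1, M, atol=1e-10)
        assert np.max(np.abs(model.u1 @ star.values)) < 1e-8

    def test_rank_one_matrix_removed_to_zero(self):
        rng = np.random.default_rng(7)
        u = rng.normal(size=10)
        v = rng.normal(size=4)
        mat = _matrix(np.outer(u, v))
        star = remove_first_mode(mat, extract_signature(mat))
        assert np.max(np.abs(star.values)) < 1e-10

    def test_second_mode_survives_exactly(self):
        q, _ = np.linalg.qr(np.random.default_rng(8).normal(size=(12, 2)))
        p, _ = np.linalg.qr(np.random.default_rng(9).normal(size=(6, 2)))
        M = 7.0 * np.outer(q[:, 0], p[:, 0]) + 3.0 * np.outer(q[:, 1], p[:, 1])
        mat = _matrix(M)
        star = remove_first_mode(mat, extract_signature(mat))
        np.testing.assert_allclose(
            star.values, 3.0 * np.outer(q[:, 1], p[:, 1]), atol=1e-10
        )

    def test_residual_top_singular_value_is_second_of_original(self):
        rng = np.random.default_rng(10)
        M = rng.normal(size=(100, 30))
        mat = _matrix(M)
        star = remove_first_mode(mat, extract_signature(mat))
        s_orig = np.linalg.svd(M, compute_uv=False)
        s_star = np.linalg.svd(star.values, compute_uv=False)
        assert s_star[0] == pytest.approx(s_orig[1], abs=1e-8)

    def test_profile_gram_schmidt_reconstruction(self):
        rng = np.random.default_rng(21)
        M = rng.normal(size=(50, 8))
        mat = _matrix(M)
        model = extract_signature(mat)
        profile = rng.normal(size=50)
        out, shared = remove_signature_from_profile(profile, mat.gene_ids, model)
        assert shared.all()
        u = model.u1
        assert abs(out @ u) < 1e-8
        np.testing.assert_allclose(out + (profile @ u) * u, profile, atol=1e-10)

    def test_profile_collinear_with_u1_zeroed(self):
        rng = np.random.default_rng(22)
        mat = _matrix(rng.normal(size=(30, 5)))
        model = extract_signature(mat)
        out, _ = remove_signature_from_profile(3.2 * model.u1, mat.gene_ids, model)
        assert np.max(np.abs(out)) < 1e-10

    def test_unmatched_genes_pass_through(self):
        rng = np.random.default_rng(23)
        mat = _matrix(rng.normal(size=(30, 5)))
        model = extract_signature(mat)
        ids = mat.gene_ids[:10] + ["alien1", "alien2"]
        profile = rng.normal(size=12)
        out, shared = remove_signature_from_profile(profile, ids, model)
        assert shared.sum() == 10
        np.testing.assert_array_equal(out[10:], profile[10:])
        u_sub = model.u1[:10]
        u_hat = u_sub / np.linalg.norm(u_sub)
        assert abs(out[:10] @ u_hat) < 1e-8


class TestRobustStrainFilter:
    def _with_pvalues(self, n_hits_per_sample):
        """One sample per entry, with the stated number of qualifying genes."""
        n_genes = 10
        vals = np.zeros((n_genes, len(n_hits_per_sample)))
        pvals = np.ones_like(vals)
        for j, h in enumerate(n_hits_per_sample):
            vals[:h, j] = 1.0  # |M| = 1 > log2(1.7)
            pvals[:h, j] = 0.01
        return ExpressionMatrix(
            [f"g{i}" for i in range(n_genes)],
            [f"s{j}" for j in range(len(n_hits_per_sample))],
            vals,
            pvalues=pvals,
        )

    def test_more_than_three_transcripts_is_strict(self):
        m = self._with_pvalues([4, 3, 0])
        assert robust_strain_filter(m) == ["s0"]

    def test_fold_change_threshold_is_strict(self):
        vals = np.full((5, 1), np.log2(1.7))
        m = ExpressionMatrix(
            [f"g{i}" for i in range(5)], ["s0"], vals,
            pvalues=np.full((5, 1), 0.01),
        )
        assert robust_strain_filter(m) == []

    def test_requires_pvalues(self, small_matrix):
        with pytest.raises(ValueError, match="p-value"):
            robust_strain_filter(small_matrix)


@settings(deadline=None, max_examples=25, derandomize=True)
@given(st.integers(0, 2**31 - 1))
def test_first_mode_removal_reconstructs_any_matrix(seed):
    """M(1) + M* = M and orthogonality hold for arbitrary random matrices."""
    rng = np.random.default_rng(seed)
    M = rng.normal(size=(int(rng.integers(3, 20)), int(rng.integers(2, 10))))
    mat = _matrix(M)
    model = extract_signature(mat)
    star = remove_first_mode(mat, model)
    np.testing.assert_allclose(
        star.values + model.s1 * np.outer(model.u1, model.v1), M, atol=1e-10
    )
    assert np.max(np.abs(model.u1 @ star.values)) < 1e-8


def test_planted_signature_recovery(compendium_seed1):
    """Default synthetic compendium: u1 recovers the planted signature and
    projection scores track the planted growth rates."""
    matrix, truth = compendium_seed1
    model = extract_signature(matrix)
    sigma = truth.planted_signature
    cos = abs(model.u1 @ sigma) / np.linalg.norm(sigma)
    assert cos >= 0.95
    scores = similarity_scores(matrix, model)
    r = np.corrcoef(scores, truth.planted_growth_rates)[0, 1]
    assert abs(r) >= 0.9
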