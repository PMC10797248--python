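"""PCA/ICA decomposition: oracles, conventions, determinism, alignment."""

import numpy as np
import pytest

from gwasdecomp import (
    GenomicICA,
    GenomicPCA,
    align_components,
    ica_decompose,
    load_result,
    pca_decompose,
    scree_table,
)
from gwasdecomp.exceptions import RegistryMismatchError, ValidationError
from oracles import best_assignment_total_abs_r


def random_effects(seed, m=20, n=50):
    rng = np.random.default_rng(seed)
    return GenomicPCA.from_array(rng.standard_normal((m, n))).effects


def planted_effects(seed, m=40, n=2000, k=3, pi=0.05, noise=0.0):
    """X = A S with sparse Laplacian-like (spike-and-slab) sources."""
    rng = np.random.default_rng(seed)
    S = np.where(rng.random((k, n)) < pi, rng.laplace(0, 1, (k, n)), 0.0)
    A = rng.normal(0, 1, (m, k))
    X = A @ S + noise * rng.standard_normal((m, n))
    return X, S, A


class TestPCA:
    def test_rank_one_matrix_single_component(self):
        u = np.arange(1, 7, dtype=float)
        v = np.linspace(-1, 1, 30)
        model = GenomicPCA.from_array(np.outer(u, v))
        res = model.fit(1)
        assert res.variance_explained[0] == pytest.approx(1.0, abs=1e-12)

    def test_full_rank_reconstruction(self):
        em = random_effects(0)
        res = pca_decompose(em, min(em.shape))
        rel = np.linalg.norm(res.reconstruct() - em.values) / np.linalg.norm(em.values)
        assert rel < 1e-8

    def test_variance_explained_matches_svd_oracle(self):
        em = random_effects(1)
        res = pca_decompose(em, 5)
        s = np.linalg.svd(em.values, compute_uv=False)
        np.testing.assert_allclose(res.variance_explained, s[:5] ** 2 / np.sum(s**2), atol=1e-10)

    def test_rows_orthogonal(self):
        res = pca_decompose(random_effects(2), 4)
        G = res.snp_loadings @ res.snp_loadings.T
        np.testing.assert_allclose(G, np.eye(4), atol=1e-10)

    def test_k_out_of_range(self):
        with pytest.raises(ValidationError):
            pca_decompose(random_effects(3), 21)


class TestScree:
    def test_equal_spectrum(self):
        # orthogonal design: all singular values equal
        X = np.eye(100)[:100]
        res = GenomicPCA.from_array(X).fit(5)
        out = scree_table(res, [5])
        assert out["cumulative_variance"].iloc[0] == pytest.approx(0.05, abs=1e-10)

    def test_completeness_and_oracle(self):
        em = random_effects(4)
        res = pca_decompose(em, 3)
        s = np.linalg.svd(em.values, compute_uv=False)
        out = scree_table(res, [1, 2, 3, min(em.shape)])
        want = np.cumsum(s**2) / np.sum(s**2)
        np.testing.assert_allclose(
            out["cumulative_variance"], [want[0], want[1], want[2], 1.0], atol=1e-10
        )
        assert out["cumulative_variance"].is_monotonic_increasing

    def test_dim_beyond_spectrum_rejected(self):
        res = pca_decompose(random_effects(5), 2)
        with pytest.raises(ValidationError):
            scree_table(res, [500])


class TestICA:
    def test_recovers_planted_laplacian_sources(self):
        X, S, _ = planted_effects(7)
        res = GenomicICA.from_array(X).fit(3, seed=0)
        C = np.abs(np.corrcoef(np.vstack([res.snp_loadings, S]))[:3, 3:])
        # best match per true factor, up to sign/permutation
        assert (C.max(axis=0) > 0.999).all()

    def test_gaussian_input_well_formed(self):
        """Gaussian sources are not identifiable, but output must be clean
        and variance_explained must still equal the PCA values."""
        em = random_effects(8, m=15, n=300)
        try:
            res = ica_decompose(em, 2, seed=0)
        except Exception as e:
            from gwasdecomp.exceptions import ConvergenceError

            assert isinstance(e, ConvergenceError)
            return
        assert np.all(np.isfinite(res.snp_loadings))
        pca = pca_decompose(em, 2)
        np.testing.assert_allclose(res.variance_explained, pca.variance_explained, atol=1e-12)

    def test_column_permutation_equivariance(self):
        X, _, _ = planted_effects(9, m=25, n=500)
        perm = np.random.default_rng(1).permutation(500)
        res = GenomicICA.from_array(X).fit(3, seed=4)
        res_p = GenomicICA.from_array(X[:, perm]).fit(3, seed=4)
        np.testing.assert_allclose(res_p.snp_loadings, res.snp_loadings[:, perm], atol=1e-8)
        np.testing.assert_allclose(res_p.trait_loadings, res.trait_loadings, atol=1e-8)

    def test_k1_rejected(self):
        with pytest.raises(ValidationError):
            ica_decompose(random_effects(10), 1)

    def test_seed_reproducibility_bitwise(self):
        X, _, _ = planted_effects(11)
        a = GenomicICA.from_array(X).fit(3, seed=123)
        b = GenomicICA.from_array(X).fit(3, seed=123)
        assert np.array_equal(a.snp_loadings, b.snp_loadings)
        assert np.array_equal(a.trait_loadings, b.trait_loadings)

    def test_cross_seed_stability(self):
        X, _, _ = planted_effects(12)
        a = GenomicICA.from_array(X).fit(3, seed=0)
        b = GenomicICA.from_array(X).fit(3, seed=99)
        pairs = align_components(a, b)
        assert (pairs["r"].abs() > 0.99).all()

    def test_unit_rms_rows_and_reconstruction(self):
        X, _, _ = planted_effects(13, noise=0.05)
        res = GenomicICA.from_array(X).fit(3, seed=0)
        rms = np.sqrt((res.snp_loadings**2).mean(axis=1))
        np.testing.assert_allclose(rms, 1.0, atol=1e-10)
        pca = pca_decompose(GenomicICA.from_array(X).effects, 3)
        rel = np.linalg.norm(res.reconstruct() - pca.reconstruct()) / np.linalg.norm(
            pca.reconstruct()
        )
        assert rel < 1e-6

    def test_matches_sklearn_fastica_subspace(self):
        """Independent cross-check: sklearn's FastICA (whiten off, applied to
        the same whitened sources) finds the same source family."""
        from sklearn.decomposition import FastICA

        X, S, _ = planted_effects(14, m=30, n=3000)
        res = GenomicICA.from_array(X).fit(3, seed=0)
        U, s, Vt = np.linalg.svd(X, full_matrices=False)
        Z = np.sqrt(3000) * Vt[:3]
        sk = FastICA(whiten=False, fun="logcosh", random_state=0, max_iter=1000)
        S_sk = sk.fit_transform(Z.T).T
        C = np.abs(np.corrcoef(np.vstack([res.snp_loadings, S_sk]))[:3, 3:])
        assert (C.max(axis=1) > 0.999).all()


class TestConventions:
    def test_skewness_positive_sign(self):
        X, _, _ = planted_effects(15)
        res = GenomicICA.from_array(X).fit(3, seed=0)
        from scipy.stats import skew

        assert (skew(res.snp_loadings, axis=1) > 0).all()

    def test_no_demeaning_column_offset_changes_result(self):
        """A constant added to one SNP column must propagate (global signal
        removal is off: effects are already null-centred)."""
        em = random_effects(16, m=10, n=40)
        base = pca_decompose(em, 3)
        shifted = em.values.copy()
        shifted[:, 0] += 5.0
        res = pca_decompose(GenomicPCA.from_array(shifted).effects, 3)
        assert not np.allclose(res.singular_spectrum, base.singular_spectrum)
        # opt-in column centering removes the offset again
        centered = GenomicPCA.from_array(shifted, center_columns=True).fit(3)
        base_centered = GenomicPCA.from_array(em.values, center_columns=True).fit(3)
        np.testing.assert_allclose(
            centered.singular_spectrum, base_centered.singular_spectrum, atol=1e-8
        )

    def test_no_variance_normalization_column_scale_matters(self):
        """Scaling one SNP column scales its loading influence (allelic
        effect magnitudes are biological signal, not nuisance)."""
        rng = np.random.default_rng(17)
        X = rng.standard_normal((10, 40))
        X2 = X.copy()
        X2[:, 5] *= 100.0
        res = pca_decompose(GenomicPCA.from_array(X2).effects, 1)
        # the blown-up column dominates the first right singular vector
        assert np.argmax(np.abs(res.snp_loadings[0])) == 5


class TestAlign:
    def test_permuted_and_flipped_self_alignment(self):
        X, _, _ = planted_effects(18)
        a = GenomicICA.from_array(X).fit(3, seed=0)
        b = GenomicICA.from_array(X).fit(3, seed=0)
        perm = [2, 0, 1]
        b.snp_loadings = b.snp_loadings[perm] * np.array([[-1], [1], [-1]])
        pairs = align_components(a, b)
        assert pairs["r"].abs().min() > 1 - 1e-12
        got = {(int(r.index_a), int(r.index_b)) for r in pairs.itertuples()}
        assert got == {(0, 1), (1, 2), (2, 0)}  # inverse of perm
        # b row1 = +a0, b row2 = -a1, b row0 = -a2
        assert list(pairs.sort_values("index_a")["sign"]) == [1, -1, -1]

    def test_single_component_pair(self):
        em = random_effects(19)
        a = pca_decompose(em, 1)
        b = pca_decompose(em, 1)
        pairs = align_components(a, b)
        assert len(pairs) == 1
        assert pairs["r"].iloc[0] == pytest.approx(1.0)

    @pytest.mark.parametrize("seed", range(5))
    def test_total_matches_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        a = GenomicPCA.from_array(rng.standard_normal((12, 80))).fit(4)
        b = GenomicPCA.from_array(rng.standard_normal((12, 80)), snp_ids=None).fit(4)
        b.snp_registry = a.snp_registry  # same registry, independent loadings
        pairs = align_components(a, b)
        total = pairs["r"].abs().sum()
        want = best_assignment_total_abs_r(a.snp_loadings, b.snp_loadings)
        assert total == pytest.approx(want, abs=1e-12)

    def test_registry_mismatch_rejected(self):
        a = pca_decompose(random_effects(20), 2)
        b = GenomicPCA.from_array(
            np.random.default_rng(0).standard_normal((20, 50)),
            snp_ids=[f"other{j}" for j in range(50)],
        ).fit(2)
        with pytest.raises(RegistryMismatchError):
            align_components(a, b)


def test_save_load_round_trip(tmp_path):
    X, _, _ = planted_effects(21, m=15, n=200)
    res = GenomicICA.from_array(X).fit(3, seed=5)
    res.save(tmp_path / "d")
    back = load_result(tmp_path / "d")
    np.testing.assert_array_equal(back.snp_loadings, res.snp_loadings)
    np.testing.assert_array_equal(back.trait_loadings, res.trait_loadings)
    assert back.config == res.config
    assert back.method == "ica" and back.k == 3
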