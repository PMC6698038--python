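"""Kinship, PCA, effective marker count and thresholds."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from trastools.io import GenotypeMatrix, SnpRecord
from trastools.popstruct import (compute_kinship, compute_pcs,
                                 effective_marker_count,
                                 significance_thresholds)
from trastools.simulate import SimulationConfig, simulate_cohort


def _gm(dosages, prefix="S"):
    n, m = dosages.shape
    snps = [SnpRecord(f"{prefix}{j}", f"T{j}", j + 1, "A", "G") for j in range(m)]
    return GenotypeMatrix([f"s{i}" for i in range(n)], snps,
                          np.asarray(dosages, float))


class TestKinship:
    def test_clones_are_maximally_related(self, rng):
        # identical genotype rows: relatedness equals self-relatedness
        # (up to the stabilizing ridge on the diagonal)
        row = rng.integers(0, 3, size=30).astype(float)
        G = _gm(np.vstack([row, row, rng.integers(0, 3, 30)]))
        K = compute_kinship(G).K
        assert K[0, 1] == pytest.approx(K[0, 0], abs=2e-6)
        assert K[0, 1] == pytest.approx(K[1, 1], abs=2e-6)

    def test_rows_of_centered_kinship_sum_to_zero(self, rng):
        # column-centering makes sample contributions sum out: each row of
        # the pre-ridge kinship sums to zero, so off-diagonals balance the
        # diagonal exactly
        X = rng.integers(0, 3, size=(6, 40)).astype(float)
        K = compute_kinship(_gm(X)).K
        K = K - np.eye(6) * 1e-6  # remove the ridge (rank-deficient case)
        np.testing.assert_allclose(K.sum(axis=1), 0, atol=1e-10)

    def test_matches_double_loop_oracle(self, rng):
        X = rng.integers(0, 3, size=(10, 50)).astype(float)
        G = _gm(X)
        K = compute_kinship(G, estimator="centered").K
        Z = X - X.mean(axis=0)
        p = X.mean(axis=0) / 2
        denom = np.sum(2 * p * (1 - p))
        brute = np.zeros((10, 10))
        for i in range(10):
            for k in range(10):
                brute[i, k] = sum(Z[i, j] * Z[k, j] for j in range(50)) / denom
        if np.linalg.eigvalsh(brute)[0] < 1e-8:
            brute = brute + 1e-6 * np.eye(10)
        assert np.max(np.abs(K - brute)) < 1e-10

    def test_psd_and_diagonal_scale(self, small_cohort):
        for est in ("centered", "standardized"):
            K = compute_kinship(small_cohort.genotypes, estimator=est).K
            assert np.linalg.eigvalsh(K)[0] >= -1e-8
            assert 0.5 <= np.mean(np.diag(K)) <= 2.0

    def test_invariant_to_marker_and_sample_order(self, rng):
        X = rng.integers(0, 3, size=(8, 40)).astype(float)
        G = _gm(X)
        K = compute_kinship(G).K
        perm_m = rng.permutation(40)
        K2 = compute_kinship(_gm(X[:, perm_m])).K
        np.testing.assert_allclose(K, K2, atol=1e-12)
        perm_s = rng.permutation(8)
        K3 = compute_kinship(_gm(X[perm_s])).K
        np.testing.assert_allclose(K[np.ix_(perm_s, perm_s)], K3, atol=1e-12)

    def test_standardized_rejects_constant_column(self):
        X = np.array([[0, 1.0], [0, 2], [0, 1], [0, 0]])
        with pytest.raises(ValueError, match="zero-variance"):
            compute_kinship(_gm(X), estimator="standardized")


class TestPCs:
    def test_separates_two_subpopulations(self):
        co = simulate_cohort(SimulationConfig(
            n_samples=60, n_snps=300, n_transcripts=20, n_subpops=2, fst=0.3,
            include_cascades=False, seed=3))
        W = compute_pcs(co.genotypes, n_pcs=2).W
        pc1 = W[:, 1]
        labels = np.array([co.truth.subpop[s] for s in co.genotypes.samples])
        a, b = pc1[labels == 0], pc1[labels == 1]
        assert max(a.min(), b.min()) > min(a.max(), b.max()) or \
            a.max() < b.min() or b.max() < a.min()

    def test_scores_orthogonal_and_full_rank(self, small_cohort):
        cs = compute_pcs(small_cohort.genotypes, n_pcs=4)
        scores = cs.W[:, 1:]
        gram = scores.T @ scores
        off = gram[~np.eye(4, dtype=bool)]
        assert np.max(np.abs(off)) <= 1e-8 * np.max(np.abs(gram))
        assert np.linalg.matrix_rank(cs.W) == 5

    def test_deterministic_sign_convention(self, rng):
        X = rng.integers(0, 3, size=(12, 30)).astype(float)
        W1 = compute_pcs(_gm(X), 3).W
        W2 = compute_pcs(_gm(X), 3).W
        np.testing.assert_array_equal(W1, W2)

    def test_too_many_pcs_rejected(self, rng):
        X = rng.integers(0, 3, size=(5, 10)).astype(float)
        with pytest.raises(ValueError):
            compute_pcs(_gm(X), n_pcs=5)


class TestEffectiveMarkerCount:
    def test_independent_markers_count_fully(self, rng):
        # orthogonal columns -> exact identity correlation -> M_eff = m
        n, m = 16, 8
        Q, _ = np.linalg.qr(rng.standard_normal((n, m)))
        Q -= Q.mean(axis=0)
        Q, _ = np.linalg.qr(Q)
        G = _gm(Q + 1.0)
        assert effective_marker_count(G) == pytest.approx(m, abs=1e-6)

    def test_duplicated_markers_collapse(self, rng):
        # k mutually uncorrelated markers duplicated -> each pair contributes
        # eigenvalues {2, 0} -> M_eff = k; built from orthogonal columns so
        # the pairwise sample correlations are exactly zero
        n, k = 20, 5
        Q, _ = np.linalg.qr(rng.standard_normal((n, k)))
        Q -= Q.mean(axis=0)
        Q, _ = np.linalg.qr(Q)
        dup = np.column_stack([Q, Q]) + 1.0
        m_eff = effective_marker_count(_gm(dup))
        assert m_eff == pytest.approx(k, abs=1e-6)

    def test_blockwise_matches_full_eigendecomposition(self, rng):
        # AR(1)-correlated Gaussian markers, single block = direct computation
        n, m, rho = 60, 50, 0.5
        eps = rng.standard_normal((n, m))
        X = np.empty((n, m))
        X[:, 0] = eps[:, 0]
        for j in range(1, m):
            X[:, j] = rho * X[:, j - 1] + np.sqrt(1 - rho ** 2) * eps[:, j]
        G = _gm(X + 2.0)
        lam = np.linalg.eigvalsh(np.corrcoef(X, rowvar=False))
        direct = float(np.sum((lam >= 1) + (np.clip(lam, 0, None)
                                            - np.floor(np.clip(lam, 0, None)))))
        assert effective_marker_count(G, block_size=1000) == \
            pytest.approx(direct, abs=1e-8)

    def test_never_exceeds_marker_count(self, rng):
        X = rng.integers(0, 3, size=(25, 40)).astype(float)
        X[:, 1] = X[:, 0]  # introduce correlation
        G = _gm(X)
        m_eff = effective_marker_count(G, block_size=7)
        assert m_eff <= 40 + 1e-9

    def test_constant_column_rejected(self):
        X = np.array([[0, 1.0], [0, 2], [0, 0], [0, 1]])
        with pytest.raises(ValueError, match="constant"):
            effective_marker_count(_gm(X))


class TestThresholds:
    def test_single_marker_reduces_to_alpha(self):
        th = significance_thresholds(1, 1, 0.05)
        assert th.bonferroni_p == pytest.approx(0.05)
        assert th.suggestive_p == 1.0

    @settings(derandomize=True, max_examples=50)
    @given(m=st.integers(2, 10 ** 6),
           alpha=st.floats(1e-6, 0.5),
           shrink=st.floats(0.1, 1.0))
    def test_monotone_and_bounded(self, m, alpha, shrink):
        m_eff = max(1.0, m * shrink)
        th = significance_thresholds(m, m_eff, alpha)
        assert th.bonferroni_p <= alpha
        assert th.suggestive_p <= 1.0
        th2 = significance_thresholds(m, min(float(m), m_eff * 1.5), alpha)
        assert th2.bonferroni_p <= th.bonferroni_p + 1e-18

    def test_invalid_alpha_rejected(self):
        for bad in (0.0, 1.0, -0.1, 2.0):
            with pytest.raises(ValueError):
                significance_thresholds(100, 100, bad)
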