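import numpy as np
import pytest

from phenodiv import (
    DistanceMatrix,
    TraitTable,
    mahalanobis_matrix,
    one_way_anova,
    pooled_residual_covariance,
    singh_contributions,
)
from phenodiv.divergence import SingularCovarianceError, pairwise_trait_terms
from oracles import brute_force_pooled_cov, brute_force_singh


def _identity_psi_table(mean_rows, noise_seed=0, r=50, sd=1.0):
    """Table whose pooled covariance is ~diag(sd^2): big-r iid residuals."""
    rng = np.random.default_rng(noise_seed)
    means = np.asarray(mean_rows, dtype=float)
    G, T = means.shape
    values = means[:, :, None] + rng.normal(0.0, sd, size=(G, T, r))
    names = [f"g{i}" for i in range(G)]
    return TraitTable(names, [f"t{j}" for j in range(T)], r, values)


class TestPooledCovariance:
    def test_single_trait_reduces_to_qmr(self, tiny_table):
        psi = pooled_residual_covariance(tiny_table)
        a = one_way_anova(tiny_table, "y")
        assert psi.psi.shape == (1, 1)
        assert psi.psi[0, 0] == pytest.approx(a.qmr)
        assert psi.df == 3

    def test_diagonal_equals_each_trait_qmr(self, random_table):
        psi = pooled_residual_covariance(random_table)
        for j, trait in enumerate(random_table.traits):
            assert psi.psi[j, j] == pytest.approx(
                one_way_anova(random_table, trait).qmr, rel=1e-12
            )

    def test_matches_brute_force_loop(self, two_trait_table):
        psi = pooled_residual_covariance(two_trait_table)
        expected = brute_force_pooled_cov(two_trait_table.values)
        np.testing.assert_allclose(psi.psi, expected, rtol=1e-12)

    def test_duplicated_trait_is_singular(self, tiny_table):
        dup = tiny_table.with_trait("y2", tiny_table.trait_values("y"))
        with pytest.raises(SingularCovarianceError, match="collinear"):
            pooled_residual_covariance(dup)

    def test_means_scale_divides_by_r(self, random_table):
        obs = pooled_residual_covariance(random_table, scale="observations")
        mns = pooled_residual_covariance(random_table, scale="means")
        np.testing.assert_allclose(mns.psi, obs.psi / random_table.r, rtol=1e-12)

    def test_underdetermined_warns(self):
        rng = np.random.default_rng(0)
        t = TraitTable(
            ["a", "b"], [f"t{i}" for i in range(5)], 2, rng.normal(size=(2, 5, 2))
        )
        # df < T: warns, and the resulting rank-deficient psi is rejected
        with pytest.warns(UserWarning, match="df=2 < number of traits"):
            with pytest.raises(SingularCovarianceError):
                pooled_residual_covariance(t)


class TestMahalanobis:
    def test_identical_means_zero_distance(self):
        t = _identity_psi_table([[0.0, 0.0], [0.0, 0.0]], noise_seed=1)
        psi = pooled_residual_covariance(t)
        d2 = mahalanobis_matrix(t, psi)
        assert d2.d2[0, 1] == pytest.approx(0.0, abs=0.5)

    def test_identity_metric_is_squared_euclidean(self):
        # exactly identity psi via a hand-built DistanceMatrix check:
        # residuals constructed so psi = I
        t = _psi_exact_identity()
        psi = pooled_residual_covariance(t)
        np.testing.assert_allclose(psi.psi, np.eye(2), atol=1e-12)
        d2 = mahalanobis_matrix(t, psi)
        m = t.genotype_means().to_numpy()
        diff = m[0] - m[1]
        assert d2.d2[0, 1] == pytest.approx(float(diff @ diff), rel=1e-9)

    def test_diagonal_psi_oracle(self, two_trait_table):
        psi = pooled_residual_covariance(two_trait_table)
        d2 = mahalanobis_matrix(two_trait_table, psi)
        m = two_trait_table.genotype_means().to_numpy()
        inv = np.linalg.inv(psi.psi)
        for i in range(3):
            for j in range(3):
                d = m[i] - m[j]
                assert d2.d2[i, j] == pytest.approx(float(d @ inv @ d), abs=1e-9)

    def test_symmetry_zero_diagonal_nonnegative(self, random_table):
        psi = pooled_residual_covariance(random_table)
        d2 = mahalanobis_matrix(random_table, psi)
        np.testing.assert_allclose(d2.d2, d2.d2.T, atol=1e-12)
        assert np.all(np.diag(d2.d2) == 0.0)
        assert np.all(d2.d2 >= 0.0)

    def test_invariant_under_trait_rescaling(self, random_table):
        psi = pooled_residual_covariance(random_table)
        d2 = mahalanobis_matrix(random_table, psi)
        scaled_values = random_table.values.copy()
        scaled_values[:, 1, :] *= 10.0
        ts = TraitTable(
            list(random_table.genotypes), list(random_table.traits),
            random_table.r, scaled_values,
        )
        d2s = mahalanobis_matrix(ts, pooled_residual_covariance(ts))
        np.testing.assert_allclose(d2s.d2, d2.d2, rtol=1e-6)


def _psi_exact_identity():
    """2 genotypes x 2 traits x 3 replicates with pooled covariance exactly I."""
    # per-genotype residuals with zero mean, cross-product 0, SS = df/G per trait
    G, T, r = 2, 2, 3
    resid_t0 = np.array([1.0, -1.0, 0.0])
    resid_t1 = np.array([0.0, 1.0, -1.0])
    values = np.empty((G, T, r))
    means = np.array([[0.0, 0.0], [3.0, 4.0]])
    for i in range(G):
        values[i, 0] = means[i, 0] + resid_t0
        values[i, 1] = means[i, 1] + resid_t1
    # pooled SS per trait = 2 genotypes * 2 = 4, df = G(r-1) = 4 -> diag 1
    # cross SS per genotype = 1*0 + (-1)*1 + 0*(-1) = -1 -> off-diag -2/4
    # fix cross terms by flipping one genotype's t1 residuals
    values[1, 1] = means[1, 1] - resid_t1
    return TraitTable(["a", "b"], ["x", "y"], r, values)


class TestSinghContributions:
    def test_two_genotype_identity_metric(self):
        t = _psi_exact_identity()
        psi = pooled_residual_covariance(t)
        contrib = singh_contributions(t, psi)
        # mean difference (3,4): contributions 9/25 and 16/25
        np.testing.assert_allclose(contrib.percent, [36.0, 64.0], atol=1e-9)

    def test_constant_trait_contributes_zero(self):
        rng = np.random.default_rng(8)
        G, r = 5, 6
        t0 = rng.normal(0, 1, size=(G, 1, r)) + np.arange(G)[:, None, None] * 5
        t1 = rng.normal(0, 1, size=(G, 1, r))  # same mean 0 for all genotypes
        t1 -= t1.mean(axis=2, keepdims=True)  # genotype means exactly equal
        values = np.concatenate([t0, t1], axis=1)
        t = TraitTable([f"g{i}" for i in range(G)], ["sig", "flat"], r, values)
        psi = pooled_residual_covariance(t)
        # decorrelate psi so the flat trait cannot borrow signal
        psi_diag = type(psi)(psi.traits, np.diag(np.diag(psi.psi)), psi.df)
        contrib = singh_contributions(t, psi_diag)
        assert contrib.percent[1] == pytest.approx(0.0, abs=1e-9)

    def test_pair_terms_sum_to_d2_and_totals_match_brute_force(self, random_table):
        psi = pooled_residual_covariance(random_table)
        d2 = mahalanobis_matrix(random_table, psi)
        G = random_table.n_genotypes
        for i in range(G):
            for j in range(i + 1, G):
                c = pairwise_trait_terms(random_table, psi, i, j)
                assert c.sum() == pytest.approx(d2.d2[i, j], rel=1e-9)
        m = random_table.genotype_means().to_numpy()
        s_j, total = brute_force_singh(m, psi.psi)
        contrib = singh_contributions(random_table, psi)
        np.testing.assert_allclose(contrib.s_j, s_j, rtol=1e-9)
        assert contrib.s_j.sum() == pytest.approx(total, rel=1e-9)
        assert contrib.percent.sum() == pytest.approx(100.0, abs=1e-6)

    def test_all_identical_genotypes_error(self):
        # replicates (a, -a, b, -b): every genotype mean is exactly zero
        values = np.array(
            [
                [[1, -1, 2, -2], [3, -3, 1, -1]],
                [[2, -2, 5, -5], [1, -1, 4, -4]],
                [[4, -4, 1, -1], [2, -2, 3, -3]],
            ],
            dtype=float,
        )
        t = TraitTable(["a", "b", "c"], ["x", "y"], 4, values)
        psi = pooled_residual_covariance(t)
        with pytest.raises(ValueError, match="total divergence is zero"):
            singh_contributions(t, psi)
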