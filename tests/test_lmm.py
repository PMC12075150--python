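"""Kinship construction, variance components, and Wald tests against
brute-force explicit-covariance oracles."""

import numpy as np
import pytest
from scipy.stats import chi2

from boagwas.containers import GenotypeMatrix, MISSING, make_marker_map, make_sample_table
from boagwas.lmm import (
    GRMEigen,
    LmmError,
    RankDeficientError,
    _profile,
    assoc_test,
    chi2_sf,
    fit_null_lmm,
    loco_grms,
    vanraden_grm,
)

from conftest import random_genotypes


def brute_force_grm(dosage):
    """Oracle: double loop over individual pairs with explicit centering."""
    d = np.asarray(dosage, dtype=float)
    n, m = d.shape
    miss = d == MISSING
    p = np.array([d[~miss[:, j], j].mean() / 2 for j in range(m)])
    for j in range(m):
        d[miss[:, j], j] = 2 * p[j]
    denom = 2 * np.sum(p * (1 - p))
    g = np.zeros((n, n))
    for i in range(n):
        for k in range(n):
            g[i, k] = np.sum((d[i] - 2 * p) * (d[k] - 2 * p)) / denom
    return g


class TestVanRaden:
    def test_hand_computed_two_by_one(self):
        geno = GenotypeMatrix(
            dosage=np.array([[0], [2]], dtype=np.int8),
            markers=make_marker_map(["m1"], [1], [5]),
            samples=make_sample_table(["a", "b"]),
        )
        grm = vanraden_grm(geno)
        np.testing.assert_allclose(grm.G, [[2, -2], [-2, 2]], atol=1e-12)
        assert grm.denominator == pytest.approx(0.5)

    def test_row_sums_zero_and_symmetry(self, rng):
        geno = random_genotypes(rng, 15, 40, missing_rate=0.05)
        grm = vanraden_grm(geno)
        np.testing.assert_allclose(grm.G.sum(axis=1), 0.0, atol=1e-10)
        np.testing.assert_allclose(grm.G, grm.G.T, atol=1e-12)
        assert grm.eigenvalues.min() > -1e-8

    def test_matches_bruteforce_10x50(self, rng):
        geno = random_genotypes(rng, 10, 50, missing_rate=0.04)
        grm = vanraden_grm(geno)
        np.testing.assert_allclose(grm.G, brute_force_grm(geno.dosage), atol=1e-12)

    def test_monomorphic_denominator_error(self):
        geno = GenotypeMatrix(
            dosage=np.full((4, 3), 2, dtype=np.int8),
            markers=make_marker_map(["m1", "m2", "m3"], [1, 1, 1], [1, 2, 3]),
            samples=make_sample_table(list("abcd")),
        )
        with pytest.raises(LmmError):
            vanraden_grm(geno)


class TestLoco:
    def test_numerator_additivity_two_chromosomes(self, rng):
        geno = random_genotypes(rng, 12, 30, n_chrom=2)
        full = vanraden_grm(geno)
        locos = loco_grms(geno)
        chrom = geno.markers["chromosome"].to_numpy()
        for c, loco in locos.items():
            only_c = vanraden_grm(geno, marker_mask=chrom == c)
            lhs = full.G * full.denominator
            rhs = loco.G * loco.denominator + only_c.G * only_c.denominator
            np.testing.assert_allclose(lhs, rhs, atol=1e-9)

    def test_excluded_chromosome_has_no_influence(self, rng):
        geno = random_genotypes(rng, 10, 24, n_chrom=2)
        locos = loco_grms(geno)
        chrom = geno.markers["chromosome"].to_numpy()
        shuffled = geno.copy()
        idx = np.flatnonzero(chrom == 1)
        perm = rng.permutation(geno.n_individuals)
        shuffled.dosage[:, idx] = shuffled.dosage[perm][:, idx]
        locos2 = loco_grms(shuffled)
        np.testing.assert_allclose(locos[1].G, locos2[1].G, atol=1e-12)

    def test_row_sums_zero_many_chromosomes(self, small_cohort):
        _, geno, _, _, _ = small_cohort
        for loco in loco_grms(geno).values():
            np.testing.assert_allclose(loco.G.sum(axis=1), 0.0, atol=1e-8)

    def test_single_chromosome_rejected(self, rng):
        geno = random_genotypes(rng, 8, 10, n_chrom=1)
        with pytest.raises(LmmError):
            loco_grms(geno)


def _random_instance(rng, n, m=None, h2=0.5):
    """Random (y, X, grm) with genuine genetic covariance."""
    m = m or n + 40
    geno = random_genotypes(rng, n, m)
    grm = vanraden_grm(geno)
    X = np.column_stack([np.ones(n), rng.standard_normal((n, 2))])
    lam = np.maximum(grm.eigenvalues, 0)
    g = grm.eigenvectors @ (np.sqrt(h2 * lam) * rng.standard_normal(n))
    y = X @ rng.standard_normal(3) + g + rng.normal(0, np.sqrt(1 - h2), n)
    return y, X, grm


class TestNullFit:
    def test_identity_grm_resolves_to_ols(self, rng):
        """With G = I the split is unidentifiable; the tie rule returns the
        h2 = 0 boundary and the total variance equals the ML OLS residual
        variance."""
        n = 60
        X = np.column_stack([np.ones(n), rng.standard_normal(n)])
        y = X @ [1.0, 0.5] + rng.normal(0, 1.3, n)
        vc = fit_null_lmm(y, X, GRMEigen.identity(n))
        assert vc.h2 == 0.0
        beta = np.linalg.lstsq(X, y, rcond=None)[0]
        rss = np.sum((y - X @ beta) ** 2)
        assert vc.sigma_g2 + vc.sigma_e2 == pytest.approx(rss / n, rel=1e-10)

    def test_profile_matches_explicit_mvn_density(self, rng):
        """Rotated profile log-likelihood equals the direct multivariate
        normal log-density with V = sigma_g^2 G + sigma_e^2 I."""
        y, X, grm = _random_instance(rng, 12)
        n = len(y)
        lam, u = grm.floored_eigenvalues(), grm.eigenvectors
        for h2 in [0.0, 0.2, 0.5, 0.8, 0.95]:
            ll, _, s2, _ = _profile(h2, lam, u.T @ y, u.T @ X, "ml")
            v = s2 * (h2 * grm.G + (1 - h2) * np.eye(n))
            vi = np.linalg.inv(v)
            _, logdet = np.linalg.slogdet(v)
            beta = np.linalg.solve(X.T @ vi @ X, X.T @ vi @ y)
            r = y - X @ beta
            direct = -0.5 * (n * np.log(2 * np.pi) + logdet + r @ vi @ r)
            assert ll == pytest.approx(direct, abs=1e-8)

    def test_rank_deficient_x_rejected(self, rng):
        n = 30
        X = np.column_stack([np.ones(n), np.ones(n)])
        with pytest.raises(RankDeficientError):
            fit_null_lmm(rng.standard_normal(n), X, GRMEigen.identity(n))

    def test_h2_recovery_small(self, rng):
        """Moderate-scale parameter recovery; REML removes the fixed-effect
        bias of ML."""
        vals = []
        for rep in range(10):
            y, X, grm = _random_instance(np.random.default_rng(300 + rep), 200, 400, h2=0.4)
            vals.append(fit_null_lmm(y, X, grm, method="reml").h2)
        assert np.mean(vals) == pytest.approx(0.4, abs=0.08)


class TestAssoc:
    def test_ols_limit_matches_textbook_wald(self, rng):
        """sigma_g^2 pinned at 0 with G = I reproduces OLS Wald p-values."""
        n = 50
        X = np.column_stack([np.ones(n), rng.standard_normal(n)])
        snp = rng.integers(0, 3, n).astype(float)
        y = 0.3 * snp + X @ [1, 0.5] + rng.normal(0, 1, n)
        res = assoc_test(y, X, snp, GRMEigen.identity(n), "snp", fixed_h2=0.0)
        d = np.column_stack([X, snp])
        beta = np.linalg.lstsq(d, y, rcond=None)[0]
        resid = y - d @ beta
        s2 = resid @ resid / n  # ML scale
        cov = s2 * np.linalg.inv(d.T @ d)
        wald = beta[-1] ** 2 / cov[-1, -1]
        assert res.wald == pytest.approx(wald, abs=1e-10)
        assert res.p == pytest.approx(chi2.sf(wald, 1), abs=1e-10)

    def test_identical_boa_column_is_aliased(self, rng):
        n = 40
        X = np.ones((n, 1))
        snp = rng.integers(0, 3, n).astype(float)
        y = snp * 0.4 + rng.standard_normal(n)
        res = assoc_test(y, X, np.column_stack([snp, snp]), GRMEigen.identity(n), "joint")
        assert res.aliased
        assert res.df == 1
        assert np.isnan(res.beta_boa)
        assert np.isfinite(res.beta_snp)

    def test_monomorphic_covariable_gives_missing_result(self, rng):
        n = 30
        y = rng.standard_normal(n)
        res = assoc_test(y, np.ones((n, 1)), np.full(n, 2.0), GRMEigen.identity(n), "snp")
        assert np.isnan(res.p)
        assert res.df == 0

    def test_joint_wald_decomposes_under_gls_orthogonality(self, rng):
        """When the two covariables are orthogonal to each other and to X in
        the V^{-1} metric, the 2-df joint Wald equals the sum of the fit's
        per-effect 1-df Walds."""
        y, X, grm = _random_instance(rng, 60)
        h2 = 0.4
        v = h2 * grm.G + (1 - h2) * np.eye(len(y))
        vi = np.linalg.inv(v)
        c1 = rng.standard_normal(len(y))
        # V-orthogonalize c1 against X, then c2 against [X, c1]
        b1 = np.linalg.solve(X.T @ vi @ X, X.T @ vi @ c1)
        c1 = c1 - X @ b1
        c2 = rng.standard_normal(len(y))
        d = np.column_stack([X, c1])
        b2 = np.linalg.solve(d.T @ vi @ d, d.T @ vi @ c2)
        c2 = c2 - d @ b2
        res = assoc_test(y, X, np.column_stack([c1, c2]), grm, "joint", fixed_h2=h2)
        w_snp = (res.beta_snp / res.se_snp) ** 2
        w_boa = (res.beta_boa / res.se_boa) ** 2
        assert res.wald == pytest.approx(w_snp + w_boa, abs=1e-8)

    def test_wald_matches_bruteforce_gls(self):
        """Rotated Wald statistics equal explicit-V GLS on random instances."""
        for seed in range(5):
            rng = np.random.default_rng(800 + seed)
            y, X, grm = _random_instance(rng, int(rng.integers(25, 80)))
            n = len(y)
            snp = rng.integers(0, 3, n).astype(float)
            boa = rng.integers(0, 3, n).astype(float)
            h2 = fit_null_lmm(y, X, grm).h2
            v = h2 * grm.G + (1 - h2) * np.eye(n)
            vi = np.linalg.inv(v)
            for model, cols in [("snp", snp[:, None]), ("boa", boa[:, None]),
                                ("joint", np.column_stack([snp, boa]))]:
                res = assoc_test(y, X, cols, grm, model, fixed_h2=h2)
                d = np.column_stack([X, cols])
                beta = np.linalg.solve(d.T @ vi @ d, d.T @ vi @ y)
                r = y - d @ beta
                s2 = (r @ vi @ r) / n
                cov = s2 * np.linalg.inv(d.T @ vi @ d)
                k = X.shape[1]
                bb, cb = beta[k:], cov[k:, k:]
                if model == "joint":
                    wald = bb @ np.linalg.solve(cb, bb)
                else:
                    wald = bb[0] ** 2 / cb[0, 0]
                assert res.wald == pytest.approx(wald, abs=1e-6)


class TestChi2:
    def test_zero_statistic(self):
        assert chi2_sf(0.0, 1) == 1.0
        assert chi2_sf(0.0, 2) == 1.0

    def test_df2_closed_form(self):
        w = 2 * np.log(20)
        assert chi2_sf(w, 2) == pytest.approx(0.05, abs=1e-12)
        for w in [0.5, 3.0, 10.0]:
            assert chi2_sf(w, 2) == pytest.approx(np.exp(-w / 2), rel=1e-12)

    def test_df1_quantile(self):
        assert chi2_sf(3.841459, 1) == pytest.approx(0.05, abs=1e-6)

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            chi2_sf(-1.0, 1)
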