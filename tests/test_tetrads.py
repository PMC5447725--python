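import warnings
from itertools import combinations
from math import comb

import numpy as np
import pytest
from scipy import stats

import gscata as g
from gscata.tetrads import (
    PIVOT_TOL,
    covariance_pairs,
    sigma_S_adf,
    sigma_S_normal,
)


def brute_force_tetrads(Sigma):
    """Independent four-nested-loop enumeration in the canonical order."""
    J = Sigma.shape[0]
    vals = []
    for i in range(J):
        for j in range(i + 1, J):
            for k in range(j + 1, J):
                for l in range(k + 1, J):
                    vals.append(Sigma[i, j] * Sigma[k, l] - Sigma[i, k] * Sigma[j, l])
                    vals.append(Sigma[i, k] * Sigma[l, j] - Sigma[i, l] * Sigma[k, j])
                    vals.append(Sigma[i, l] * Sigma[j, k] - Sigma[i, j] * Sigma[l, k])
    return np.asarray(vals)


class TestEnumeration:
    @pytest.mark.parametrize("J,count", [(4, 3), (5, 15), (8, 210), (10, 630)])
    def test_count_closed_form(self, J, count):
        cat = g.enumerate_tetrads(J)
        assert cat.n_tetrads == count == 3 * comb(J, 4)

    def test_j_below_four_rejected(self):
        with pytest.raises(ValueError):
            g.enumerate_tetrads(3)

    def test_canonical_order_matches_brute_force(self):
        rng = np.random.default_rng(3)
        A = rng.normal(size=(5, 5))
        Sigma = (A + A.T) / 2
        cat = g.enumerate_tetrads(5)
        np.testing.assert_allclose(
            g.tetrad_values(Sigma, cat), brute_force_tetrads(Sigma), atol=1e-14
        )

    def test_quadruples_lexicographic(self):
        cat = g.enumerate_tetrads(6)
        quads = list(dict.fromkeys(cat.quadruples))
        assert quads == sorted(combinations(range(6), 4))


class TestTetradValues:
    def test_identity_gives_zeros(self):
        cat = g.enumerate_tetrads(6)
        assert np.all(g.tetrad_values(np.eye(6), cat) == 0)

    def test_single_factor_all_three_vanish(self, one_factor_sigma):
        cat = g.enumerate_tetrads(4)
        tau = g.tetrad_values(one_factor_sigma, cat)
        np.testing.assert_allclose(tau, 0.0, atol=1e-15)

    def test_asymmetric_input_rejected(self):
        cat = g.enumerate_tetrads(4)
        M = np.eye(4)
        M[0, 1] = 0.5
        with pytest.raises(ValueError, match="symmetric"):
            g.tetrad_values(M, cat)

    def test_redundancy_law_one_factor_quadruple(self):
        """For a one-factor quadruple, any two vanishing tetrads imply the
        third: the three tetrad values always sum to zero and each is zero
        under the rank-one structure."""
        rng = np.random.default_rng(6)
        cat = g.enumerate_tetrads(4)
        for _ in range(20):
            lam = rng.uniform(0.3, 0.95, size=4)
            Sig = np.outer(lam, lam)
            np.fill_diagonal(Sig, 1.0)
            tau = g.tetrad_values(Sig, cat)
            np.testing.assert_allclose(tau, 0.0, atol=1e-14)
            # the sum identity holds for arbitrary symmetric input too
            A = rng.normal(size=(4, 4))
            tau_any = g.tetrad_values((A + A.T) / 2, cat)
            assert abs(tau_any.sum()) < 1e-12


class TestVanishingSet:
    def test_one_component_four_indicators(self, one_factor_exact_data,
                                           one_factor_spec):
        fit = g.fit_gsca(one_factor_exact_data, one_factor_spec)
        Sig = g.implied_correlation(fit, one_factor_exact_data)
        cat = g.enumerate_tetrads(4)
        van = g.implied_vanishing_set(Sig, cat)
        assert van.tolist() == [0, 1, 2]

    def test_saturated_matrix_untestable(self):
        rng = np.random.default_rng(9)
        A = rng.normal(size=(40, 4))
        S = np.corrcoef(A, rowvar=False)
        cat = g.enumerate_tetrads(4)
        with pytest.raises(g.UntestableModelError):
            g.implied_vanishing_set(S, cat)

    def test_m3_vanishing_matches_generic_parameter_oracle(self):
        """A tetrad is structural for the four-block model iff it vanishes
        at several independent random parameter draws of the population
        structure."""
        cat = g.enumerate_tetrads(8)
        rng = np.random.default_rng(13)
        masks = []
        for _ in range(3):
            lam = rng.uniform(0.5, 0.95, size=8)
            # random PD factor correlation
            Q = rng.normal(size=(4, 4))
            Phi = Q @ Q.T
            d = np.sqrt(np.diag(Phi))
            Phi = Phi / np.outer(d, d)
            blocks = [(0, 1), (2, 3), (4, 5), (6, 7)]
            Lam = np.zeros((8, 4))
            for p, (a, b) in enumerate(blocks):
                Lam[a, p], Lam[b, p] = lam[a], lam[b]
            Sig = Lam @ Phi @ Lam.T
            np.fill_diagonal(Sig, 1.0)
            masks.append(np.abs(g.tetrad_values(Sig, cat)) < 1e-12)
        structural = masks[0] & masks[1] & masks[2]
        # fitted M3 on synthetic data implies exactly the structural set
        cfg = g.builtin_config("M3", n=1000, seed=77)
        data = g.standardize(g.generate(cfg, clip=False))
        fit = g.fit_gsca(data, g.builtin_model("M3"))
        van = g.implied_vanishing_set(g.implied_correlation(fit, data), cat)
        assert set(van.tolist()) == set(np.flatnonzero(structural).tolist())
        assert structural.sum() == 54


class TestSigmaS:
    def test_duplication_invariance(self):
        rng = np.random.default_rng(21)
        X = rng.normal(size=(30, 4))
        d1 = g.standardize(X, names=tuple("abcd"))
        d2 = g.standardize(np.vstack([X, X, X]), names=tuple("abcd"))
        np.testing.assert_allclose(sigma_S_adf(d1), sigma_S_adf(d2), atol=1e-12)

    def test_explicit_loop_oracle(self):
        rng = np.random.default_rng(22)
        X = rng.normal(size=(20, 4))
        data = g.standardize(X, names=tuple("abcd"))
        Z = data.Z
        N = 20
        pairs = covariance_pairs(4)
        S = data.sample_correlation
        expect = np.empty((6, 6))
        for a, (gi, h) in enumerate(pairs):
            for c, (i, j) in enumerate(pairs):
                m4 = sum(Z[n, gi] * Z[n, h] * Z[n, i] * Z[n, j] for n in range(N)) / N
                expect[a, c] = m4 - S[gi, h] * S[i, j]
        np.testing.assert_allclose(sigma_S_adf(data), expect, atol=1e-12)

    def test_gaussian_large_n_matches_normal_theory(self):
        """For Gaussian data the fourth-moment estimator converges to the
        normal-theory closed form sigma_gi sigma_hj + sigma_gj sigma_hi."""
        lam = np.array([0.9, 0.8, 0.7, 0.6])
        Sig = np.outer(lam, lam)
        np.fill_diagonal(Sig, 1.0)
        rng = np.random.default_rng(23)
        X = rng.standard_normal((50000, 4)) @ np.linalg.cholesky(Sig).T
        data = g.standardize(X, names=tuple("abcd"))
        adf = sigma_S_adf(data)
        closed = sigma_S_normal(data.sample_correlation)
        # Monte-Carlo error of fourth moments at n=50000 is well below 0.05
        assert np.abs(adf - closed).max() < 0.05

    def test_small_n_warns(self):
        rng = np.random.default_rng(1)
        data = g.standardize(rng.normal(size=(8, 4)), names=tuple("abcd"))
        with pytest.warns(UserWarning, match="N < 10"):
            sigma_S_adf(data)


class TestJacobian:
    def test_identity_point_all_zero(self):
        cat = g.enumerate_tetrads(5)
        jac = g.jacobian_tau_sigma(cat, np.eye(5))
        assert np.all(jac == 0)

    def test_at_most_four_nonzeros_per_row(self):
        cat = g.enumerate_tetrads(7)
        rng = np.random.default_rng(2)
        A = rng.normal(size=(7, 7))
        jac = g.jacobian_tau_sigma(cat, (A + A.T) / 2)
        assert ((jac != 0).sum(axis=1) <= 4).all()

    def test_finite_difference_oracle(self):
        cat = g.enumerate_tetrads(5)
        rng = np.random.default_rng(4)
        A = rng.uniform(-0.5, 0.5, size=(5, 5))
        Sigma = (A + A.T) / 2
        np.fill_diagonal(Sigma, 1.0)
        jac = g.jacobian_tau_sigma(cat, Sigma)
        pairs = covariance_pairs(5)
        h = 1e-6
        for c, (a, b) in enumerate(pairs):
            Sp = Sigma.copy()
            Sp[a, b] += h
            Sp[b, a] += h
            fd = (g.tetrad_values(Sp, cat) - g.tetrad_values(Sigma, cat)) / h
            np.testing.assert_allclose(jac[:, c], fd, atol=1e-6)


class TestSweepSelection:
    def _sigma_tau(self, data, vanishing, cat):
        S = data.sample_correlation
        jac = g.jacobian_tau_sigma(cat, S)[vanishing]
        return jac @ sigma_S_adf(data) @ jac.T

    def test_one_factor_retains_two_of_three(self, one_factor_noisy_data):
        cat = g.enumerate_tetrads(4)
        van = np.array([0, 1, 2])
        Sig_tau = self._sigma_tau(one_factor_noisy_data, van, cat)
        for seed in range(20):
            sel = g.select_nonredundant(van, Sig_tau, seed=seed)
            assert sel.size == 2
            assert np.linalg.matrix_rank(Sig_tau) == 2

    def test_duplicated_rows_never_coselected(self):
        van = np.array([0, 1, 2, 3])
        base = np.array([[2.0, 0.3], [0.3, 1.0]])
        # tetrads 0/1 identical and 2/3 identical
        K = np.kron(base, np.ones((2, 2)))
        sel = g.select_nonredundant(van, K, seed=5)
        assert sel.size == 2
        assert not ({0, 1} <= set(sel.tolist()))
        assert not ({2, 3} <= set(sel.tolist()))

    def test_retained_count_equals_rank(self, m3_data):
        cat = g.enumerate_tetrads(8)
        fit = g.fit_gsca(m3_data, g.builtin_model("M3"))
        van = g.implied_vanishing_set(g.implied_correlation(fit, m3_data), cat)
        Sig_tau = self._sigma_tau(m3_data, van, cat)
        rank = np.linalg.matrix_rank(Sig_tau, tol=PIVOT_TOL * Sig_tau.diagonal().max())
        for seed in range(20):
            sel = g.select_nonredundant(van, Sig_tau, seed=seed)
            assert sel.size == rank


class TestTetradTest:
    def test_exact_vanishing_data_gives_zero_statistic(self, one_factor_sigma,
                                                       one_factor_spec):
        """Data whose sample correlations carry the exact rank-one
        structure: all sample tetrads in the vanishing set are zero, so
        T = 0 and p = 1."""
        from conftest import exact_sample_data

        data = exact_sample_data(one_factor_sigma, n=300, seed=8)
        fit = g.fit_gsca(data, one_factor_spec)
        res = g.tetrad_test(data, fit, seed=0)
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(1.0)
        assert res.df == 2

    def test_statistic_invariant_to_selection_order(self, one_factor_noisy_data,
                                                    one_factor_spec):
        fit = g.fit_gsca(one_factor_noisy_data, one_factor_spec)
        res1 = g.tetrad_test(one_factor_noisy_data, fit,
                             _selection=np.array([0, 1]))
        res2 = g.tetrad_test(one_factor_noisy_data, fit,
                             _selection=np.array([1, 0]))
        assert res1.statistic == pytest.approx(res2.statistic, abs=1e-9)

    def test_t_and_t1_nonnegative(self, one_factor_noisy_data, one_factor_spec):
        fit = g.fit_gsca(one_factor_noisy_data, one_factor_spec)
        for use_T1 in (False, True):
            res = g.tetrad_test(one_factor_noisy_data, fit, seed=1, use_T1=use_T1)
            assert res.statistic >= 0.0

    def test_large_sample_warning(self, m0_data, m0_fit):
        with pytest.warns(UserWarning, match="large sample"):
            g.tetrad_test(m0_data, m0_fit, seed=0)

    def test_explicit_loop_oracle_j5(self):
        """T on J=5 synthetic data equals a no-linear-algebra-shortcut
        reimplementation built from explicit loops."""
        rng = np.random.default_rng(31)
        lam = np.array([0.9, 0.85, 0.8, 0.75, 0.7])
        Sig = np.outer(lam, lam)
        np.fill_diagonal(Sig, 1.0)
        X = rng.standard_normal((400, 5)) @ np.linalg.cholesky(Sig).T
        data = g.standardize(X, names=tuple("abcde"))
        spec = g.parse_model("F =~ a + b + c + d + e\n")
        fit = g.fit_gsca(data, spec)
        res = g.tetrad_test(data, fit, seed=3)
        expected = _oracle_T(data.Z, res.nonredundant_idx, res.catalog)
        assert res.statistic == pytest.approx(expected, abs=1e-8)

    def test_normal_theory_option_close_for_gaussian(self, one_factor_noisy_data,
                                                     one_factor_spec):
        fit = g.fit_gsca(one_factor_noisy_data, one_factor_spec)
        sel = np.array([0, 1])
        adf = g.tetrad_test(one_factor_noisy_data, fit, _selection=sel)
        nt = g.tetrad_test(one_factor_noisy_data, fit, _selection=sel,
                           normal_theory=True)
        assert nt.statistic == pytest.approx(adf.statistic, rel=0.5)

    def test_chi2_calibration_under_null(self, one_factor_sigma,
                                         one_factor_spec):
        """Type-I error near nominal and the statistic's distribution
        consistent with chi-square(2) under a true one-factor model."""
        L = np.linalg.cholesky(one_factor_sigma)
        rng = np.random.default_rng(71)
        T = []
        rej = 0
        R = 400
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            for _ in range(R):
                X = rng.standard_normal((500, 4)) @ L.T
                data = g.standardize(X, names=("x1", "x2", "x3", "x4"))
                fit = g.fit_gsca(data, one_factor_spec)
                res = g.tetrad_test(data, fit, seed=int(rng.integers(2**31)))
                T.append(res.statistic)
                rej += res.p_value < 0.05
        assert 0.02 <= rej / R <= 0.09
        ks = stats.kstest(np.asarray(T), stats.chi2(2).cdf)
        assert ks.pvalue > 0.01


def _oracle_T(Z, selection, catalog):
    """Explicit-loop tetrad statistic: python loops only, gaussian
    elimination written out by hand."""
    N, J = Z.shape
    # sample correlations
    S = [[sum(Z[n][a] * Z[n][b] for n in range(N)) / N for b in range(J)]
         for a in range(J)]
    pairs = [(a, b) for b in range(J) for a in range(b + 1, J)]
    K = len(pairs)
    # fourth-moment covariance of sample covariances
    SigS = [[0.0] * K for _ in range(K)]
    for x, (ga, h) in enumerate(pairs):
        for y, (i, j) in enumerate(pairs):
            m4 = sum(Z[n][ga] * Z[n][h] * Z[n][i] * Z[n][j] for n in range(N)) / N
            SigS[x][y] = m4 - S[ga][h] * S[i][j]
    # jacobian rows for the selected tetrads
    colof = {}
    for t, (a, b) in enumerate(pairs):
        colof[(a, b)] = t
        colof[(b, a)] = t
    rows = []
    tau = []
    for t in selection:
        (a, b), (c, d), (e, f), (gg, h) = catalog.pairings[t]
        row = [0.0] * K
        row[colof[(a, b)]] += S[c][d]
        row[colof[(c, d)]] += S[a][b]
        row[colof[(e, f)]] -= S[gg][h]
        row[colof[(gg, h)]] -= S[e][f]
        rows.append(row)
        tau.append(S[a][b] * S[c][d] - S[e][f] * S[gg][h])
    m = len(rows)
    # Sigma_tau = rows * SigS * rows'
    Sig_tau = [[sum(rows[x][u] * SigS[u][v] * rows[y][v]
                    for u in range(K) for v in range(K))
                for y in range(m)] for x in range(m)]
    # solve Sig_tau * sol = tau by gaussian elimination
    Aug = [Sig_tau[x][:] + [tau[x]] for x in range(m)]
    for col in range(m):
        piv = max(range(col, m), key=lambda r: abs(Aug[r][col]))
        Aug[col], Aug[piv] = Aug[piv], Aug[col]
        for r in range(m):
            if r != col and Aug[r][col] != 0.0:
                fac = Aug[r][col] / Aug[col][col]
                for cc in range(col, m + 1):
                    Aug[r][cc] -= fac * Aug[col][cc]
    sol = [Aug[x][m] / Aug[x][x] for x in range(m)]
    return N * sum(tau[x] * sol[x] for x in range(m))
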