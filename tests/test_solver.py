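"""IHT solver: step sizes, convergence, debiasing, full fits."""

import numpy as np
import pytest
from scipy.optimize import minimize_scalar

from conftest import dense_standardized, random_genotypes
from ihtglm.families import get_family, glm_weights
from ihtglm.genotypes import CovariateMatrix, Design
from ihtglm.projections import SparsityConstraint
from ihtglm.solver import IhtOptions, converged, debias, fit_iht, step_size


def gaussian_problem(rng, n, p, k_true, noise=1.0, effects=None):
    G = random_genotypes(rng, n, p)
    beta = np.zeros(p)
    causal = rng.choice(p, k_true, replace=False)
    beta[causal] = effects if effects is not None else rng.uniform(0.3, 1.0, k_true)
    y = G.standardized_xv(beta) + noise * rng.standard_normal(n)
    return G, beta, np.sort(causal), y


class TestStepSize:
    def test_identity_design_gives_unit_step(self, rng):
        Z = CovariateMatrix.from_array(np.eye(6), standardize=False)
        D = Design(None, Z)
        fam = get_family("normal")
        mu = np.zeros(6)
        grad = rng.normal(size=6)
        assert step_size(grad, D, fam, mu, mu) == pytest.approx(1.0)

    def test_diagonal_information(self):
        Z = CovariateMatrix.from_array(
            np.diag([np.sqrt(2.0), 1.0]), standardize=False
        )
        D = Design(None, Z)
        fam = get_family("normal")
        mu = np.zeros(2)
        s = step_size(np.array([1.0, 0.0]), D, fam, mu, mu)
        assert s == pytest.approx(0.5)

    def test_zero_gradient_signals_convergence(self):
        Z = CovariateMatrix.from_array(np.eye(3), standardize=False)
        D = Design(None, Z)
        fam = get_family("normal")
        mu = np.zeros(3)
        assert step_size(np.zeros(3), D, fam, mu, mu) is None

    def test_matches_golden_section_line_search(self, rng):
        # for a Gaussian loglikelihood the expected-information quotient is
        # the exact maximizer of L(beta + s * grad) along the full gradient
        for _ in range(10):
            n, p = 15, 6
            X = rng.normal(size=(n, p))
            Z = CovariateMatrix.from_array(X, standardize=False)
            D = Design(None, Z)
            fam = get_family("normal")
            y = rng.normal(size=n)
            beta = rng.normal(scale=0.3, size=p)
            eta = X @ beta
            mu = fam.mean(eta)
            grad = X.T @ (y - mu)
            s = step_size(grad, D, fam, mu, eta)

            def neg_ll(t):
                return -fam.loglikelihood(y, X @ (beta + t * grad))

            res = minimize_scalar(
                neg_ll, bracket=(0.0, max(2 * s, 1e-3)), method="golden",
                options={"xtol": 1e-12},
            )
            assert s == pytest.approx(res.x, rel=1e-6)


class TestConverged:
    @pytest.mark.parametrize(
        "prev,nxt,tol,expected",
        [
            ([1.0, 1.0], [1.00005, 1.0], 1e-4, True),
            ([0.0, 0.0], [0.0, 0.0], 1e-4, True),
            ([1.0, 0.0], [1.5, 0.0], 1e-4, False),
        ],
    )
    def test_relative_supnorm_criterion(self, prev, nxt, tol, expected):
        assert converged(np.array(prev), np.array(nxt), tol) is expected


class TestDebias:
    def test_single_column_is_univariate_ols(self, rng):
        G, _, _, y = gaussian_problem(rng, 40, 3, 1)
        fam = get_family("normal")
        st = fit_iht(y, G, family=fam, constraint=SparsityConstraint(k=1))
        D = Design(G)
        st = debias(st, D, fam, y)
        j = st.support[0]
        x = dense_standardized(G)[:, j]
        assert st.b[j] == pytest.approx(x @ y / (x @ x), rel=1e-8)

    def test_empty_support_unchanged(self, rng):
        G, _, _, y = gaussian_problem(rng, 20, 4, 1)
        fam = get_family("normal")
        st = fit_iht(y, G, family=fam, constraint=SparsityConstraint(k=0))
        before = st.b.copy()
        st = debias(st, Design(G), fam, y)
        assert np.array_equal(st.b, before)

    def test_matches_dense_least_squares_on_support(self, rng):
        G, _, _, y = gaussian_problem(rng, 100, 200, 10)
        fam = get_family("normal")
        st = fit_iht(
            y, G, family=fam, constraint=SparsityConstraint(k=10),
            options=IhtOptions(debias=True),
        )
        S = st.support
        Xs = dense_standardized(G)[:, S]
        ols, *_ = np.linalg.lstsq(Xs, y, rcond=None)
        assert np.allclose(st.b[S], ols, atol=1e-6)


class TestFitIht:
    def test_orthonormal_design_one_step_ols(self, rng):
        Z = CovariateMatrix.from_array(np.eye(8), standardize=False)
        y = rng.normal(size=8)
        st = fit_iht(y, None, Z, family=get_family("normal"),
                     constraint=SparsityConstraint(k=8))
        assert np.allclose(st.b, y, atol=1e-8)

    def test_k_zero_returns_null_model(self, rng):
        G, _, _, y = gaussian_problem(rng, 30, 10, 2)
        fam = get_family("normal")
        st = fit_iht(y, G, family=fam, constraint=SparsityConstraint(k=0))
        assert st.converged and st.support.size == 0
        assert st.loglik == pytest.approx(fam.loglikelihood(y, np.zeros(30)))

    def test_overparameterized_gaussian_reaches_ols(self, rng):
        # k >= p and n > p: the sparse solver must agree with dense OLS
        G, _, _, y = gaussian_problem(rng, 80, 12, 4)
        st = fit_iht(
            y, G, family=get_family("normal"), constraint=SparsityConstraint(k=12),
            options=IhtOptions(tol=1e-10, max_iter=2000),
        )
        Xs = dense_standardized(G)
        ols, *_ = np.linalg.lstsq(Xs, y, rcond=None)
        assert np.allclose(st.b, ols, atol=1e-6)

    def test_large_effects_recovered(self, rng):
        G, beta, causal, y = gaussian_problem(
            rng, 1000, 2000, 10, effects=np.arange(0.1, 1.01, 0.1)
        )
        st = fit_iht(y, G, family=get_family("normal"),
                     constraint=SparsityConstraint(k=10),
                     options=IhtOptions(backend="dense"))
        big = causal[np.isin(np.round(beta[causal], 2),
                             [0.6, 0.7, 0.8, 0.9, 1.0])]
        assert set(big).issubset(set(st.support))

    @pytest.mark.parametrize("family", ["normal", "bernoulli"])
    def test_accepted_loglik_nondecreasing(self, family, rng):
        for _ in range(8):
            n, p, k = 80, 150, 5
            G = random_genotypes(rng, n, p)
            beta = np.zeros(p)
            beta[rng.choice(p, k, replace=False)] = rng.uniform(0.3, 1.0, k)
            eta = G.standardized_xv(beta)
            fam = get_family(family)
            mu = fam.mean(eta)
            if family == "normal":
                y = mu + rng.standard_normal(n)
            else:
                y = (rng.random(n) < mu).astype(float)
            st = fit_iht(y, G, family=fam, constraint=SparsityConstraint(k=k))
            lls = [t[1] for t in st.trace]
            backs = [t[3] for t in st.trace]
            for i in range(1, len(lls)):
                if backs[i] < 5:  # a successful backtracking pass restores ascent
                    assert lls[i] >= lls[i - 1] - 1e-9

    def test_support_respects_constraint_every_iteration(self, rng):
        G, _, _, y = gaussian_problem(rng, 60, 120, 4)
        membership = np.arange(120) // 10
        c = SparsityConstraint(membership=membership, j=3, lambda_g=2)
        st = fit_iht(y, G, family=get_family("normal"), constraint=c)
        for _, _, _, _, supp in st.trace:
            assert supp <= c.max_support()
        b = st.b[:120]
        groups = np.unique(membership[b != 0])
        assert groups.size <= 3
        for g in groups:
            assert np.count_nonzero(b[membership == g]) <= 2

    def test_covariates_can_be_exempt_from_projection(self, rng):
        G, _, _, y = gaussian_problem(rng, 50, 20, 3)
        Z = CovariateMatrix.intercept_only(50)
        st = fit_iht(
            y + 4.0, G, Z, family=get_family("normal"),
            constraint=SparsityConstraint(k=3),
            options=IhtOptions(project_covariates=False),
        )
        assert st.b[20] == pytest.approx(4.0, abs=0.5)  # intercept survives
        assert np.count_nonzero(st.b[:20]) <= 3

    def test_response_length_mismatch(self, rng):
        G = random_genotypes(rng, 10, 5)
        with pytest.raises(ValueError, match="length"):
            fit_iht(np.zeros(9), G, family=get_family("normal"),
                    constraint=SparsityConstraint(k=1))
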