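import math

import numpy as np
import pytest
from scipy import optimize

from xciskew.data_model import XDataset, encode
from xciskew.glm_engine import fit_linear, fit_logistic, reparameterize


class TestReparameterize:
    @pytest.mark.parametrize(
        "cov2, expected",
        [
            ([[1.0, 0.0], [0.0, 1.0]], (1.0, 0.5, 0.5)),
            ([[2.0, 2.0], [2.0, 2.0]], (2.0, 2.0, 2.0)),  # perfect correlation
        ],
    )
    def test_closed_form(self, cov2, expected):
        assert reparameterize(np.array(cov2)) == pytest.approx(expected)

    def test_rejects_asymmetric(self):
        with pytest.raises(ValueError):
            reparameterize(np.array([[1.0, 0.5], [0.2, 1.0]]))

    def test_monte_carlo_oracle(self):
        # (v1, v2, v12) must equal the sample covariance of (b1, (b1+b2)/2)
        rng = np.random.default_rng(7)
        a = rng.normal(size=(2, 2))
        cov2 = a @ a.T + 0.1 * np.eye(2)
        draws = rng.multivariate_normal([0, 0], cov2, size=1_000_000)
        b1 = draws[:, 0]
        bbar = draws.mean(axis=1)
        emp = np.cov(np.vstack([b1, bbar]))
        v1, v2, v12 = reparameterize(cov2)
        assert v1 == pytest.approx(emp[0, 0], rel=0.01)
        assert v2 == pytest.approx(emp[1, 1], rel=0.01)
        assert v12 == pytest.approx(emp[0, 1], rel=0.01)


class TestLogistic:
    def test_saturated_closed_form(self, gwas_dataset):
        # on 3-cell grouped data the MLE is the log odds ratios Dd/dd, DD/Dd
        est = fit_logistic(encode(gwas_dataset.dosage), None, gwas_dataset.trait)
        assert est.converged
        assert est.beta1_hat == pytest.approx(math.log(508 * 219 / (541 * 163)), abs=1e-8)
        assert est.beta2_hat == pytest.approx(math.log(444 * 541 / (367 * 508)), abs=1e-8)

    def test_no_association_gives_zero_effects(self):
        ds = XDataset.from_grouped_counts((50, 100, 30), (50, 100, 30))
        est = fit_logistic(encode(ds.dosage), None, ds.trait)
        assert est.beta1_hat == pytest.approx(0.0, abs=1e-10)
        assert est.beta2_hat == pytest.approx(0.0, abs=1e-10)

    def test_mle_matches_direct_maximization(self):
        # independent oracle: generic optimizer on the Bernoulli log-likelihood
        rng = np.random.default_rng(11)
        dosage = rng.integers(0, 3, size=30)
        codes = encode(dosage)
        Z = rng.normal(size=(30, 1))
        eta = -0.2 + 0.5 * codes.X1 + 0.3 * codes.X2 + 0.4 * Z[:, 0]
        Y = (rng.random(30) < 1 / (1 + np.exp(-eta))).astype(float)
        D = np.column_stack([np.ones(30), codes.X1, codes.X2, Z])

        def negll(beta):
            lin = D @ beta
            return -np.sum(Y * lin - np.logaddexp(0.0, lin))

        res = optimize.minimize(negll, np.zeros(4), method="BFGS", tol=1e-12)
        est = fit_logistic(codes, Z, Y)
        fitted = [est.beta0_hat, est.beta1_hat, est.beta2_hat, est.b_hat[0]]
        assert fitted == pytest.approx(res.x, abs=1e-6)

    def test_matches_statsmodels_coefficients(self, replication_dataset):
        sm = pytest.importorskip("statsmodels.api")
        codes = encode(replication_dataset.dosage)
        D = np.column_stack([np.ones(replication_dataset.n), codes.X1, codes.X2])
        ref = sm.Logit(replication_dataset.trait, D).fit(disp=0)
        est = fit_logistic(codes, None, replication_dataset.trait)
        assert [est.beta0_hat, est.beta1_hat, est.beta2_hat] == pytest.approx(
            ref.params, abs=1e-6
        )

    def test_empirical_info_equals_modelbased_on_saturated_fit(self, gwas_dataset):
        # at the saturated MLE sum (y-p)^2 x x' equals sum p(1-p) x x' cellwise
        codes = encode(gwas_dataset.dosage)
        emp = fit_logistic(codes, None, gwas_dataset.trait, cov_type="empirical")
        obs = fit_logistic(codes, None, gwas_dataset.trait, cov_type="observed")
        assert emp.v1 == pytest.approx(obs.v1, rel=1e-6)
        assert emp.v2 == pytest.approx(obs.v2, rel=1e-6)

    def test_rank_deficiency_raises(self):
        codes = encode(np.array([1, 1, 1, 1]))  # X1 constant = intercept
        with pytest.raises(np.linalg.LinAlgError):
            fit_logistic(codes, None, np.array([0.0, 1.0, 0.0, 1.0]))


class TestLinear:
    def test_exact_interpolation(self):
        # noise-free Y = 1 + 0.3*(gamma*X1 + (2-gamma)*X2) with gamma = 0.8
        dosage = np.array([0, 1, 2, 0, 1, 2])
        codes = encode(dosage)
        Y = 1.0 + 0.3 * codes.genotypic_value(0.8)
        est = fit_linear(codes, None, Y)
        assert est.beta1_hat == pytest.approx(0.24, abs=1e-12)
        assert est.beta2_hat == pytest.approx(0.36, abs=1e-12)
        assert est.v1 == pytest.approx(0.0, abs=1e-20)

    def test_normal_equations_oracle(self):
        rng = np.random.default_rng(3)
        dosage = np.array([0, 0, 1, 1, 2, 2])
        codes = encode(dosage)
        Z = rng.normal(size=(6, 1))
        Y = rng.normal(size=6)
        D = np.column_stack([np.ones(6), codes.X1, codes.X2, Z])
        beta_ref = np.linalg.solve(D.T @ D, D.T @ Y)
        est = fit_linear(codes, Z, Y)
        fitted = [est.beta0_hat, est.beta1_hat, est.beta2_hat, est.b_hat[0]]
        assert fitted == pytest.approx(beta_ref, abs=1e-10)
        # dispersion-estimated covariance convention
        resid = Y - D @ beta_ref
        sigma2 = resid @ resid / 2  # n - p = 6 - 4
        cov_ref = sigma2 * np.linalg.inv(D.T @ D)
        v1_ref, _, _ = (cov_ref[1, 1], None, None)
        assert est.v1 == pytest.approx(v1_ref, rel=1e-10)

    def test_location_equivariance_and_order_invariance(self):
        rng = np.random.default_rng(5)
        dosage = rng.integers(0, 3, size=40)
        Y = rng.normal(size=40)
        codes = encode(dosage)
        a = fit_linear(codes, None, Y)
        b = fit_linear(codes, None, Y + 3.5)
        assert b.beta0_hat == pytest.approx(a.beta0_hat + 3.5)
        assert b.beta1_hat == pytest.approx(a.beta1_hat)
        perm = rng.permutation(40)
        c = fit_linear(encode(dosage[perm]), None, Y[perm])
        assert c.beta1_hat == pytest.approx(a.beta1_hat)
        assert c.v1 == pytest.approx(a.v1)

    def test_invariants(self):
        rng = np.random.default_rng(9)
        for _ in range(20):
            dosage = rng.integers(0, 3, size=25)
            if len(set(dosage)) < 3:
                continue
            est = fit_linear(encode(dosage), None, rng.normal(size=25))
            assert est.beta_hat == (est.beta1_hat + est.beta2_hat) / 2
            assert est.v1 >= 0 and est.v2 >= 0
            assert abs(est.v12) <= math.sqrt(est.v1 * est.v2) + 1e-12
            eig = np.linalg.eigvalsh(est.full_cov)
            assert eig.min() >= -1e-10
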