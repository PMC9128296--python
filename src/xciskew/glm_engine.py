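"""Working GLM fits and the reparameterized variance triple.

Both trait types are modelled through

    h(E[Y | G, Z]) = beta0 + beta1*X1 + beta2*X2 + b'Z

with the logit link for qualitative traits and the identity link for
quantitative traits.  Writing beta = (beta1 + beta2) / 2, the skewness
parameter is the ratio gamma = beta1 / beta, so every frequentist estimator
downstream consumes the triple

    v1  = Var(beta1_hat)
    v2  = Var(beta_hat)
    v12 = Cov(beta1_hat, beta_hat)

For qualitative traits the coefficient covariance is the inverse of the
*empirical* (outer-product-of-scores) Fisher information

    I_emp = sum_i (Y_i - p_i)^2 x_i x_i'

evaluated at the MLE; a ``cov_type="observed"`` switch selects the usual
model-based observed information for sensitivity checks.  For quantitative
traits the fit is OLS with the dispersion-estimated covariance
sigma2_hat * (D'D)^{-1}, sigma2_hat = RSS / (n - p), matching the default
Gaussian GLM convention.  The generative model for quantitative traits has
genotype-specific variances; the working fit deliberately ignores this
heteroscedasticity (a documented model/data mismatch of the method).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data_model import DesignCodes


@dataclass
class CoefEstimates:
    """Fitted coefficients and the (v1, v2, v12) variance triple.

    ``beta_hat`` is always exactly (beta1_hat + beta2_hat) / 2.  ``full_cov``
    is the covariance of (beta0, beta1, beta2, b) in that order.
    """

    beta0_hat: float
    beta1_hat: float
    beta2_hat: float
    b_hat: np.ndarray
    v1: float
    v2: float
    v12: float
    full_cov: np.ndarray
    converged: bool = True
    n_iter: int = 0

    @property
    def beta_hat(self) -> float:
        return 0.5 * (self.beta1_hat + self.beta2_hat)

    def to_dict(self) -> dict:
        return {
            "beta0_hat": self.beta0_hat,
            "beta1_hat": self.beta1_hat,
            "beta2_hat": self.beta2_hat,
            "beta_hat": self.beta_hat,
            "b_hat": list(np.atleast_1d(self.b_hat)),
            "v1": self.v1,
            "v2": self.v2,
            "v12": self.v12,
            "converged": self.converged,
            "n_iter": self.n_iter,
        }


def reparameterize(cov2: np.ndarray) -> tuple[float, float, float]:
    """Map the 2x2 covariance of (beta1_hat, beta2_hat) to (v1, v2, v12).

    Since beta_hat = (beta1_hat + beta2_hat) / 2, linearity of covariance
    gives v1 = Var(b1), v2 = (Var(b1) + Var(b2) + 2 Cov) / 4 and
    v12 = (Var(b1) + Cov) / 2.
    """
    cov2 = np.asarray(cov2, dtype=float)
    if cov2.shape != (2, 2):
        raise ValueError("expected a 2x2 covariance matrix")
    if not np.allclose(cov2, cov2.T, rtol=1e-8, atol=1e-12):
        raise ValueError("covariance matrix must be symmetric")
    v11, v22, c = cov2[0, 0], cov2[1, 1], cov2[0, 1]
    v1 = v11
    v2 = (v11 + v22 + 2.0 * c) / 4.0
    v12 = (v11 + c) / 2.0
    return float(v1), float(v2), float(v12)


def _design(codes: DesignCodes, Z: np.ndarray | None) -> np.ndarray:
    n = codes.X1.shape[0]
    Z = np.empty((n, 0)) if Z is None else np.atleast_2d(np.asarray(Z, dtype=float))
    if Z.shape[0] != n:
        raise ValueError("covariate rows do not match design length")
    return np.column_stack([np.ones(n), codes.X1, codes.X2, Z])


def _check_rank(D: np.ndarray) -> None:
    if np.linalg.matrix_rank(D) < D.shape[1]:
        raise np.linalg.LinAlgError("design matrix is rank deficient")


def _finalize(beta: np.ndarray, cov: np.ndarray, converged: bool, n_iter: int) -> CoefEstimates:
    v1, v2, v12 = reparameterize(cov[1:3, 1:3])
    return CoefEstimates(
        beta0_hat=float(beta[0]),
        beta1_hat=float(beta[1]),
        beta2_hat=float(beta[2]),
        b_hat=np.asarray(beta[3:], dtype=float),
        v1=v1,
        v2=v2,
        v12=v12,
        full_cov=cov,
        converged=converged,
        n_iter=n_iter,
    )


def fit_logistic(
    codes: DesignCodes,
    Z: np.ndarray | None,
    Y: np.ndarray,
    cov_type: str = "empirical",
    tol: float = 1e-10,
    max_iter: int = 100,
) -> CoefEstimates:
    """Logistic MLE by iteratively reweighted least squares.

    ``cov_type="empirical"`` (default) inverts the outer-product-of-scores
    information sum_i (Y_i - p_i)^2 x_i x_i'; ``"observed"`` inverts the
    model-based information sum_i p_i (1 - p_i) x_i x_i'.  Non-convergence
    (e.g. separation) is reported through ``converged=False`` rather than an
    exception so replicate studies can record and skip the fit.
    """
    if cov_type not in ("empirical", "observed"):
        raise ValueError("cov_type must be 'empirical' or 'observed'")
    Y = np.asarray(Y, dtype=float)
    if not np.isin(Y, (0.0, 1.0)).all():
        raise ValueError("qualitative trait values must be 0 or 1")
    D = _design(codes, Z)
    _check_rank(D)

    beta = np.zeros(D.shape[1])
    ll_old = -np.inf
    converged = False
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        eta = D @ beta
        p = 1.0 / (1.0 + np.exp(-eta))
        w = np.clip(p * (1.0 - p), 1e-12, None)
        grad = D.T @ (Y - p)
        info = (D * w[:, None]).T @ D
        try:
            step = np.linalg.solve(info, grad)
        except np.linalg.LinAlgError:
            break
        beta = beta + step
        eta = D @ beta
        ll = float(np.sum(Y * eta - np.logaddexp(0.0, eta)))
        if abs(ll - ll_old) < tol * (abs(ll_old) + 1.0):
            converged = True
            break
        ll_old = ll

    eta = D @ beta
    p = 1.0 / (1.0 + np.exp(-eta))
    if cov_type == "empirical":
        info = (D * ((Y - p) ** 2)[:, None]).T @ D
    else:
        w = np.clip(p * (1.0 - p), 1e-12, None)
        info = (D * w[:, None]).T @ D
    cov = np.linalg.pinv(info)
    cov = 0.5 * (cov + cov.T)
    return _finalize(beta, cov, converged, n_iter)


def fit_linear(codes: DesignCodes, Z: np.ndarray | None, Y: np.ndarray) -> CoefEstimates:
    """Ordinary least squares with homoscedastic model-based covariance."""
    Y = np.asarray(Y, dtype=float)
    D = _design(codes, Z)
    _check_rank(D)
    n, p = D.shape
    if n <= p:
        raise ValueError("no residual degrees of freedom")
    beta, _, _, _ = np.linalg.lstsq(D, Y, rcond=None)
    resid = Y - D @ beta
    sigma2 = float(resid @ resid) / (n - p)
    cov = sigma2 * np.linalg.inv(D.T @ D)
    cov = 0.5 * (cov + cov.T)
    return _finalize(beta, cov, True, 1)
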