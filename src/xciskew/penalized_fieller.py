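"""Penalized Fieller estimator: bounded intervals for the XCI skewness.

When the denominator beta_hat of the ratio gamma = beta1 / beta is not
significantly different from zero, the plain ratio explodes and the Fieller
set is unbounded before truncation.  The penalized variant maximizes

    pl(beta) = -(beta_hat - beta)^2 / (2 v2) + lambda * log|beta|

whose maximizer has the closed form

    beta* = beta_hat / 2 + sign(beta_hat) sqrt(beta_hat^2 / 4 + lambda v2),

shrinking the denominator away from zero.  The numerator is corrected for
the induced bias via beta1* = beta1_hat + gamma_tilde (beta* - beta_hat)
with gamma_tilde = beta1_hat / beta*.  First-order Taylor expansion (the
O(n^-3) remainders are dropped) gives the starred variance triple

    v2*  = omega^2 v2,                      omega = beta* / (2 beta* - beta_hat)
    v1*  = omega^-2 v1 - 4 (omega^-1 - 1) gamma_tilde v12
           + 4 (1 - omega)^2 gamma_tilde^2 v2
    v12* = v12 - 2 omega (1 - omega) gamma_tilde v2

and the confidence set is the Fieller quadratic with the starred quantities
substituted.  With lambda >= z^2 / 4 the interval is always bounded; the
default lambda = z^2_{1-alpha/2} / 4 (~0.9604 at alpha = 0.05) keeps the
interval bounded while controlling coverage, and the same lambda is used for
the point estimate so point and interval are mutually consistent.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from scipy import stats

from .fieller import GammaEstimate, GammaInterval, _interval_from_quadratic, _truncated_ratio
from .glm_engine import CoefEstimates


@dataclass
class PenalizedQuantities:
    """The starred (penalized) coefficient and variance quantities."""

    lam: float
    beta_star: float
    omega: float
    gamma_tilde: float
    beta1_star: float
    v1_star: float
    v2_star: float
    v12_star: float


def default_lambda(alpha: float = 0.05) -> float:
    """The bounded-interval penalty lambda = z^2_{1-alpha/2} / 4."""
    z = stats.norm.ppf(1.0 - alpha / 2.0)
    return z * z / 4.0


def penalize(est: CoefEstimates, lam: float | None = None, alpha: float = 0.05) -> PenalizedQuantities:
    """Compute the starred quantities for penalty ``lam`` (default z^2/4).

    sign(0) is taken as +1 so that beta_hat = 0 still yields the nonzero
    penalized denominator +sqrt(lambda v2), keeping the estimator defined
    everywhere.
    """
    if lam is None:
        lam = default_lambda(alpha)
    if lam < 0:
        raise ValueError("lambda must be nonnegative")
    beta = est.beta_hat
    beta1 = est.beta1_hat
    v1, v2, v12 = est.v1, est.v2, est.v12
    if v2 <= 0 and lam > 0:
        raise ValueError("v2 must be positive for a nonzero penalty")

    sign = 1.0 if beta >= 0 else -1.0
    beta_star = beta / 2.0 + sign * math.sqrt(beta * beta / 4.0 + lam * v2)
    if lam == 0.0:
        # zero-penalty identity: everything collapses to the unstarred inputs
        return PenalizedQuantities(0.0, beta, 1.0, (beta1 / beta) if beta != 0 else math.nan,
                                   beta1, v1, v2, v12)

    omega = beta_star / (2.0 * beta_star - beta)
    gamma_tilde = beta1 / beta_star
    beta1_star = beta1 + gamma_tilde * (beta_star - beta)
    v2_star = omega * omega * v2
    v1_star = (
        v1 / (omega * omega)
        - 4.0 * (1.0 / omega - 1.0) * gamma_tilde * v12
        + 4.0 * (1.0 - omega) ** 2 * gamma_tilde**2 * v2
    )
    v12_star = v12 - 2.0 * omega * (1.0 - omega) * gamma_tilde * v2
    return PenalizedQuantities(lam, beta_star, omega, gamma_tilde, beta1_star,
                               v1_star, v2_star, v12_star)


def gamma_point_pf(pen: PenalizedQuantities) -> GammaEstimate:
    """Penalized point estimate gamma_PF = beta1* / beta* ^ [0, 2]."""
    return _truncated_ratio(pen.beta1_star, pen.beta_star, "PF")


def pf_interval(pen: PenalizedQuantities, alpha: float = 0.05) -> GammaInterval:
    """Penalized Fieller confidence set: the Fieller quadratic on starred inputs."""
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must lie in (0, 1)")
    return _interval_from_quadratic(
        pen.beta1_star, pen.beta_star, pen.v1_star, pen.v2_star, pen.v12_star, alpha, "PF"
    )


def estimate_pf(
    est: CoefEstimates, alpha: float = 0.05, lam: float | None = None
) -> tuple[GammaEstimate, GammaInterval]:
    """Convenience: penalize once, return the PF point estimate and interval."""
    pen = penalize(est, lam=lam, alpha=alpha)
    return gamma_point_pf(pen), pf_interval(pen, alpha)
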