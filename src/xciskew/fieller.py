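"""Fieller's ratio estimate and confidence set for the XCI skewness gamma.

The point estimate is the ratio of regression coefficients

    gamma_origin = beta1_hat / beta_hat = 2 beta1_hat / (beta1_hat + beta2_hat)

truncated into [0, 2].  The confidence set inverts the Wald test of
H0: gamma = g, i.e. |beta1_hat - g beta_hat| / sqrt(v1 + g^2 v2 - 2 g v12)
< z, which rearranges to the quadratic A g^2 + B g + C <= 0 with

    A = beta_hat^2 - z^2 v2
    B = 2 (z^2 v12 - beta1_hat beta_hat)
    C = beta1_hat^2 - z^2 v1

and discriminant Delta = B^2 - 4AC.  Before truncation the solution set is
an interval (A > 0), the complement of an interval (A < 0, Delta > 0), the
whole line (A < 0, Delta < 0) or — in the degenerate tangency cases A = 0 or
Delta = 0 — treated as the empty set.  After intersecting with [0, 2] the
result is classified as informative, noninformative (exactly [0, 2]),
empty, or discontinuous (two disjoint pieces).

Endpoint convention: analytic roots are open endpoints, truncation
boundaries 0 and 2 are closed, matching the printed style "[0, 1.6579)".
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from scipy import stats

from .glm_engine import CoefEstimates


@dataclass(frozen=True)
class Piece:
    """One sub-interval of [0, 2] with endpoint openness flags."""

    lo: float
    hi: float
    lo_closed: bool
    hi_closed: bool

    @property
    def width(self) -> float:
        return self.hi - self.lo

    def contains(self, x: float) -> bool:
        if self.lo < x < self.hi:
            return True
        if x == self.lo and self.lo_closed:
            return True
        if x == self.hi and self.hi_closed:
            return True
        return False

    def __str__(self) -> str:
        left = "[" if self.lo_closed else "("
        right = "]" if self.hi_closed else ")"
        return f"{left}{self.lo:.4f}, {self.hi:.4f}{right}"


@dataclass
class GammaInterval:
    """A confidence/credible set for gamma: a subset of [0, 2].

    ``pieces`` holds 0, 1 or 2 disjoint sub-intervals; ``kind`` classifies
    the outcome; ``raw_bounds`` carries the untruncated quadratic roots when
    they exist; ``case`` records which branch of the case analysis applied.
    """

    pieces: list[Piece]
    kind: str  # informative | noninformative | empty | discontinuous
    raw_bounds: tuple[float, float] | None = None
    case: str = ""
    alpha: float = 0.05
    method: str = "F"

    @property
    def width(self) -> float:
        """Total length of the set (sum over pieces; empty -> 0)."""
        return sum(p.width for p in self.pieces)

    def contains(self, x: float) -> bool:
        return any(p.contains(x) for p in self.pieces)

    def to_dict(self) -> dict:
        return {
            "method": self.method,
            "alpha": self.alpha,
            "kind": self.kind,
            "case": self.case,
            "pieces": [
                {"lo": p.lo, "hi": p.hi, "lo_closed": p.lo_closed, "hi_closed": p.hi_closed}
                for p in self.pieces
            ],
            "raw_bounds": list(self.raw_bounds) if self.raw_bounds else None,
            "width": self.width,
        }

    def __str__(self) -> str:
        if not self.pieces:
            return "(empty set)"
        return " U ".join(str(p) for p in self.pieces)


@dataclass
class GammaEstimate:
    """Point estimate of gamma with its untruncated value.

    ``raw`` may lie outside [0, 2] or be +/-inf (sign-preserving when the
    denominator is exactly zero); ``gamma_hat`` is the truncation of ``raw``
    into [0, 2].  When beta1_hat = beta2_hat = 0 exactly the ratio is
    undefined and both fields are NaN with ``defined=False``.
    """

    gamma_hat: float
    raw: float
    truncated: bool
    method: str
    defined: bool = True

    def to_dict(self) -> dict:
        return {
            "method": self.method,
            "gamma_hat": self.gamma_hat,
            "raw": self.raw,
            "truncated": self.truncated,
            "defined": self.defined,
        }


def _truncated_ratio(num: float, den: float, method: str) -> GammaEstimate:
    if num == 0.0 and den == 0.0:
        return GammaEstimate(math.nan, math.nan, False, method, defined=False)
    if den == 0.0:
        raw = math.inf if num > 0 else -math.inf
    else:
        raw = num / den
    gamma_hat = min(2.0, max(0.0, raw))
    return GammaEstimate(gamma_hat, raw, not (0.0 <= raw <= 2.0), method)


def gamma_point_fieller(est: CoefEstimates) -> GammaEstimate:
    """Truncated ratio point estimate gamma_F = 2 b1 / (b1 + b2) ^ [0, 2]."""
    return _truncated_ratio(est.beta1_hat, est.beta_hat, "F")


def _clip_open_interval(lo: float, hi: float) -> Piece | None:
    """Intersect the open analytic interval (lo, hi) with [0, 2]."""
    new_lo, lo_closed = (0.0, True) if lo < 0.0 else (lo, False)
    new_hi, hi_closed = (2.0, True) if hi > 2.0 else (hi, False)
    if new_lo > new_hi:
        return None
    if new_lo == new_hi and not (lo_closed and hi_closed):
        return None
    return Piece(new_lo, new_hi, lo_closed, hi_closed)


def _classify(pieces: list[Piece]) -> str:
    if not pieces:
        return "empty"
    if len(pieces) == 2:
        return "discontinuous"
    p = pieces[0]
    if p.lo == 0.0 and p.hi == 2.0 and p.lo_closed and p.hi_closed:
        return "noninformative"
    return "informative"


def fieller_quadratic(
    beta1: float, beta: float, v1: float, v2: float, v12: float, alpha: float
) -> tuple[float, float, float, float]:
    """Coefficients (A, B, C) and discriminant Delta of the Fieller quadratic."""
    z2 = stats.norm.ppf(1.0 - alpha / 2.0) ** 2
    A = beta * beta - z2 * v2
    B = 2.0 * (z2 * v12 - beta1 * beta)
    C = beta1 * beta1 - z2 * v1
    return A, B, C, B * B - 4.0 * A * C


def _interval_from_quadratic(
    beta1: float,
    beta: float,
    v1: float,
    v2: float,
    v12: float,
    alpha: float,
    method: str,
) -> GammaInterval:
    A, B, C, delta = fieller_quadratic(beta1, beta, v1, v2, v12, alpha)

    if A == 0.0 or delta == 0.0:
        return GammaInterval([], "empty", None, "degenerate", alpha, method)

    if A > 0.0:
        # the method's own implication: a significant denominator forces Delta > 0
        assert delta > 0.0, "A > 0 must imply Delta > 0"
        sq = math.sqrt(delta)
        lo, hi = sorted(((-B - sq) / (2 * A), (-B + sq) / (2 * A)))
        piece = _clip_open_interval(lo, hi)
        pieces = [piece] if piece is not None else []
        return GammaInterval(pieces, _classify(pieces), (lo, hi), "Apos", alpha, method)

    if delta > 0.0:  # A < 0: complement of an interval
        sq = math.sqrt(delta)
        lo, hi = sorted(((-B - sq) / (2 * A), (-B + sq) / (2 * A)))
        pieces = []
        left = _clip_open_interval(-math.inf, lo)
        right = _clip_open_interval(hi, math.inf)
        pieces = [p for p in (left, right) if p is not None]
        return GammaInterval(pieces, _classify(pieces), (lo, hi), "Aneg_DeltaPos", alpha, method)

    # A < 0 and Delta < 0: the Wald statistic never reaches z anywhere
    pieces = [Piece(0.0, 2.0, True, True)]
    return GammaInterval(pieces, "noninformative", None, "Aneg_DeltaNeg", alpha, method)


def fieller_interval(est: CoefEstimates, alpha: float = 0.05) -> GammaInterval:
    """Fieller confidence set at level 1 - alpha, truncated into [0, 2]."""
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must lie in (0, 1)")
    if est.v1 < 0 or est.v2 < 0:
        raise ValueError("variances must be nonnegative")
    return _interval_from_quadratic(
        est.beta1_hat, est.beta_hat, est.v1, est.v2, est.v12, alpha, "F"
    )


def interpret_gamma(g: GammaEstimate | GammaInterval) -> dict:
    """Translate an estimate or interval into an XCI pattern call.

    gamma in [0, 1) means inactivation skewed towards the risk allele D
    (fewer cells express D), gamma = 1 random inactivation, gamma in (1, 2]
    skew towards the normal allele d.  gamma / 2 is the proportion of cells
    with D active.  An interval supports an XCI-S call only when it excludes
    1; an interval containing 1 is compatible with XCI-R or escape.
    """
    if isinstance(g, GammaInterval):
        if g.kind == "empty":
            return {"call": "no information", "pattern": None}
        if g.contains(1.0):
            return {"call": "XCI-R or XCI-E", "pattern": "random-or-escape"}
        lo_side = all(p.hi < 1.0 for p in g.pieces)
        pattern = "XCI-S towards D" if lo_side else "XCI-S towards d"
        return {"call": "XCI-S", "pattern": pattern}
    if not g.defined or math.isnan(g.gamma_hat):
        return {"call": "no information", "pattern": None}
    gamma = g.gamma_hat
    if gamma < 1.0:
        pattern = "XCI-S towards D"
    elif gamma > 1.0:
        pattern = "XCI-S towards d"
    else:
        pattern = "XCI-R"
    return {
        "call": pattern,
        "pattern": pattern,
        "prop_cells_D_active": gamma / 2.0,
    }
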