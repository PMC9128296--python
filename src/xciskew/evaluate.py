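"""Summary metrics for replicate studies.

For each estimation method a replicate study yields K point estimates and K
interval estimates against known truths.  The summaries are:

* MSE = sum_k (gamma_hat_k - gamma_k)^2 / K over the truncated estimates;
* the percentages of extreme point estimates exactly 0 or exactly 2
  (truncation produces exact boundary values, so equality needs no epsilon);
* coverage probability CP: percent of replicates whose interval (union of
  pieces for a discontinuous set) contains the truth — an empty set never
  covers;
* the mean, median, SD and IQR of the interval widths, where the width of a
  discontinuous set is the sum of its piece lengths, a noninformative
  interval has width 2 and an empty set width 0 (empty sets are included at
  width 0 by default; ``drop_empty`` excludes them);
* NP / EP / DP: percentages of noninformative, empty and discontinuous
  outcomes.  Bayesian HPDIs are structurally single nonempty intervals
  inside [0, 2], so their NP, EP and DP are 0 by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from typing import Sequence

import numpy as np

from .fieller import GammaEstimate, GammaInterval


@dataclass
class MethodSummary:
    """All reported summaries for one method in one scenario."""

    method: str
    mse: float
    prop_extreme_0: float
    prop_extreme_2: float
    prop_extreme_total: float
    cp: float
    w_mean: float
    w_median: float
    w_sd: float
    w_iqr: float
    np_pct: float
    ep_pct: float
    dp_pct: float

    def to_dict(self) -> dict:
        return asdict(self)


def mse(estimates: np.ndarray, truths: np.ndarray) -> float:
    """Mean squared error of point estimates against truths."""
    estimates = np.asarray(estimates, dtype=float)
    truths = np.asarray(truths, dtype=float)
    if estimates.shape != truths.shape:
        raise ValueError("estimates and truths must have equal length")
    if estimates.size == 0:
        raise ValueError("need at least one replicate")
    return float(np.mean((estimates - truths) ** 2))


def extreme_proportions(estimates: Sequence[GammaEstimate]) -> tuple[float, float, float]:
    """Percentages of truncated point estimates exactly 0, exactly 2, and total."""
    if not estimates:
        raise ValueError("need at least one estimate")
    vals = np.array([e.gamma_hat for e in estimates], dtype=float)
    p0 = 100.0 * float(np.mean(vals == 0.0))
    p2 = 100.0 * float(np.mean(vals == 2.0))
    return p0, p2, p0 + p2


def interval_metrics(
    intervals: Sequence[GammaInterval],
    truths: np.ndarray,
    drop_empty: bool = False,
) -> dict:
    """Coverage, width statistics and outcome-type percentages."""
    truths = np.asarray(truths, dtype=float)
    if len(intervals) != truths.size or not len(intervals):
        raise ValueError("intervals and truths must have equal, nonzero length")
    covered = np.array([iv.contains(t) for iv, t in zip(intervals, truths)])
    widths = np.array([iv.width for iv in intervals], dtype=float)
    kinds = np.array([iv.kind for iv in intervals])
    if drop_empty:
        widths = widths[kinds != "empty"]
    if widths.size == 0:
        widths = np.array([0.0])
    k = len(intervals)
    return {
        "cp": 100.0 * float(np.mean(covered)),
        "w_mean": float(np.mean(widths)),
        "w_median": float(np.median(widths)),
        "w_sd": float(np.std(widths, ddof=1)) if widths.size > 1 else 0.0,
        "w_iqr": float(np.subtract(*np.percentile(widths, [75, 25]))),
        "np_pct": 100.0 * float(np.sum(kinds == "noninformative")) / k,
        "ep_pct": 100.0 * float(np.sum(kinds == "empty")) / k,
        "dp_pct": 100.0 * float(np.sum(kinds == "discontinuous")) / k,
    }


def summarize(results, drop_empty: bool = False) -> list[MethodSummary]:
    """Build one MethodSummary per method from a ReplicateResults object."""
    out = []
    for method in results.methods:
        ests = results.estimates[method]
        ok = [k for k, e in enumerate(ests) if e.defined and np.isfinite(e.gamma_hat)]
        vals = np.array([ests[k].gamma_hat for k in ok])
        truths = results.gamma_true[ok]
        p0, p2, ptot = extreme_proportions([ests[k] for k in ok])
        ivs = [results.intervals[method][k] for k in ok]
        im = interval_metrics(ivs, truths, drop_empty=drop_empty)
        out.append(
            MethodSummary(
                method=method,
                mse=mse(vals, truths),
                prop_extreme_0=p0,
                prop_extreme_2=p2,
                prop_extreme_total=ptot,
                cp=im["cp"],
                w_mean=im["w_mean"],
                w_median=im["w_median"],
                w_sd=im["w_sd"],
                w_iqr=im["w_iqr"],
                np_pct=im["np_pct"],
                ep_pct=im["ep_pct"],
                dp_pct=im["dp_pct"],
            )
        )
    return out


def summary_frame(summaries: Sequence[MethodSummary]):
    """Tidy one-row-per-method table mirroring the reference table layout."""
    import pandas as pd

    return pd.DataFrame([s.to_dict() for s in summaries])
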