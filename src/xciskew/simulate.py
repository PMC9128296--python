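"""Simulation designs for the XCI-skewness estimators and replicate studies.

Female genotype frequencies at the SNP follow

    (g0, g1, g2) = (q^2 + rho*p*q, 2(1 - rho)*p*q, p^2 + rho*p*q)

where p is the risk-allele (usually minor-allele) frequency, q = 1 - p and
rho is the inbreeding coefficient (rho = 0 is Hardy-Weinberg equilibrium).

Qualitative design (case-control, 1:1): the DD-vs-dd odds ratio is fixed at
lambda2 (default 2), so beta = log(lambda2) / 2 and the heterozygote odds
ratio is lambda1 = lambda2^(gamma/2).  Bayes' rule gives the case genotype
probabilities c_j proportional to (g0, g1*lambda1, g2*lambda2); the common
factor exp(beta0) = 1 / (g0 + g1*lambda1 + g2*lambda2) normalizes them.
Case and control genotype counts are trinomial draws of n/2 each.

Quantitative design: genotype counts are one trinomial draw of size n from
(g0, g1, g2) and the trait is Normal(beta0 + beta*gamma*X1 + beta*(2-gamma)*X2,
sigma^2_genotype) with beta0 = 0, beta = 0.3 and variance triples
(1, 1.2, 1) or (4, 4.8, 4) by default.

A replicate study draws gamma_true ~ U(0, 2) per replicate (or keeps it
fixed), simulates a dataset, fits the working GLM and computes the requested
estimators; 500 replicates per scenario is the reference design.  Everything
is deterministic under the configured seed (per-replicate substreams are
spawned from it).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .bayes import PriorSpec, SamplerConfig, hpdi, posterior_mode, sample_posterior
from .data_model import XDataset, encode
from .fieller import GammaEstimate, GammaInterval, Piece, fieller_interval, gamma_point_fieller
from .glm_engine import fit_linear, fit_logistic
from .penalized_fieller import gamma_point_pf, penalize, pf_interval

ALL_METHODS = ("F", "PF", "BN", "BU")


@dataclass
class SimConfig:
    """One simulation scenario.

    ``gamma`` is a fixed value in [0, 2] or the string "random" for the
    stochastic-gamma design (one U(0, 2) draw per replicate).
    """

    trait_type: str = "qualitative"
    n: int = 500
    maf: float = 0.3
    rho: float = 0.0
    lambda2: float = 2.0
    beta0: float = 0.0
    beta: float = 0.3
    sigma2: tuple[float, float, float] = (1.0, 1.2, 1.0)
    gamma: float | str = "random"
    replicates: int = 500
    seed: int = 0
    alpha: float = 0.05

    def __post_init__(self) -> None:
        genotype_freqs(self.maf, self.rho)  # validates (maf, rho)
        if self.trait_type == "qualitative" and self.n % 2:
            raise ValueError("qualitative design requires even n (1:1 case-control)")
        if isinstance(self.gamma, str) and self.gamma != "random":
            raise ValueError("gamma must be a number or 'random'")
        if not isinstance(self.gamma, str) and not 0.0 <= float(self.gamma) <= 2.0:
            raise ValueError("fixed gamma must lie in [0, 2]")
        if any(s < 0 for s in self.sigma2):
            raise ValueError("variances must be nonnegative")

    def to_dict(self) -> dict:
        return {
            "trait_type": self.trait_type,
            "n": self.n,
            "maf": self.maf,
            "rho": self.rho,
            "lambda2": self.lambda2,
            "beta0": self.beta0,
            "beta": self.beta,
            "sigma2": list(self.sigma2),
            "gamma": self.gamma,
            "replicates": self.replicates,
            "seed": self.seed,
            "alpha": self.alpha,
        }


def genotype_freqs(p: float, rho: float) -> tuple[float, float, float]:
    """Female genotype frequencies (dd, Dd, DD) under inbreeding rho."""
    if not 0.0 < p < 1.0:
        raise ValueError("allele frequency must lie in (0, 1)")
    q = 1.0 - p
    g = (q * q + rho * p * q, 2.0 * (1.0 - rho) * p * q, p * p + rho * p * q)
    if min(g) < 0.0:
        raise ValueError(f"rho={rho} gives a negative genotype frequency at p={p}")
    return g


def case_probabilities(
    p: float, rho: float, gamma: float, lambda2: float
) -> tuple[tuple[float, float, float], float]:
    """Case genotype probabilities (c0, c1, c2) and the intercept beta0."""
    g = genotype_freqs(p, rho)
    lambda1 = lambda2 ** (gamma / 2.0)
    denom = g[0] + g[1] * lambda1 + g[2] * lambda2
    eb0 = 1.0 / denom
    c = (g[0] * eb0, g[1] * lambda1 * eb0, g[2] * lambda2 * eb0)
    return c, float(np.log(eb0))


def _dataset_from_counts(case_counts, ctrl_counts) -> XDataset:
    return XDataset.from_grouped_counts(tuple(case_counts), tuple(ctrl_counts))


def simulate_qualitative(
    cfg: SimConfig, gamma_true: float, rng: np.random.Generator
) -> XDataset:
    """Draw a 1:1 case-control dataset under the logistic genotype model."""
    if cfg.n % 2:
        raise ValueError("qualitative design requires even n")
    g = genotype_freqs(cfg.maf, cfg.rho)
    c, _ = case_probabilities(cfg.maf, cfg.rho, gamma_true, cfg.lambda2)
    half = cfg.n // 2
    case_counts = rng.multinomial(half, c)
    ctrl_counts = rng.multinomial(half, g)
    return _dataset_from_counts(case_counts, ctrl_counts)


def simulate_quantitative(
    cfg: SimConfig, gamma_true: float, rng: np.random.Generator
) -> XDataset:
    """Draw a quantitative-trait dataset with genotype-specific variances."""
    g = genotype_freqs(cfg.maf, cfg.rho)
    counts = rng.multinomial(cfg.n, g)
    dosage = np.repeat([0, 1, 2], counts)
    means = np.array(
        [cfg.beta0, cfg.beta0 + cfg.beta * gamma_true, cfg.beta0 + 2.0 * cfg.beta]
    )
    sds = np.sqrt(np.asarray(cfg.sigma2, dtype=float))
    Y = rng.normal(means[dosage], sds[dosage])
    return XDataset(
        subject_id=np.arange(cfg.n),
        dosage=dosage,
        trait=Y,
        covariates=np.empty((cfg.n, 0)),
        trait_type="quantitative",
    )


def simulate_dataset(cfg: SimConfig, gamma_true: float, rng: np.random.Generator) -> XDataset:
    if cfg.trait_type == "qualitative":
        return simulate_qualitative(cfg, gamma_true, rng)
    return simulate_quantitative(cfg, gamma_true, rng)


def _hpdi_interval(lo: float, hi: float, alpha: float, method: str) -> GammaInterval:
    piece = Piece(lo, hi, True, True)
    return GammaInterval([piece], "informative", None, "hpdi", alpha, method)


@dataclass
class ReplicateResults:
    """Per-replicate truths, point estimates and interval estimates."""

    config: SimConfig
    gamma_true: np.ndarray
    estimates: dict[str, list[GammaEstimate]]
    intervals: dict[str, list[GammaInterval]]
    failures: list[dict] = field(default_factory=list)

    @property
    def methods(self) -> list[str]:
        return list(self.estimates)

    def to_frame(self):
        import pandas as pd

        rows = []
        for method in self.methods:
            for k, (est, iv) in enumerate(zip(self.estimates[method], self.intervals[method])):
                rows.append(
                    {
                        "replicate": k,
                        "method": method,
                        "gamma_true": self.gamma_true[k],
                        "gamma_hat": est.gamma_hat,
                        "raw": est.raw,
                        "truncated": est.truncated,
                        "kind": iv.kind,
                        "width": iv.width,
                        "covered": iv.contains(self.gamma_true[k]),
                        "interval": str(iv),
                    }
                )
        return pd.DataFrame(rows)


def run_replicates(
    cfg: SimConfig,
    methods: Sequence[str] = ("F", "PF"),
    sampler_cfg: SamplerConfig | None = None,
    covariate_hook: Callable[[XDataset, np.random.Generator], XDataset] | None = None,
) -> ReplicateResults:
    """Run the replicate study for one scenario.

    Frequentist estimators (F, PF) are always cheap; BN/BU run the HMC
    sampler per replicate and default to the reduced profile.  Per-replicate
    fit failures are recorded in ``failures`` rather than raised.  A
    ``covariate_hook`` may append covariates to each simulated dataset.
    """
    unknown = set(methods) - set(ALL_METHODS)
    if unknown:
        raise ValueError(f"unknown methods: {sorted(unknown)}")
    need_bayes = [m for m in methods if m in ("BN", "BU")]

    root = np.random.SeedSequence(cfg.seed)
    rep_seeds = root.spawn(cfg.replicates)
    gamma_true = np.empty(cfg.replicates)
    estimates: dict[str, list[GammaEstimate]] = {m: [] for m in methods}
    intervals: dict[str, list[GammaInterval]] = {m: [] for m in methods}
    failures: list[dict] = []

    for k, ss in enumerate(rep_seeds):
        rng = np.random.default_rng(ss)
        g_true = float(rng.uniform(0.0, 2.0)) if cfg.gamma == "random" else float(cfg.gamma)
        gamma_true[k] = g_true
        data = simulate_dataset(cfg, g_true, rng)
        if covariate_hook is not None:
            data = covariate_hook(data, rng)
        codes = encode(data.dosage)
        Z = data.covariates if data.n_covariates else None

        try:
            if cfg.trait_type == "qualitative":
                est = fit_logistic(codes, Z, data.trait)
            else:
                est = fit_linear(codes, Z, data.trait)
        except Exception as exc:  # noqa: BLE001 - recorded, not fatal
            failures.append({"replicate": k, "stage": "fit", "error": str(exc)})
            for m in methods:
                estimates[m].append(GammaEstimate(np.nan, np.nan, False, m, defined=False))
                intervals[m].append(GammaInterval([], "empty", None, "fit_failure", cfg.alpha, m))
            continue

        if "F" in methods:
            estimates["F"].append(gamma_point_fieller(est))
            intervals["F"].append(fieller_interval(est, cfg.alpha))
        if "PF" in methods:
            pen = penalize(est, alpha=cfg.alpha)
            estimates["PF"].append(gamma_point_pf(pen))
            intervals["PF"].append(pf_interval(pen, cfg.alpha))

        for m in need_bayes:
            prior = PriorSpec(gamma_prior="normal" if m == "BN" else "uniform")
            scfg = sampler_cfg or SamplerConfig.reduced()
            # derive the per-replicate sampler seed from the replicate stream
            scfg = SamplerConfig(
                chains=scfg.chains,
                iterations=scfg.iterations,
                warmup=scfg.warmup,
                target_accept=scfg.target_accept,
                seed=int(rng.integers(0, 2**31 - 1)),
                rhat_threshold=scfg.rhat_threshold,
                max_leapfrog=scfg.max_leapfrog,
            )
            try:
                import warnings

                with warnings.catch_warnings():
                    warnings.simplefilter("ignore", RuntimeWarning)
                    samples = sample_posterior(data, prior, scfg)
                g = samples.gamma
                mode = posterior_mode(g)
                lo, hi = hpdi(g, 1.0 - cfg.alpha)
                estimates[m].append(GammaEstimate(mode, mode, False, m))
                intervals[m].append(_hpdi_interval(lo, hi, cfg.alpha, m))
            except Exception as exc:  # noqa: BLE001
                failures.append({"replicate": k, "stage": m, "error": str(exc)})
                estimates[m].append(GammaEstimate(np.nan, np.nan, False, m, defined=False))
                intervals[m].append(GammaInterval([], "empty", None, "fit_failure", cfg.alpha, m))

    return ReplicateResults(cfg, gamma_true, estimates, intervals, failures)
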