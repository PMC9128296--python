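import math

import numpy as np
import pytest
from scipy import stats

from xciskew.bayes import (
    PriorSpec,
    SamplerConfig,
    hpdi,
    log_posterior,
    posterior_mode,
    rhat,
    sample_posterior,
)
from xciskew.data_model import XDataset
from xciskew.simulate import SimConfig, simulate_quantitative


def _empty_dataset(trait_type="qualitative"):
    return XDataset(
        subject_id=np.array([]),
        dosage=np.array([], dtype=int),
        trait=np.array([]),
        covariates=np.empty((0, 0)),
        trait_type=trait_type,
    )


class TestLogPosterior:
    def test_outside_support_is_minus_inf(self):
        ds = _empty_dataset()
        pr = PriorSpec(gamma_prior="uniform")
        assert log_posterior({"beta0": 0, "beta": 0, "gamma": 2.5}, ds, pr) == -math.inf

    def test_prior_only_normal_mode_at_one(self):
        # with no data the density over gamma is the prior: N(1,1) truncated
        ds = _empty_dataset()
        pr = PriorSpec(gamma_prior="normal")
        grid = np.linspace(0.01, 1.99, 199)
        vals = [log_posterior({"beta0": 0, "beta": 0, "gamma": g}, ds, pr) for g in grid]
        assert grid[int(np.argmax(vals))] == pytest.approx(1.0, abs=0.011)

    def test_gamma_irrelevant_for_dd_only_subject(self):
        # a dd subject contributes no gamma information (X1 = X2 = 0)
        ds = XDataset(
            subject_id=[0], dosage=[0], trait=[1.0],
            covariates=np.empty((1, 0)), trait_type="qualitative",
        )
        pr = PriorSpec(gamma_prior="uniform")
        base = {"beta0": 0.3, "beta": 0.5}
        diffs = {
            g: log_posterior({**base, "gamma": g}, ds, pr) for g in (0.2, 1.0, 1.8)
        }
        assert len({round(v, 12) for v in diffs.values()}) == 1

    def test_matches_naive_term_by_term_sum(self):
        # 20-subject oracle: independent summation of every likelihood and
        # prior term in long double precision
        rng = np.random.default_rng(31)
        dosage = rng.integers(0, 3, size=20)
        Y = rng.integers(0, 2, size=20).astype(float)
        ds = XDataset(np.arange(20), dosage, Y, np.empty((20, 0)), "qualitative")
        pr = PriorSpec(gamma_prior="normal")
        theta = {"beta0": -0.3, "beta": 0.4, "gamma": 1.3}

        acc = np.longdouble(0.0)
        acc += stats.norm(0, 10).logpdf(theta["beta0"])
        acc += stats.norm(0, 10).logpdf(theta["beta"])
        acc += stats.truncnorm(-1, 1, loc=1, scale=1).logpdf(theta["gamma"])
        x1 = (dosage >= 1).astype(float)
        x2 = (dosage == 2).astype(float)
        for i in range(20):
            eta = theta["beta0"] + theta["beta"] * (
                theta["gamma"] * x1[i] + (2 - theta["gamma"]) * x2[i]
            )
            p = 1.0 / (1.0 + np.exp(np.longdouble(-eta)))
            acc += Y[i] * np.log(p) + (1 - Y[i]) * np.log1p(-p)
        assert log_posterior(theta, ds, pr) == pytest.approx(float(acc), abs=1e-10)


class TestRhat:
    def test_well_mixed_white_noise(self):
        rng = np.random.default_rng(0)
        chains = rng.normal(size=(4, 2000))
        assert rhat(chains) == pytest.approx(1.0, abs=0.01)

    def test_separated_chains_flagged(self):
        rng = np.random.default_rng(1)
        chains = rng.normal(size=(2, 1000))
        chains[1] += 10.0
        assert rhat(chains) > 3.0

    def test_textbook_formula_on_fixed_arrays(self):
        # hand-computed split-chain formula on a 2 x 8 example
        chains = np.array(
            [[0.1, 0.4, -0.2, 0.3, 0.0, 0.5, -0.1, 0.2],
             [1.0, 0.8, 1.2, 0.9, 1.1, 0.7, 1.3, 0.6]]
        )
        seqs = np.array([chains[0, :4], chains[0, 4:], chains[1, :4], chains[1, 4:]])
        n = 4
        W = np.mean([np.var(s, ddof=1) for s in seqs])
        B = n * np.var([s.mean() for s in seqs], ddof=1)
        expected = math.sqrt(((n - 1) / n * W + B / n) / W)
        assert rhat(chains) == pytest.approx(expected, abs=1e-12)

    def test_matches_arviz_split_rhat(self):
        az = pytest.importorskip("arviz")
        rng = np.random.default_rng(3)
        chains = rng.normal(size=(4, 500)) + 0.3 * rng.normal(size=(4, 1))
        ref = float(az.rhat(az.convert_to_dataset(chains))["x"].values)
        # arviz rank-normalizes; agreement is approximate, not exact
        assert rhat(chains) == pytest.approx(ref, abs=0.05)

    def test_zero_within_variance(self):
        chains = np.array([[1.0] * 8, [2.0] * 8])
        assert rhat(chains) == math.inf

    def test_too_few_chains(self):
        with pytest.raises(ValueError):
            rhat(np.zeros((1, 100)))


class TestModeAndHpdi:
    def test_constant_draws(self):
        assert posterior_mode(np.full(500, 0.7)) == pytest.approx(0.7)
        assert hpdi(np.full(500, 0.7)) == (0.7, 0.7)

    def test_mode_of_narrow_normal(self):
        rng = np.random.default_rng(5)
        draws = np.clip(rng.normal(1.0, 0.05, size=80_000), 0, 2)
        assert posterior_mode(draws) == pytest.approx(1.0, abs=0.01)

    def test_mode_at_boundary(self):
        rng = np.random.default_rng(6)
        draws = rng.exponential(1 / 5.0, size=80_000)
        draws = draws[draws <= 2.0]
        assert posterior_mode(draws) < 0.05

    def test_mode_requires_enough_draws(self):
        with pytest.raises(ValueError):
            posterior_mode(np.ones(50))

    def test_hpdi_five_point_example(self):
        assert hpdi(np.array([0.0, 0.1, 0.2, 0.3, 10.0]), 0.8) == (0.0, 0.3)

    def test_hpdi_matches_exhaustive_window_oracle(self):
        rng = np.random.default_rng(7)
        for _ in range(50):
            kind = rng.integers(0, 3)
            if kind == 0:
                draws = rng.normal(1, 0.3, 400)
            elif kind == 1:
                draws = rng.exponential(0.5, 400)
            else:
                draws = rng.uniform(0, 2, 400)
            x = np.sort(draws)
            level = rng.choice([0.5, 0.8, 0.95])
            m = math.ceil(level * x.size)
            best = min(
                ((x[j + m - 1] - x[j], (x[j], x[j + m - 1])) for j in range(x.size - m + 1)),
                key=lambda t: t[0],
            )[1]
            assert hpdi(draws, level) == best


class TestSampling:
    def test_prior_recovery_uniform(self):
        # no data, BU prior: gamma draws must be U(0, 2); KS test at 1% on
        # 10^4 thinned draws, plus moment checks within 3 SE
        ds = _empty_dataset()
        cfg = SamplerConfig(chains=4, iterations=6000, warmup=1000, seed=2026)
        s = sample_posterior(ds, PriorSpec(gamma_prior="uniform"), cfg)
        g = s.gamma[::2]
        assert g.size == 10_000
        assert abs(g.mean() - 1.0) < 3 * math.sqrt(1 / 3 / g.size)
        _, pval = stats.kstest(g, stats.uniform(0, 2).cdf)
        assert pval > 0.01

    def test_prior_recovery_normal(self):
        # the truncated N(1,1) prior is nearly flat on [0,2], so the sample
        # mode is inherently noisy; check symmetry tightly and the mode loosely
        ds = _empty_dataset()
        cfg = SamplerConfig(chains=4, iterations=4000, warmup=1000, seed=3)
        s = sample_posterior(ds, PriorSpec(gamma_prior="normal"), cfg)
        g = s.gamma
        assert g.mean() == pytest.approx(1.0, abs=0.03)
        assert 0.5 < posterior_mode(g) < 1.5

    def test_structural_guarantees(self, replication_dataset):
        cfg = SamplerConfig.reduced(seed=4)
        s = sample_posterior(replication_dataset, PriorSpec(gamma_prior="normal"), cfg)
        g = s.gamma
        assert np.all((g >= 0) & (g <= 2))
        lo, hi = hpdi(g)
        assert 0 <= lo <= hi <= 2 and hi - lo <= 2
        assert set(s.rhat) == {"beta0", "beta", "gamma"}

    def test_parameter_recovery_quantitative(self):
        # strongly informative data concentrate the posterior near the truth;
        # n is large enough that the data's own sampling noise in gamma_hat
        # (SE ~ sqrt(v)/beta) sits well inside the assertion band
        cfg = SimConfig(trait_type="quantitative", n=50_000, maf=0.3, seed=0)
        rng = np.random.default_rng(99)
        ds = simulate_quantitative(cfg, 0.6, rng)
        s = sample_posterior(ds, PriorSpec(gamma_prior="normal"), SamplerConfig.reduced(seed=5))
        assert s.max_rhat() < 1.05
        assert posterior_mode(s.gamma) == pytest.approx(0.6, abs=0.1)

    def test_determinism_under_seed(self, gwas_dataset):
        cfg = SamplerConfig(chains=2, iterations=300, warmup=150, seed=11)
        a = sample_posterior(gwas_dataset, PriorSpec(gamma_prior="uniform"), cfg)
        b = sample_posterior(gwas_dataset, PriorSpec(gamma_prior="uniform"), cfg)
        np.testing.assert_array_equal(a.draws["gamma"], b.draws["gamma"])
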