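"""Model-level oracles: each likelihood fit against an independent route."""

import math

import numpy as np
import pytest
from scipy import optimize, stats

import microcount as mc
from microcount.datatypes import NonIdentifiableError, ValidationError
from microcount.models import (
    CensoredLognormalModel,
    LognormalModel,
    PoissonLognormalModel,
    arithmetic_moments,
    log_scale_params,
)


class TestMomentConversion:
    def test_round_trip(self, rng):
        for _ in range(200):
            meanlog = rng.uniform(-8, 3)
            sdlog = rng.uniform(0.01, 2.5)
            mean, sd = arithmetic_moments(meanlog, sdlog)
            m2, s2 = log_scale_params(mean, sd)
            assert m2 == pytest.approx(meanlog, abs=1e-12)
            assert s2 == pytest.approx(sdlog, abs=1e-12)

    def test_known_values(self):
        mean, sd = arithmetic_moments(0.0, 1.0)
        assert mean == pytest.approx(math.exp(0.5), rel=1e-12)
        assert sd == pytest.approx(math.exp(0.5) * math.sqrt(math.e - 1), rel=1e-12)


class TestLognormalModel:
    def test_matches_numerical_likelihood_maximisation(self, rng):
        vals = rng.lognormal(-2.0, 0.7, size=10)
        res = LognormalModel(vals).fit()

        def nll(p):
            return -stats.lognorm.logpdf(vals, p[1], scale=np.exp(p[0])).sum()

        opt = optimize.minimize(nll, [0.0, 1.0], method="Nelder-Mead",
                                options=dict(xatol=1e-10, fatol=1e-12))
        assert res.meanlog == pytest.approx(opt.x[0], abs=1e-6)
        assert res.sdlog == pytest.approx(opt.x[1], abs=1e-6)
        assert res.llf == pytest.approx(-opt.fun, abs=1e-8)

    def test_uses_n_divisor_not_n_minus_one(self):
        vals = [1.0, 2.0, 4.0]
        res = LognormalModel(vals).fit()
        logs = np.log(vals)
        assert res.sdlog == pytest.approx(logs.std(ddof=0), rel=1e-12)
        assert res.sdlog < logs.std(ddof=1)

    def test_degenerate_equal_values(self):
        res = LognormalModel([0.5, 0.5]).fit()
        assert res.meanlog == pytest.approx(math.log(0.5))
        assert res.sdlog == 0.0
        assert res.arith_sd == 0.0

    def test_input_contract(self):
        with pytest.raises(ValidationError):
            LognormalModel([1.0])
        with pytest.raises(ValidationError):
            LognormalModel([1.0, -2.0])


class TestCensoredLognormalModel:
    def test_no_censoring_equals_uncensored_fit(self, rng):
        vals = rng.lognormal(-3, 0.5, size=6)
        full = LognormalModel(vals).fit()
        cens = CensoredLognormalModel(vals, []).fit()
        assert cens.meanlog == pytest.approx(full.meanlog, abs=1e-9)
        assert cens.sdlog == pytest.approx(full.sdlog, abs=1e-9)

    def test_matches_dense_grid_search(self):
        values = np.array([0.02, 0.05])
        limits = np.array([0.015, 0.02, 0.018])
        model = CensoredLognormalModel(values, limits)
        res = model.fit()
        # independent vectorised grid evaluation of the censored likelihood
        mus = np.linspace(res.meanlog - 1.5, res.meanlog + 1.5, 401)
        sds = np.linspace(max(res.sdlog - 1.0, 0.01), res.sdlog + 1.0, 401)
        M, S = np.meshgrid(mus, sds, indexing="ij")
        ll = np.zeros_like(M)
        for v in values:
            ll += stats.norm.logpdf(np.log(v), M, S) - np.log(v)
        for lim in limits:
            ll += stats.norm.logcdf((np.log(lim) - M) / S)
        i, j = np.unravel_index(np.argmax(ll), ll.shape)
        assert model.loglike((res.meanlog, res.sdlog)) >= ll[i, j] - 1e-6
        assert res.meanlog == pytest.approx(mus[i], abs=(mus[1] - mus[0]) * 1.5)
        assert res.sdlog == pytest.approx(sds[j], abs=(sds[1] - sds[0]) * 1.5)

    def test_converged_flag_and_se_reported(self, calgary_reported):
        res = mc.approach_censored_mle(calgary_reported)
        assert res.converged
        assert np.all(np.isfinite(res.bse))


class TestPoissonLognormalModel:
    def test_gauss_hermite_agrees_with_adaptive_quadrature(self, calgary):
        counts = [o.count for o in calgary.records]
        vols = [o.volume for o in calgary.records]
        model = PoissonLognormalModel(counts, vols)
        for params in [(-5.3, 0.83), (-4.0, 0.4), (-6.0, 1.5)]:
            gh = model.loglike(params)
            quad = model.loglike_quad(params)
            assert gh == pytest.approx(quad, rel=1e-6)

    def test_local_optimality_of_returned_maximum(self, calgary_fits, rng):
        res = calgary_fits["E"]
        model = res.model
        ll_hat = model.loglike((res.meanlog, res.sdlog))
        for _ in range(100):
            pert = (
                res.meanlog + rng.uniform(-0.3, 0.3),
                max(res.sdlog + rng.uniform(-0.3, 0.3), 1e-3),
            )
            assert ll_hat >= model.loglike(pert) - 1e-9

    def test_sdlog_zero_limit_is_pooled_poisson_mle(self):
        # equal volumes, sdlog pinned near 0: MLE of meanlog -> log of
        # total count / total volume (the Poisson MLE)
        counts = [3, 1, 0, 2, 4, 0]
        vols = [10.0] * 6
        model = PoissonLognormalModel(counts, vols)
        pooled = sum(counts) / sum(vols)

        def nll(m):
            return -model.loglike((m[0], 1e-9))

        opt = optimize.minimize(nll, [math.log(pooled)], method="Nelder-Mead",
                                options=dict(xatol=1e-12, fatol=1e-12))
        assert math.exp(opt.x[0]) == pytest.approx(pooled, rel=1e-6)

    def test_tntc_uses_survival_probability(self):
        # replacing an exact high count by TNTC(threshold) must give the
        # Poisson survival term inside the marginal likelihood
        model = PoissonLognormalModel([5, None], [1.0, 1.0], [None, 3])
        m, s = -0.2, 0.5
        L = np.exp(model.loglikeobs((m, s)))
        t, w = np.polynomial.hermite.hermgauss(61)
        lam = np.exp(m + math.sqrt(2) * s * t)
        oracle = (w * stats.poisson.sf(2, lam)).sum() / math.sqrt(math.pi)
        assert L[1] == pytest.approx(oracle, rel=1e-10)

    def test_all_zero_counts_non_identifiable(self):
        with pytest.raises(NonIdentifiableError):
            PoissonLognormalModel([0, 0, 0], [50.0, 50.0, 50.0])

    def test_record_must_be_count_or_tntc(self):
        with pytest.raises(ValidationError):
            PoissonLognormalModel([1, 2], [1.0, 1.0], [None, 4])


def test_summary_contains_estimates(calgary_fits):
    text = calgary_fits["E"].summary()
    assert "meanlog" in text and "arithmetic mean" in text
    assert f"{calgary_fits['E'].meanlog:.4f}"[:6] in text
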