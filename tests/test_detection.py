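"""Non-detect probability, method sensitivity limit and MPN estimation."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import integrate, optimize

import microcount as mc
from microcount.datatypes import ValidationError

PERFECT = mc.RecoveryModel.perfect()
CONST04 = mc.RecoveryModel.constant(0.4)
BETA23 = mc.RecoveryModel.beta(2, 3)


class TestProbNondetect:
    def test_zero_concentration_always_nondetect(self):
        for rec in (PERFECT, CONST04, BETA23):
            assert mc.prob_nondetect(0.0, 1.0, rec) == 1.0

    def test_perfect_recovery_closed_form(self):
        # c chosen so exp(-cV) = 1/100 exactly
        assert mc.prob_nondetect(math.log(100), 1.0, PERFECT) == pytest.approx(
            0.01, rel=1e-9
        )

    def test_constant_recovery_is_volume_scaling(self):
        # thinning by p is indistinguishable from analysing p*V liters
        assert mc.prob_nondetect(10, 1.0, CONST04) == pytest.approx(
            mc.prob_nondetect(4, 1.0, PERFECT), rel=1e-12
        )

    def test_beta_recovery_matches_explicit_quadrature(self):
        # E[exp(-10 R)], R ~ Beta(2,3): density 12 r (1-r)^2 on (0,1)
        oracle, _ = integrate.quad(
            lambda r: 12 * r * (1 - r) ** 2 * math.exp(-10 * r), 0, 1
        )
        assert mc.prob_nondetect(10, 1.0, BETA23) == pytest.approx(oracle, rel=1e-10)

    @pytest.mark.parametrize("cv", np.geomspace(0.01, 200, 12).tolist())
    def test_hypergeometric_route_agrees_with_quadrature(self, cv):
        from scipy import stats

        dens = stats.beta(2.5, 1.7).pdf
        oracle, _ = integrate.quad(
            lambda r: math.exp(-cv * r) * dens(r), 0, 1,
            limit=400, epsabs=0, epsrel=1e-13,
        )
        got = mc.prob_nondetect(cv, 1.0, mc.RecoveryModel.beta(2.5, 1.7))
        assert got == pytest.approx(oracle, rel=1e-8)

    @given(
        c=st.floats(0.01, 50),
        dc=st.floats(0.01, 10),
        v=st.floats(0.05, 100),
        dv=st.floats(0.01, 10),
    )
    @settings(max_examples=60, deadline=None)
    def test_strictly_decreasing_in_concentration_and_volume(self, c, dc, v, dv):
        from hypothesis import assume

        # keep exp(-cV) above the underflow floor so strictness is testable
        assume((c + dc) * (v + dv) < 600)
        for rec in (PERFECT, CONST04, BETA23):
            p0 = mc.prob_nondetect(c, v, rec)
            assert mc.prob_nondetect(c + dc, v, rec) < p0
            assert mc.prob_nondetect(c, v + dv, rec) < p0

    def test_jensen_bound_beta_above_constant_at_equal_mean(self, rng):
        # exp is convex, so averaging recovery before exponentiating
        # understates the non-detect probability
        for _ in range(100):
            a, b = rng.uniform(0.2, 6, size=2)
            c = rng.uniform(0.1, 40)
            v = rng.uniform(0.1, 10)
            beta = mc.RecoveryModel.beta(a, b)
            const = mc.RecoveryModel.constant(a / (a + b))
            assert (
                mc.prob_nondetect(c, v, beta)
                >= mc.prob_nondetect(c, v, const) - 1e-12
            )

    @pytest.mark.parametrize(
        "c,v", [(-1, 1), (math.nan, 1), (1, 0), (1, -2), (1, math.inf)]
    )
    def test_domain_errors(self, c, v):
        with pytest.raises(ValidationError):
            mc.prob_nondetect(c, v, PERFECT)

    def test_degenerate_beta_parameters_rejected(self):
        with pytest.raises(ValidationError):
            mc.RecoveryModel.beta(0, 3)
        with pytest.raises(ValidationError):
            mc.RecoveryModel.beta(2, -1)


class TestMsl:
    @pytest.mark.parametrize(
        "rec,expected",
        [
            (PERFECT, math.log(100)),       # ln(1/alpha)/V
            (CONST04, math.log(100) / 0.4),  # ln(1/alpha)/(pV)
        ],
    )
    def test_closed_forms(self, rec, expected):
        assert mc.msl(1.0, rec, 0.01) == pytest.approx(expected, rel=1e-9)

    def test_scales_inversely_with_volume(self):
        assert mc.msl(100.0, PERFECT, 0.01) == pytest.approx(
            mc.msl(1.0, PERFECT, 0.01) / 100, rel=1e-9
        )

    @pytest.mark.parametrize("rec", [PERFECT, CONST04, BETA23])
    @pytest.mark.parametrize("alpha", [0.01, 0.05, 0.3])
    def test_nondetect_probability_at_msl_equals_alpha(self, rec, alpha):
        c_star = mc.msl(1.0, rec, alpha)
        assert mc.prob_nondetect(c_star, 1.0, rec) == pytest.approx(
            alpha, abs=1e-6
        )

    def test_alpha_out_of_range(self):
        for alpha in (0.0, 1.0, -0.1, 2.0):
            with pytest.raises(ValidationError):
                mc.msl(1.0, PERFECT, alpha)


def _grid_mpn(tests, c_grid):
    """Dense grid-search oracle for the MPN likelihood."""
    best_c, best_ll = None, -math.inf
    for c in c_grid:
        ll = 0.0
        for t in tests:
            p_pos = -math.expm1(-c * t.volume)
            if t.positive:
                if p_pos <= 0:
                    ll = -math.inf
                    break
                ll += math.log(p_pos)
            else:
                ll += -c * t.volume
        if ll > best_ll:
            best_c, best_ll = c, ll
    return best_c


class TestMpn:
    def test_all_negative_boundary(self):
        tests = [mc.PresenceAbsenceTest(1.0, False)] * 5
        res = mc.mpn_estimate(tests)
        assert res.mle == 0.0 and res.identifiable

    def test_all_positive_non_identifiable(self):
        res = mc.mpn_estimate([mc.PresenceAbsenceTest(1.0, True)] * 4)
        assert not res.identifiable
        assert math.isinf(res.mle)

    def test_equal_volume_closed_form(self):
        # -ln(negatives/total)/V with 5 of 10 positive at 1 L
        tests = [mc.PresenceAbsenceTest(1.0, i < 5) for i in range(10)]
        assert mc.mpn_estimate(tests).mle == pytest.approx(math.log(2), rel=1e-9)

    def test_mixed_volume_series_matches_grid(self):
        # Quanti-Tray-like three-volume series
        tests = (
            [mc.PresenceAbsenceTest(0.1, True)] * 3
            + [mc.PresenceAbsenceTest(0.01, True)] * 1
            + [mc.PresenceAbsenceTest(0.01, False)] * 4
            + [mc.PresenceAbsenceTest(0.001, False)] * 5
        )
        res = mc.mpn_estimate(tests)
        grid = np.linspace(1e-3, 500, 400001)
        assert res.mle == pytest.approx(_grid_mpn(tests, grid), abs=2e-3 * 500)

    def test_random_series_match_grid_argmax(self, rng):
        for _ in range(50):
            n = rng.integers(3, 12)
            vols = rng.uniform(0.05, 5.0, size=n)
            c_true = rng.uniform(0.1, 3.0)
            pos = rng.random(n) < -np.expm1(-c_true * vols)
            if pos.all() or not pos.any():
                continue
            tests = [
                mc.PresenceAbsenceTest(float(v), bool(p))
                for v, p in zip(vols, pos)
            ]
            res = mc.mpn_estimate(tests)
            grid = np.geomspace(1e-4, 1e3, 20000)
            c_grid = _grid_mpn(tests, grid)
            # grid resolution: neighbouring grid points differ by ~0.08%
            assert res.mle == pytest.approx(c_grid, rel=2e-3)

    def test_empty_series_rejected(self):
        with pytest.raises(ValidationError):
            mc.mpn_estimate([])
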