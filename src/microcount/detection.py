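"""Non-detect probabilities, the method sensitivity limit, and MPN.

Counts from a well-mixed source are modelled as Poisson with expectation
``c * V * R`` — concentration times analytical volume times recovery.  The
probability that a sample yields a non-detect (a count of zero) is then

* perfect recovery:        ``exp(-c V)``
* constant recovery ``p``: ``exp(-c V p)``
* beta(a, b) recovery:     ``E_R[exp(-c V R)] = 1F1(a; a + b; -c V)``,

the last being the moment generating function of a Beta(a, b) random
variable at ``-c V``, i.e. Kummer's confluent hypergeometric function.

The method sensitivity limit (MSL) is the concentration at which the
non-detect probability falls to a chosen small ``alpha`` (default 1%):
above the MSL a non-detect becomes improbable, so the MSL characterises
the sensitivity of a method/volume/recovery combination on the
concentration scale.

The most probable number (MPN) estimator treats a series of
presence/absence tests as censored counts (positive = count >= 1) and
maximises the resulting Bernoulli likelihood over the concentration.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import integrate, optimize, special, stats

from .datatypes import (
    NonIdentifiableError,
    PresenceAbsenceTest,
    RecoveryModel,
    ValidationError,
)

__all__ = ["prob_nondetect", "msl", "mpn_estimate", "MpnResult"]


def _beta_mixed_zero_prob(a: float, b: float, cv: float) -> float:
    """E over R ~ Beta(a, b) of exp(-cv * R).

    Prefers the closed form 1F1(a; a+b; -cv); falls back to adaptive
    quadrature when the special function overflows or loses its value
    (large |cv| can underflow to an invalid result in some regimes).
    """
    val = special.hyp1f1(a, a + b, -cv)
    if np.isfinite(val) and 0.0 < val <= 1.0:
        return float(val)
    dens = stats.beta(a, b).pdf
    out, _ = integrate.quad(lambda r: math.exp(-cv * r) * dens(r), 0.0, 1.0)
    return float(out)


def prob_nondetect(
    concentration: float, volume: float, recovery: RecoveryModel
) -> float:
    """Probability of observing a count of zero.

    Parameters
    ----------
    concentration : float
        True source concentration, organisms per liter (>= 0).
    volume : float
        Analytical volume in liters (> 0).
    recovery : RecoveryModel
        Analytical recovery profile.

    Returns
    -------
    float
        P(count = 0), in (0, 1].
    """
    if not math.isfinite(concentration) or concentration < 0:
        raise ValidationError(
            f"concentration must be finite and >= 0, got {concentration!r}"
        )
    if not math.isfinite(volume) or volume <= 0:
        raise ValidationError(f"volume must be finite and > 0, got {volume!r}")
    cv = concentration * volume
    if recovery.variant == "perfect":
        return math.exp(-cv)
    if recovery.variant == "constant":
        return math.exp(-cv * recovery.p)
    return _beta_mixed_zero_prob(recovery.a, recovery.b, cv)


def msl(
    volume: float,
    recovery: RecoveryModel,
    alpha: float = 0.01,
) -> float:
    """Method sensitivity limit: the concentration at which P(ND) = alpha.

    For perfect recovery this is ``ln(1/alpha)/V`` and for constant
    recovery ``ln(1/alpha)/(p V)``; for beta recovery the monotone
    equation ``1F1(a; a+b; -c V) = alpha`` is solved by bracketing root
    search.

    Parameters
    ----------
    volume : float
        Analytical volume in liters.
    recovery : RecoveryModel
        Analytical recovery profile.
    alpha : float
        Target non-detect probability in (0, 1); default 0.01, i.e. the
        concentration beyond which fewer than 1% of samples are expected
        to be non-detects.
    """
    if not 0 < alpha < 1:
        raise ValidationError(f"alpha must be in (0, 1), got {alpha!r}")
    if not math.isfinite(volume) or volume <= 0:
        raise ValidationError(f"volume must be finite and > 0, got {volume!r}")
    if recovery.variant == "perfect":
        return math.log(1.0 / alpha) / volume
    if recovery.variant == "constant":
        return math.log(1.0 / alpha) / (recovery.p * volume)
    # beta: bracket [0, hi], doubling hi from the mean-recovery guess
    # until P(ND) < alpha (guaranteed to terminate by monotone decay).
    hi = math.log(1.0 / alpha) / (volume * recovery.mean)
    while prob_nondetect(hi, volume, recovery) > alpha:
        hi *= 2.0
    return float(
        optimize.brentq(
            lambda c: prob_nondetect(c, volume, recovery) - alpha,
            0.0,
            hi,
            xtol=1e-12,
            rtol=1e-12,
        )
    )


@dataclass(frozen=True)
class MpnResult:
    """Most-probable-number estimate from a presence/absence series.

    ``identifiable`` is False when every test is positive: the likelihood
    then increases without bound and no finite MLE exists (``mle`` is
    ``inf``).  An all-negative series has its MLE at the boundary, zero.
    """

    mle: float
    loglik: float
    identifiable: bool
    n_tests: int
    n_positive: int

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        if not self.identifiable:
            return (
                f"MpnResult(non-identifiable: all {self.n_tests} tests "
                "positive, MLE unbounded)"
            )
        return (
            f"MpnResult(mle={self.mle:.6g} per L, loglik={self.loglik:.6g}, "
            f"{self.n_positive}/{self.n_tests} positive)"
        )


def _mpn_loglik(c: float, volumes: np.ndarray, positive: np.ndarray) -> float:
    lam = c * volumes
    with np.errstate(divide="ignore"):
        ll_pos = np.log1p(-np.exp(-lam[positive])).sum()
    ll_neg = -lam[~positive].sum()
    return float(ll_pos + ll_neg)


def mpn_estimate(tests: Sequence[PresenceAbsenceTest]) -> MpnResult:
    """Maximum-likelihood concentration from presence/absence tests.

    Each positive test contributes the censored-count probability
    ``1 - exp(-c V_j)`` (at least one organism) and each negative test the
    zero-count probability ``exp(-c V_j)``.  The product is maximised over
    c >= 0.
    """
    if len(tests) == 0:
        raise ValidationError("mpn_estimate requires at least one test")
    volumes = np.array([t.volume for t in tests], dtype=float)
    positive = np.array([t.positive for t in tests], dtype=bool)
    n, npos = len(tests), int(positive.sum())

    if npos == 0:
        return MpnResult(0.0, 0.0, True, n, 0)
    if npos == n:
        return MpnResult(math.inf, 0.0, False, n, n)

    # Score equation: sum_pos V_j e^{-cV_j}/(1-e^{-cV_j}) = sum_neg V_j.
    # Its left side decreases from +inf to 0, so a unique root exists.
    neg_vol = volumes[~positive].sum()

    def score(c: float) -> float:
        lam = c * volumes[positive]
        return float((volumes[positive] * np.exp(-lam) / -np.expm1(-lam)).sum() - neg_vol)

    lo, hi = 1e-12, 1.0 / volumes.mean()
    while score(hi) > 0:
        hi *= 2.0
    while score(lo) < 0:  # pragma: no cover - lo is essentially 0
        lo /= 2.0
    c_hat = float(optimize.brentq(score, lo, hi, xtol=1e-14, rtol=1e-13))
    return MpnResult(c_hat, _mpn_loglik(c_hat, volumes, positive), True, n, npos)
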