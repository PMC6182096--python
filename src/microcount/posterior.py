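"""Bayesian posterior for a concentration given one count observation.

With a Poisson likelihood ``x ~ Poisson(c p V)`` and a flat (semi-infinite
uniform) prior on c over [0, inf), the posterior for the concentration is
conjugate:

    c | x  ~  Gamma(shape = x + 1, rate = p V)

where V is the analytical volume and p a known constant recovery fraction
(p = 1 for perfect recovery).  A non-detect (x = 0) therefore leaves an
Exponential(rate = pV) posterior — far from concentrated below 1/V, which
is why reading a non-detect as "concentration < 1 per volume analysed"
misstates the evidence.  The flat prior is improper but the posterior is
proper for every count.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from scipy import stats

from .datatypes import ValidationError

__all__ = [
    "GammaPosterior",
    "posterior_from_count",
    "prob_exceeds",
    "credible_interval",
]


@dataclass(frozen=True)
class GammaPosterior:
    """Gamma(shape, rate) posterior for a concentration in organisms/L."""

    shape: float
    rate: float

    def __post_init__(self) -> None:
        if not math.isfinite(self.shape) or self.shape <= 0:
            raise ValidationError(f"shape must be > 0, got {self.shape!r}")
        if not math.isfinite(self.rate) or self.rate <= 0:
            raise ValidationError(f"rate must be > 0, got {self.rate!r}")

    @property
    def _dist(self):
        return stats.gamma(a=self.shape, scale=1.0 / self.rate)

    @property
    def mean(self) -> float:
        """Posterior mean, (x + 1)/(p V)."""
        return self.shape / self.rate

    @property
    def mode(self) -> float:
        """Posterior mode, x/(p V) — the naive point estimate count/volume."""
        return max(self.shape - 1.0, 0.0) / self.rate

    def pdf(self, c):
        return self._dist.pdf(c)

    def cdf(self, c):
        return self._dist.cdf(c)

    def sf(self, c):
        return self._dist.sf(c)

    def ppf(self, q):
        return self._dist.ppf(q)


def posterior_from_count(
    count: int, volume: float, recovery_p: float = 1.0
) -> GammaPosterior:
    """Posterior for the concentration given one count in one volume.

    Parameters
    ----------
    count : int
        Observed organism count (non-negative integer; zero for an ND).
    volume : float
        Analytical volume in liters.
    recovery_p : float
        Known constant recovery fraction in (0, 1]; default 1 (perfect).
        Variable (beta-distributed) recovery breaks the gamma conjugacy
        and is not supported here.
    """
    if count != int(count) or count < 0:
        raise ValidationError(
            f"count must be a non-negative integer, got {count!r}"
        )
    if not math.isfinite(volume) or volume <= 0:
        raise ValidationError(f"volume must be finite and > 0, got {volume!r}")
    if not 0 < recovery_p <= 1:
        raise ValidationError(
            f"recovery_p must be in (0, 1], got {recovery_p!r}"
        )
    return GammaPosterior(shape=int(count) + 1.0, rate=recovery_p * volume)


def prob_exceeds(posterior: GammaPosterior, threshold: float) -> float:
    """Posterior probability that the true concentration exceeds *threshold*.

    Evaluated against a purported detection limit, this is the probability
    that the concentration is actually above the limit despite (or given)
    the observed count.
    """
    if not math.isfinite(threshold) or threshold < 0:
        raise ValidationError(
            f"threshold must be finite and >= 0, got {threshold!r}"
        )
    return float(posterior.sf(threshold))


def credible_interval(
    posterior: GammaPosterior, level: float = 0.95
) -> tuple[float, float]:
    """Equal-tailed credible interval at the given coverage level."""
    if not 0 < level < 1:
        raise ValidationError(f"level must be in (0, 1), got {level!r}")
    tail = (1.0 - level) / 2.0
    return float(posterior.ppf(tail)), float(posterior.ppf(1.0 - tail))
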