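"""Lognormal concentration models fitted by maximum likelihood.

Three model classes share a common results object:

:class:`LognormalModel`
    uncensored lognormal MLE on positive concentration values (closed
    form; the MLE uses the n-divisor for the log-scale SD);
:class:`CensoredLognormalModel`
    left-censored lognormal MLE — density terms for detects, CDF-at-limit
    terms for values known only to lie below a per-sample limit (the
    treatment appropriate for genuinely censored continuous data);
:class:`PoissonLognormalModel`
    hierarchical measurement-error model for raw counts — concentrations
    vary across samples as LogNormal(meanlog, sdlog), and each count is
    Poisson(concentration x volume).  Non-detects enter as observed zero
    counts through the Poisson mass; TNTC entries enter through the
    Poisson survival probability of the censored count range.  The
    marginal per-sample likelihood is an integral over the unobserved
    concentration, evaluated by Gauss-Hermite quadrature in
    log-concentration.

All models parameterise the fitted distribution by (meanlog, sdlog) on
the log scale; the results object also reports the arithmetic mean
``exp(meanlog + sdlog^2/2)`` and arithmetic SD
``mean * sqrt(exp(sdlog^2) - 1)`` in organisms per liter, the scale on
which monitoring statistics are usually quoted.
"""

from __future__ import annotations

import math
from typing import Sequence

import numpy as np
from scipy import integrate, optimize, stats

from .datatypes import NonIdentifiableError, ValidationError

__all__ = [
    "LognormalModel",
    "CensoredLognormalModel",
    "PoissonLognormalModel",
    "LognormalResults",
    "arithmetic_moments",
    "log_scale_params",
]

_GH_NODES_DEFAULT = 61


def arithmetic_moments(meanlog: float, sdlog: float) -> tuple[float, float]:
    """(arithmetic mean, arithmetic SD) of LogNormal(meanlog, sdlog)."""
    mean = math.exp(meanlog + 0.5 * sdlog**2)
    sd = mean * math.sqrt(math.expm1(sdlog**2))
    return mean, sd


def log_scale_params(mean: float, sd: float) -> tuple[float, float]:
    """Inverse of :func:`arithmetic_moments`: (meanlog, sdlog) from
    arithmetic mean and SD of a lognormal."""
    if mean <= 0 or sd < 0:
        raise ValidationError("mean must be > 0 and sd >= 0")
    s2 = math.log1p((sd / mean) ** 2)
    return math.log(mean) - 0.5 * s2, math.sqrt(s2)


class LognormalResults:
    """MLE fit of a lognormal concentration distribution.

    Attributes
    ----------
    meanlog, sdlog : float
        Log-scale location and spread of the fitted lognormal.
    arith_mean, arith_sd : float
        Arithmetic mean and SD of the fitted distribution (organisms/L).
    llf : float
        Log-likelihood at the optimum.
    converged : bool
        Whether the optimiser reported convergence (always True for the
        closed-form uncensored fit).
    bse : ndarray
        Approximate standard errors of (meanlog, sdlog) from the observed
        information; NaN where the Hessian is unavailable or singular.
    """

    def __init__(
        self,
        model,
        meanlog: float,
        sdlog: float,
        llf: float,
        converged: bool,
        approach: str = "",
        bse=None,
    ) -> None:
        self.model = model
        self.meanlog = float(meanlog)
        self.sdlog = float(sdlog)
        self.llf = float(llf)
        self.converged = bool(converged)
        self.approach = approach
        self.params = np.array([self.meanlog, self.sdlog])
        self.bse = np.full(2, np.nan) if bse is None else np.asarray(bse, float)
        self.nobs = model.nobs

    @property
    def arith_mean(self) -> float:
        return arithmetic_moments(self.meanlog, self.sdlog)[0]

    @property
    def arith_sd(self) -> float:
        return arithmetic_moments(self.meanlog, self.sdlog)[1]

    def distribution(self):
        """The fitted lognormal as a frozen scipy distribution."""
        return stats.lognorm(s=max(self.sdlog, 1e-300), scale=math.exp(self.meanlog))

    def summary(self) -> str:
        """Plain-text summary table of the fit."""
        name = type(self.model).__name__
        lines = [
            f"{name} maximum-likelihood fit"
            + (f"  [approach {self.approach}]" if self.approach else ""),
            "=" * 58,
            f"  n obs:            {self.nobs}",
            f"  log-likelihood:   {self.llf:.6f}",
            f"  converged:        {self.converged}",
            "-" * 58,
            f"  meanlog (mu_L):   {self.meanlog: .6f}  (se {self.bse[0]:.4f})",
            f"  sdlog  (sigma_L): {self.sdlog: .6f}  (se {self.bse[1]:.4f})",
            f"  arithmetic mean:  {self.arith_mean: .6f} organisms/L",
            f"  arithmetic SD:    {self.arith_sd: .6f} organisms/L",
            "=" * 58,
        ]
        return "\n".join(lines)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"<LognormalResults meanlog={self.meanlog:.4f} "
            f"sdlog={self.sdlog:.4f} mean={self.arith_mean:.4g} "
            f"sd={self.arith_sd:.4g} converged={self.converged}>"
        )


def _numerical_bse(nll, params: np.ndarray) -> np.ndarray:
    """Standard errors from a central-difference Hessian of the negative
    log-likelihood; NaN on any numerical failure."""
    n = len(params)
    h = 1e-4 * np.maximum(np.abs(params), 1.0)
    hess = np.empty((n, n))
    try:
        for i in range(n):
            for j in range(i, n):
                ei = np.zeros(n); ei[i] = h[i]
                ej = np.zeros(n); ej[j] = h[j]
                fpp = nll(params + ei + ej)
                fpm = nll(params + ei - ej)
                fmp = nll(params - ei + ej)
                fmm = nll(params - ei - ej)
                hess[i, j] = hess[j, i] = (fpp - fpm - fmp + fmm) / (4 * h[i] * h[j])
        cov = np.linalg.inv(hess)
        d = np.diag(cov)
        return np.where(d > 0, np.sqrt(np.maximum(d, 0)), np.nan)
    except Exception:
        return np.full(n, np.nan)


class LognormalModel:
    """Uncensored lognormal model for positive concentration values."""

    def __init__(self, values: Sequence[float]) -> None:
        vals = np.asarray(list(values), dtype=float)
        if vals.size < 2:
            raise ValidationError(
                f"lognormal MLE requires >= 2 values, got {vals.size}"
            )
        if not np.all(np.isfinite(vals)) or np.any(vals <= 0):
            raise ValidationError("all values must be finite and > 0")
        self.values = vals
        self.nobs = vals.size

    def loglike(self, params) -> float:
        meanlog, sdlog = params
        if sdlog <= 0:
            # degenerate point mass: finite only if all values coincide
            return math.inf if np.allclose(self.values, self.values[0]) else -math.inf
        return float(stats.norm.logpdf(np.log(self.values), meanlog, sdlog).sum()
                     - np.log(self.values).sum())

    def fit(self, approach: str = "") -> LognormalResults:
        logs = np.log(self.values)
        meanlog = float(logs.mean())
        sdlog = float(logs.std(ddof=0))  # n-divisor: the MLE, not n-1
        if sdlog > 0:
            llf = self.loglike((meanlog, sdlog))
            n = self.nobs
            bse = np.array([sdlog / math.sqrt(n), sdlog / math.sqrt(2 * n)])
        else:
            llf = math.inf
            bse = np.zeros(2)
        return LognormalResults(self, meanlog, sdlog, llf, True, approach, bse)


class CensoredLognormalModel:
    """Left-censored lognormal model: exact values plus below-limit records.

    Parameters
    ----------
    values : sequence of float
        Exactly observed positive concentrations (the detects).
    limits : sequence of float
        Per-record upper bounds for the censored observations (each datum
        is known only to lie in (0, limit]).
    """

    def __init__(self, values: Sequence[float], limits: Sequence[float]) -> None:
        vals = np.asarray(list(values), dtype=float)
        lims = np.asarray(list(limits), dtype=float)
        if vals.size < 1:
            raise ValidationError("censored MLE requires >= 1 exact value")
        if np.any(vals <= 0) or np.any(lims <= 0):
            raise ValidationError("values and limits must be > 0")
        self.values = vals
        self.limits = lims
        self.nobs = vals.size + lims.size

    def loglike(self, params) -> float:
        meanlog, sdlog = params
        if sdlog <= 0 or not np.isfinite(sdlog):
            return -math.inf
        ll = float(
            stats.norm.logpdf(np.log(self.values), meanlog, sdlog).sum()
            - np.log(self.values).sum()
        )
        if self.limits.size:
            z = (np.log(self.limits) - meanlog) / sdlog
            ll += float(stats.norm.logcdf(z).sum())
        return ll

    def _starts(self) -> list[np.ndarray]:
        # moment start on detects; half-limit substitution start; perturbed
        logs_d = np.log(self.values)
        s0 = np.array([logs_d.mean(), max(logs_d.std(ddof=0), 0.2)])
        subst = np.concatenate([self.values, 0.5 * self.limits])
        logs_s = np.log(subst)
        s1 = np.array([logs_s.mean(), max(logs_s.std(ddof=0), 0.2)])
        s2 = s1 + np.array([0.5, 0.3])
        return [s0, s1, s2]

    def fit(self, approach: str = "") -> LognormalResults:
        if self.limits.size == 0:
            res = LognormalModel(self.values).fit(approach)
            return LognormalResults(
                self, res.meanlog, res.sdlog, res.llf, True, approach, res.bse
            )

        def nll(theta):
            meanlog, log_sdlog = theta
            return -self.loglike((meanlog, math.exp(log_sdlog)))

        best = None
        for start in self._starts():
            theta0 = np.array([start[0], math.log(start[1])])
            r = optimize.minimize(
                nll, theta0, method="Nelder-Mead",
                options=dict(xatol=1e-10, fatol=1e-10, maxiter=4000),
            )
            if best is None or r.fun < best.fun - 1e-12:
                best = r
        meanlog, sdlog = best.x[0], math.exp(best.x[1])
        bse_theta = _numerical_bse(nll, best.x)
        # delta method for sdlog = exp(log_sdlog)
        bse = np.array([bse_theta[0], bse_theta[1] * sdlog])
        return LognormalResults(
            self, meanlog, sdlog, -best.fun, bool(best.success), approach, bse
        )


class PoissonLognormalModel:
    """Poisson-lognormal measurement-error model for raw counts.

    Each sample i has an unobserved concentration
    ``c_i ~ LogNormal(meanlog, sdlog)`` and an observed count
    ``x_i ~ Poisson(c_i * V_i)``.  The per-sample marginal likelihood
    integrates the Poisson kernel against the lognormal density; with the
    substitution ``c = exp(meanlog + sqrt(2) * sdlog * t)`` the integral
    becomes a Gauss-Hermite sum over t.

    Parameters
    ----------
    counts : sequence of int or None
        Observed counts; ``None`` marks a TNTC entry (see below).
    volumes : sequence of float
        Analytical volumes in liters.
    tntc_thresholds : sequence of int or None, optional
        For TNTC entries, the countability threshold T: the datum is the
        censored event count >= T and contributes the Poisson survival
        probability ``P(X >= T | c V_i)`` inside the integral.
    gh_nodes : int
        Number of Gauss-Hermite quadrature nodes (default 61).
    """

    def __init__(
        self,
        counts: Sequence[int | None],
        volumes: Sequence[float],
        tntc_thresholds: Sequence[int | None] | None = None,
        gh_nodes: int = _GH_NODES_DEFAULT,
    ) -> None:
        volumes = np.asarray(list(volumes), dtype=float)
        counts = list(counts)
        if tntc_thresholds is None:
            tntc_thresholds = [None] * len(counts)
        tntc_thresholds = list(tntc_thresholds)
        if not (len(counts) == len(volumes) == len(tntc_thresholds)):
            raise ValidationError("counts, volumes and thresholds must align")
        if len(counts) < 2:
            raise ValidationError("Poisson-lognormal MLE requires >= 2 samples")
        if np.any(volumes <= 0) or not np.all(np.isfinite(volumes)):
            raise ValidationError("volumes must be finite and > 0")
        for x, t in zip(counts, tntc_thresholds):
            if (x is None) == (t is None):
                raise ValidationError(
                    "each record needs exactly one of count / TNTC threshold"
                )
            if x is not None and (x != int(x) or x < 0):
                raise ValidationError(f"invalid count {x!r}")
            if t is not None and (t != int(t) or t < 1):
                raise ValidationError(f"invalid TNTC threshold {t!r}")
        exact = np.array([t is None for t in tntc_thresholds], dtype=bool)
        if not any(
            (x is not None and x > 0) or t is not None
            for x, t in zip(counts, tntc_thresholds)
        ):
            raise NonIdentifiableError(
                "all counts are zero: the likelihood is maximised only in "
                "the limit of vanishing concentration, so no finite MLE "
                "exists without an informative prior"
            )
        self.counts = np.array([0 if x is None else int(x) for x in counts])
        self.thresholds = np.array(
            [0 if t is None else int(t) for t in tntc_thresholds]
        )
        self.exact = exact
        self.volumes = volumes
        self.nobs = len(counts)
        self.gh_nodes = int(gh_nodes)
        self._gh_t, self._gh_w = np.polynomial.hermite.hermgauss(self.gh_nodes)

    def _sample_likelihoods(self, meanlog: float, sdlog: float) -> np.ndarray:
        """Marginal likelihood of each sample at the given parameters."""
        if sdlog < 1e-10:
            lam = math.exp(meanlog) * self.volumes
            return self._kernel(lam[:, None])[:, 0]
        c = np.exp(meanlog + math.sqrt(2.0) * sdlog * self._gh_t)  # (k,)
        lam = self.volumes[:, None] * c[None, :]  # (n, k)
        vals = self._kernel(lam)  # (n, k)
        return (self._gh_w[None, :] * vals).sum(axis=1) / math.sqrt(math.pi)

    def _kernel(self, lam: np.ndarray) -> np.ndarray:
        """Poisson mass (exact counts) or survival (TNTC) at rate lam."""
        out = np.empty_like(lam)
        ex = self.exact
        if ex.any():
            out[ex] = stats.poisson.pmf(self.counts[ex, None], lam[ex])
        if (~ex).any():
            out[~ex] = stats.poisson.sf(self.thresholds[~ex, None] - 1, lam[~ex])
        return out

    def loglike(self, params) -> float:
        meanlog, sdlog = params
        if sdlog < 0 or not np.isfinite(meanlog) or not np.isfinite(sdlog):
            return -math.inf
        L = self._sample_likelihoods(meanlog, sdlog)
        if np.any(L <= 0) or not np.all(np.isfinite(L)):
            return -math.inf
        return float(np.log(L).sum())

    def loglikeobs(self, params) -> np.ndarray:
        """Per-sample log-likelihood contributions."""
        meanlog, sdlog = params
        return np.log(self._sample_likelihoods(meanlog, sdlog))

    def loglike_quad(self, params) -> float:
        """Adaptive-quadrature evaluation of the same marginal likelihood
        (an independent cross-check on the Gauss-Hermite sum)."""
        meanlog, sdlog = params
        ll = 0.0
        for i in range(self.nobs):
            def integrand(z):
                lam = np.exp(meanlog + sdlog * z) * self.volumes[i]
                lam = np.atleast_2d(lam)
                if self.exact[i]:
                    k = stats.poisson.pmf(self.counts[i], lam)
                else:
                    k = stats.poisson.sf(self.thresholds[i] - 1, lam)
                return float(k.ravel()[0]) * stats.norm.pdf(z)
            val, _ = integrate.quad(integrand, -12, 12, limit=200)
            ll += math.log(val)
        return ll

    def _starts(self) -> list[np.ndarray]:
        pooled = max(self.counts.sum(), 1) / self.volumes.sum()
        s0 = np.array([math.log(pooled), 0.7])  # pooled-mean, moderate spread
        pos = self.counts[self.exact & (self.counts > 0)]
        if pos.size >= 2:
            logs = np.log(pos / self.volumes[self.exact & (self.counts > 0)])
            s1 = np.array([logs.mean(), max(logs.std(ddof=0), 0.3)])
        else:
            s1 = s0 + np.array([0.8, 0.3])
        s2 = s0 + np.array([-0.8, 0.5])
        return [s0, s1, s2]

    def fit(self, approach: str = "") -> LognormalResults:
        def nll(theta):
            return -self.loglike((theta[0], math.exp(theta[1])))

        best = None
        for start in self._starts():
            theta0 = np.array([start[0], math.log(start[1])])
            r = optimize.minimize(
                nll, theta0, method="Nelder-Mead",
                options=dict(xatol=1e-10, fatol=1e-10, maxiter=4000),
            )
            if best is None or r.fun < best.fun - 1e-12:
                best = r
        meanlog, sdlog = best.x[0], math.exp(best.x[1])
        bse_theta = _numerical_bse(nll, best.x)
        bse = np.array([bse_theta[0], bse_theta[1] * sdlog])
        return LognormalResults(
            self, meanlog, sdlog, -best.fun, bool(best.success), approach, bse
        )
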