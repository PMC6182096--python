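"""The five non-detect-handling approaches, compared head to head.

Approaches A-D operate on legacy "reported concentration" records — per
sample either a concentration (count/volume) or a non-detect flagged
"<limit" with limit = 1/volume, the purported per-sample detection limit:

* **A** — omit the non-detects and fit a lognormal to the detects;
* **B** — substitute each non-detect with its limit, then fit;
* **C** — substitute with half its limit, then fit;
* **D** — left-censored lognormal MLE (CDF-at-limit terms for NDs), the
  textbook treatment for censored *continuous* measurements.

Approach **E** uses the raw counts and volumes directly through the
Poisson-lognormal measurement-error model, in which a non-detect is an
observed count of zero — no limit, substitution or censoring involved.
On data where non-detects are frequent, A-D systematically overstate the
mean concentration relative to E.

Each approach returns a :class:`~microcount.models.LognormalResults`.
"""

from __future__ import annotations

import math
from typing import Iterable, Sequence

import numpy as np

from .datatypes import (
    CountObservation,
    NonIdentifiableError,
    ReportedConcentration,
    ValidationError,
)
from .models import (
    CensoredLognormalModel,
    LognormalModel,
    LognormalResults,
    PoissonLognormalModel,
)

__all__ = [
    "to_reported",
    "fit_lognormal_mle",
    "approach_omit",
    "approach_substitute",
    "approach_censored_mle",
    "approach_pln",
    "fit_all_approaches",
    "naive_pooled_mean",
    "bias_ratio",
]


def to_reported(
    observations: Sequence[CountObservation],
) -> list[ReportedConcentration]:
    """Convert raw count records to legacy per-sample concentration reports.

    A detect becomes the ratio count/volume (organisms/L) at full
    precision; a zero count becomes a non-detect with per-sample limit
    1/volume.  TNTC records cannot be expressed as a single reported
    concentration and are rejected.
    """
    out = []
    for obs in observations:
        if obs.is_tntc:
            raise ValidationError(
                f"sample {obs.sample_id!r} is TNTC and has no single "
                "reported-concentration representation"
            )
        if obs.count == 0:
            out.append(
                ReportedConcentration(
                    obs.sample_id, nondetect=True, limit=1.0 / obs.volume
                )
            )
        else:
            out.append(
                ReportedConcentration(obs.sample_id, value=obs.count / obs.volume)
            )
    return out


def fit_lognormal_mle(values: Iterable[float]) -> LognormalResults:
    """Uncensored lognormal MLE on positive concentrations.

    meanlog is the mean of the logs and sdlog their root-mean-square
    deviation with divisor n (the MLE, not the n-1 sample SD).
    """
    return LognormalModel(values).fit()


def _split(data: Sequence[ReportedConcentration]):
    detects = [r.value for r in data if not r.nondetect]
    limits = [r.limit for r in data if r.nondetect]
    return detects, limits


def approach_omit(data: Sequence[ReportedConcentration]) -> LognormalResults:
    """Approach A: drop the non-detects, fit the detects."""
    detects, _ = _split(data)
    if len(detects) < 2:
        raise ValidationError(
            f"approach A needs >= 2 detects, got {len(detects)}"
        )
    return LognormalModel(detects).fit(approach="A")


def approach_substitute(
    data: Sequence[ReportedConcentration], factor: float = 1.0
) -> LognormalResults:
    """Approach B (factor 1.0) or C (factor 0.5): replace each non-detect
    with factor x its per-sample limit, then fit all values."""
    if factor not in (1.0, 0.5):
        raise ValidationError(f"substitution factor must be 1.0 or 0.5, got {factor}")
    detects, limits = _split(data)
    values = detects + [factor * lim for lim in limits]
    label = "B" if factor == 1.0 else "C"
    return LognormalModel(values).fit(approach=label)


def approach_censored_mle(
    data: Sequence[ReportedConcentration],
) -> LognormalResults:
    """Approach D: left-censored lognormal MLE.

    Detects contribute lognormal density terms; each non-detect
    contributes the cumulative density between zero and its per-sample
    limit."""
    detects, limits = _split(data)
    if len(detects) < 1:
        raise ValidationError("approach D needs at least one detect")
    return CensoredLognormalModel(detects, limits).fit(approach="D")


def approach_pln(
    data: Sequence[CountObservation], gh_nodes: int = 61
) -> LognormalResults:
    """Approach E: Poisson-lognormal MLE on raw counts and volumes.

    Exact counts (including zeros) use the Poisson mass; TNTC records use
    the Poisson survival probability of the censored count range.  Raises
    :class:`NonIdentifiableError` when every count is zero.
    """
    counts = [None if o.is_tntc else o.count for o in data]
    thresholds = [o.tntc_threshold for o in data]
    volumes = [o.volume for o in data]
    model = PoissonLognormalModel(counts, volumes, thresholds, gh_nodes=gh_nodes)
    return model.fit(approach="E")


def fit_all_approaches(
    observations: Sequence[CountObservation],
) -> dict[str, LognormalResults]:
    """Run approaches A-E on one raw-count dataset.

    A-D see the legacy reported form of the data (via :func:`to_reported`);
    E sees the raw counts."""
    reported = to_reported(observations)
    return {
        "A": approach_omit(reported),
        "B": approach_substitute(reported, 1.0),
        "C": approach_substitute(reported, 0.5),
        "D": approach_censored_mle(reported),
        "E": approach_pln(observations),
    }


def naive_pooled_mean(data: Sequence[CountObservation]) -> float:
    """Total count over total volume — the volume-weighted pooled mean.

    Treating non-detects as the zeros they are, this is a valid point
    estimate of the mean concentration for a well-mixed source, though it
    says nothing about spread or uncertainty."""
    if len(data) == 0:
        raise ValidationError("naive_pooled_mean requires >= 1 observation")
    if any(o.is_tntc for o in data):
        raise ValidationError("naive_pooled_mean cannot handle TNTC records")
    total = sum(o.count for o in data)
    volume = sum(o.volume for o in data)
    return total / volume


def bias_ratio(
    fits: dict[str, LognormalResults],
) -> dict[str, float]:
    """Ratio of each legacy approach's arithmetic mean to approach E's.

    Returns ``{"A": ..., "B": ..., "C": ..., "D": ..., "min": ..., "max": ...}``.
    A ratio above 1 means the legacy treatment overstates the mean
    concentration relative to the measurement-error model.
    """
    if "E" not in fits:
        raise ValidationError("bias_ratio requires an approach E fit")
    for k, f in fits.items():
        if not f.converged:
            raise ValidationError(f"approach {k} fit did not converge")
    mu_e = fits["E"].arith_mean
    if mu_e == 0:
        raise ValidationError("approach E mean is zero; ratios undefined")
    ratios = {
        k: fits[k].arith_mean / mu_e for k in ("A", "B", "C", "D") if k in fits
    }
    if ratios:
        ratios["min"] = min(v for k, v in ratios.items())
        ratios["max"] = max(v for k, v in ratios.items() if k != "min")
    return ratios
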