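"""Minimal plotting helpers for detection curves and posteriors."""

from __future__ import annotations

import numpy as np

from .datatypes import RecoveryModel
from .detection import prob_nondetect
from .posterior import GammaPosterior

__all__ = ["plot_nondetect_curves", "plot_posterior"]


def plot_nondetect_curves(
    volume: float,
    recoveries: list[RecoveryModel],
    c_max: float = 50.0,
    ax=None,
):
    """Plot P(non-detect) against concentration for each recovery profile."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    c = np.linspace(0, c_max, 400)
    for rec in recoveries:
        p = [prob_nondetect(ci, volume, rec) for ci in c]
        ax.plot(c, p, label=str(rec))
    ax.set_xlabel("concentration (organisms/L)")
    ax.set_ylabel("P(non-detect)")
    ax.set_ylim(0, 1.02)
    ax.legend(title=f"recovery (V = {volume:g} L)")
    return ax


def plot_posterior(
    posterior: GammaPosterior,
    mdl: float | None = None,
    c_max: float | None = None,
    ax=None,
):
    """Plot a concentration posterior density, optionally marking a
    purported detection limit and shading the exceedance region."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    if c_max is None:
        c_max = float(posterior.ppf(0.999))
    c = np.linspace(0, c_max, 400)
    ax.plot(c, posterior.pdf(c), color="k")
    if mdl is not None:
        ax.axvline(mdl, ls="--", color="grey")
        mask = c >= mdl
        ax.fill_between(c[mask], posterior.pdf(c[mask]), alpha=0.3,
                        label=f"P(c > {mdl:g}) = {posterior.sf(mdl):.1%}")
        ax.legend()
    ax.set_xlabel("concentration (organisms/L)")
    ax.set_ylabel("posterior density")
    return ax
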