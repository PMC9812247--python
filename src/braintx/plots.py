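"""Quick-look figures for the main result objects."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg", force=False)
import matplotlib.pyplot as plt
import numpy as np

__all__ = ["plot_rrho_map", "plot_es_curve", "plot_variogram"]


def plot_rrho_map(result, ax=None):
    """Heat map of signed -log10 hypergeometric overlap p-values."""
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 4))
    vmax = np.abs(result.signed_logp).max() or 1.0
    im = ax.imshow(
        result.signed_logp,
        origin="lower",
        aspect="auto",
        cmap="RdBu_r",
        vmin=-vmax,
        vmax=vmax,
        extent=(
            result.thresholds_2[0], result.thresholds_2[-1],
            result.thresholds_1[0], result.thresholds_1[-1],
        ),
    )
    ax.set_xlabel("rank cutoff, list 2")
    ax.set_ylabel("rank cutoff, list 1")
    ax.set_title(f"RRHO (rho_rrho = {result.rho_rrho:+.2f})")
    plt.colorbar(im, ax=ax, label="signed $-\\log_{10} p$")
    return ax.figure


def plot_es_curve(result, ax=None):
    """GSEA running sum with the enrichment score marked."""
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 3))
    pos = np.arange(1, len(result.es_curve) + 1)
    ax.plot(pos, result.es_curve, lw=1.2)
    ax.axhline(0, color="k", lw=0.5)
    ax.plot(result.max_position, result.es, "ro", ms=4)
    ax.set_xlabel("rank position")
    ax.set_ylabel("running sum")
    ax.set_title(f"ES = {result.es:+.3f}" + (f", p = {result.p:.3g}" if result.p is not None else ""))
    return ax.figure


def plot_variogram(empirical, surrogate_gammas=None, ax=None):
    """Empirical semivariogram, optionally with surrogate ensemble spread."""
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 3))
    if surrogate_gammas is not None:
        g = np.asarray(surrogate_gammas)
        ax.fill_between(
            empirical.lags, np.quantile(g, 0.05, axis=0),
            np.quantile(g, 0.95, axis=0), alpha=0.3, label="surrogates (90%)",
        )
        ax.plot(empirical.lags, g.mean(axis=0), lw=1, label="surrogate mean")
    ax.plot(empirical.lags, empirical.gamma, "ko-", ms=3, lw=1, label="empirical")
    ax.set_xlabel("distance (mm)")
    ax.set_ylabel(r"semivariance $\gamma(h)$")
    ax.legend(fontsize=8)
    return ax.figure
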