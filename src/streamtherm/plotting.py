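"""Basic diagnostic plots.

Matplotlib is imported lazily so headless pipeline runs never touch it.
"""

from __future__ import annotations

import numpy as np


def _plt():
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    return plt


def plot_gam(gam_fit, response=None, ax=None, title: str | None = None):
    """Plot one fitted POC curve in the standard layout.

    Fitted curve with shaded 90% confidence band, binned raw occurrence
    points, plus (when a response summary is given) a vertical line at
    the WA optimum and a horizontal bar spanning the 10th–90th occurrence
    percentiles.
    """
    plt = _plt()
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 3.5))
    ax.fill_between(gam_fit.grid, gam_fit.ci_lo, gam_fit.ci_hi, alpha=0.25,
                    color="steelblue", lw=0)
    ax.plot(gam_fit.grid, gam_fit.poc, color="steelblue")
    if gam_fit.binned_poc:
        mids, means = zip(*gam_fit.binned_poc)
        ax.plot(mids, means, "o", color="0.4", ms=4)
    if response is not None:
        ax.axvline(response.wa_optimum, color="firebrick", ls="--", lw=1)
        y = ax.get_ylim()[1] * 0.05
        ax.plot([response.p10, response.p90], [y, y], color="firebrick", lw=3,
                solid_capstyle="butt")
    ax.set_xlabel("MWMT (degC)")
    ax.set_ylabel("Probability of capture")
    if title:
        ax.set_title(title, fontsize=10)
    return ax


def plot_mtti_fit(results, val_counts=None, val_mwmt=None, ax=None):
    """Observed MWMT vs fitted MTTI with the 1:1 line."""
    plt = _plt()
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 5))
    obs = results.model.mwmt
    ax.plot(obs, results.fittedvalues, "o", ms=3, color="black", alpha=0.5,
            label="CAL")
    if val_counts is not None and val_mwmt is not None:
        pred = results.predict(val_counts)["mtti"]
        ax.plot(val_mwmt.loc[pred.index], pred, "^", ms=4, color="firebrick",
                alpha=0.7, label="VAL")
    lims = [min(obs.min(), results.fittedvalues.min()),
            max(obs.max(), results.fittedvalues.max())]
    ax.plot(lims, lims, "k--", lw=1)
    ax.set_xlabel("Observed MWMT (degC)")
    ax.set_ylabel("MTTI (degC)")
    ax.legend(frameon=False)
    return ax


def plot_richness_vs_count(samples, ax=None):
    """Total taxa vs total individuals with a lowess trend.

    Diagnostic for whether fixed-count subsampling would change richness:
    a flat trend above the subsample target indicates it would not.
    """
    plt = _plt()
    from statsmodels.nonparametric.smoothers_lowess import lowess

    if ax is None:
        _, ax = plt.subplots(figsize=(5, 3.5))
    totals = np.array([s.total_count for s in samples], float)
    rich = np.array([s.richness for s in samples], float)
    ax.plot(totals, rich, "o", ms=3, alpha=0.4, color="0.4")
    if len(totals) >= 10:
        sm = lowess(rich, totals, frac=0.5, return_sorted=True)
        ax.plot(sm[:, 0], sm[:, 1], color="firebrick")
    ax.set_xlabel("Total individuals")
    ax.set_ylabel("Total taxa")
    return ax
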