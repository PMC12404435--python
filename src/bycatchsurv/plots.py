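"""Small diagnostic figures for fitted objects."""

from __future__ import annotations

import numpy as np


def plot_posterior_trace(posterior, ax=None):
    """Trace plot of the daily-survival chains (one line per chain)."""
    import matplotlib.pyplot as plt
    from scipy.special import expit
    if ax is None:
        _, ax = plt.subplots(figsize=(7, 3))
    for c, chain in enumerate(posterior.beta0_samples):
        ax.plot(expit(chain), lw=0.7, label=f"chain {c + 1}")
    ax.set_xlabel("retained draw")
    ax.set_ylabel(r"daily survival $\phi$")
    ax.legend(frameon=False, fontsize=8)
    ax.set_title(f"known-fate posterior (R-hat = {posterior.rhat:.3f})")
    return ax


def plot_bycatch_distribution(result, ax=None):
    """Histogram of replicate bycatch-survival proportions."""
    import matplotlib.pyplot as plt
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 3))
    ax.hist(result.proportions, bins=30, color="steelblue", alpha=0.8)
    lo, hi = result.interval()
    for x, style in ((result.bs_mean, "-"), (lo, "--"), (hi, "--")):
        ax.axvline(x, color="k", ls=style, lw=1)
    ax.set_xlabel("proportion surviving capture and release")
    ax.set_ylabel("replicates")
    ax.set_title(f"{result.region}: BS = {result.bs_mean:.2f} "
                 f"({lo:.2f}-{hi:.2f})")
    return ax


def plot_tag_series(series, ax=None):
    """Depth (inverted axis) and temperature trace for one tag."""
    import matplotlib.pyplot as plt
    if ax is None:
        _, ax = plt.subplots(figsize=(8, 3))
    days = series["elapsed_min"] / 1440.0
    ax.plot(days, series["depth_m"], lw=0.5, color="navy")
    ax.invert_yaxis()
    ax.set_xlabel("days since release")
    ax.set_ylabel("depth (m)", color="navy")
    ax2 = ax.twinx()
    ax2.plot(days, series["temp_c"], lw=0.5, color="firebrick", alpha=0.7)
    ax2.set_ylabel("temperature (degC)", color="firebrick")
    return ax
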