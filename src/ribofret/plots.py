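"""Figure export: post-synchronized heatmaps, FRET histograms, dwell CDFs.

Thin matplotlib wrappers over the analysis containers; all underlying
matrices are also exportable as tabular files for re-plotting elsewhere.
"""

from __future__ import annotations

import numpy as np

__all__ = ["plot_sync_heatmap", "plot_fret_histogram", "plot_dwell_cdf"]


def plot_sync_heatmap(heatmap, ax=None, cmap="viridis", fret_limits=(0.0, 0.6)):
    """Render a post-synchronized FRET density map (time offset vs FRET)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(5, 3.2))
    m = ax.pcolormesh(heatmap.time_edges, heatmap.fret_edges, heatmap.density,
                      cmap=cmap, shading="flat")
    ax.set_xlabel("time from synchronization (s)")
    ax.set_ylabel("FRET efficiency")
    ax.set_ylim(*fret_limits)
    ax.figure.colorbar(m, ax=ax, label="density")
    ax.set_title(f"{heatmap.event}  (n = {heatmap.n_traces})")
    return ax


def plot_fret_histogram(values, gaussian_fit=None, ax=None, bin_width=0.02):
    """Pooled FRET histogram with an optional Gaussian-mixture overlay."""
    import matplotlib.pyplot as plt
    from scipy.stats import norm

    if ax is None:
        _, ax = plt.subplots(figsize=(4.5, 3.2))
    v = np.asarray(values, dtype=float)
    v = v[np.isfinite(v)]
    bins = np.arange(-0.1, 1.1 + bin_width, bin_width)
    ax.hist(np.clip(v, 0, 1), bins=bins, density=True, alpha=0.6, color="grey")
    if gaussian_fit is not None:
        x = np.linspace(-0.1, 1.1, 500)
        total = np.zeros_like(x)
        for w, m, s in zip(gaussian_fit.weights, gaussian_fit.means, gaussian_fit.sds):
            comp = w * norm.pdf(x, m, s)
            total += comp
            ax.plot(x, comp, "--", lw=1)
        ax.plot(x, total, "k-", lw=1.5)
    ax.set_xlabel("FRET efficiency")
    ax.set_ylabel("density")
    ax.set_xlim(0, 0.7)
    return ax


def plot_dwell_cdf(fit, ax=None, label=None):
    """Cumulative-probability plot of dwell times with the fitted overlay."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(4.5, 3.2))
    if fit.curve is None or fit.curve.empty:
        raise ValueError("fit carries no cumulative-probability curve data")
    ax.step(fit.curve["t_s"], fit.curve["empirical_cdf"], where="post",
            label=label or "observed")
    ax.plot(fit.curve["t_s"], fit.curve["fitted_cdf"], "r-", lw=1.2,
            label=f"{fit.model} fit")
    ax.set_xlabel("dwell time (s)")
    ax.set_ylabel("cumulative probability")
    ax.legend(frameon=False)
    return ax
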