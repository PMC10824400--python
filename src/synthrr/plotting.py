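"""Optional plotting layer over the metric tables.

All figures are regenerated from data (the CSV/metric tables come
first); plotting is deliberately thin so comparisons are made on
numbers, not pixels.  Matplotlib is imported lazily.
"""

from __future__ import annotations

__all__ = ["plot_rmse_curves", "plot_bias_stddev"]


def _pyplot():
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    return plt


def plot_rmse_curves(series_by_method: dict, title: str = "", ax=None):
    """RMSE versus iteration for several methods on one axis."""
    plt = _pyplot()
    if ax is None:
        _, ax = plt.subplots()
    for method, ms in series_by_method.items():
        df = ms.per_iteration
        ax.plot(df["iteration"], df["rmse"], label=method)
    ax.set_xlabel("iteration")
    ax.set_ylabel("normalised RMSE (%)")
    ax.set_title(title)
    ax.legend()
    return ax


def plot_bias_stddev(series_by_method: dict, title: str = "", ax=None):
    """Bias versus standard deviation tradeoff paths."""
    plt = _pyplot()
    if ax is None:
        _, ax = plt.subplots()
    for method, ms in series_by_method.items():
        df = ms.per_iteration
        ax.plot(df["bias"], df["stddev"], label=method)
    ax.set_xlabel("bias (%)")
    ax.set_ylabel("standard deviation (%)")
    ax.set_title(title)
    ax.legend()
    return ax
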