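"""Bias / standard deviation / RMSE over noise realizations and ROIs.

For Q noise realizations reconstructed in parallel, at iteration k and
over an ROI Omega with true values theta_ref:

    Bias   = sqrt( sum_j (mean_q theta_j - theta_ref_j)^2 / sum_j theta_ref_j^2 )
    StdDev = sqrt( (1/Q) sum_q sum_j (mean_q theta_j - theta_j^(q))^2
                   / sum_j theta_ref_j^2 )
    RMSE   = sqrt( Bias^2 + StdDev^2 )

All three are reported as percentages of the truth's root energy on
the ROI.  The standard deviation uses the 1/Q (population) convention
deliberately — deviations are taken about the across-realization mean
at the same iteration — so anyone comparing against a 1/(Q-1) sample
convention will see slightly smaller values here.  RMSE is never
stored independently: it is always derived from its two components,
so the Pythagorean identity holds structurally.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .phantoms import ActivityImage, ROIMask

__all__ = [
    "MetricSeries",
    "metric_record",
    "compute_metrics",
    "min_rmse",
    "bias_stddev_trajectory",
]


@dataclass(frozen=True)
class MetricSeries:
    """Per-iteration bias/stddev/RMSE (in percent) for one ROI.

    ``per_iteration`` has columns iteration, bias, stddev, rmse, in
    increasing iteration order.
    """

    per_iteration: pd.DataFrame
    roi: ROIMask
    Q: int

    def __post_init__(self) -> None:
        df = self.per_iteration
        required = {"iteration", "bias", "stddev", "rmse"}
        if not required.issubset(df.columns):
            raise ValueError(f"per_iteration must have columns {sorted(required)}")
        if len(df) == 0:
            raise ValueError("metric series is empty")
        if (df[["bias", "stddev", "rmse"]].to_numpy() < 0).any():
            raise ValueError("metrics must be nonnegative")

    def __len__(self) -> int:
        return len(self.per_iteration)


def _roi_truth(truth: ActivityImage, roi: ROIMask) -> tuple[np.ndarray, float]:
    ii, jj = roi.indices()
    ref = truth.values[ii, jj]
    norm = float(np.sum(ref**2))
    if norm == 0:
        raise ValueError("truth is identically zero on the ROI; normaliser vanishes")
    return ref, norm


def metric_record(
    stack: np.ndarray, ref: np.ndarray, norm: float
) -> tuple[float, float, float]:
    """(bias, stddev, rmse) in percent for one iteration.

    ``stack`` holds the ROI pixel values of the Q realizations as a
    (Q, n_roi) array; ``ref``/``norm`` come from :func:`_roi_truth`.
    """
    Q = stack.shape[0]
    mean = stack.mean(axis=0)
    bias = np.sqrt(np.sum((mean - ref) ** 2) / norm)
    std = np.sqrt(np.sum((mean[None, :] - stack) ** 2) / (Q * norm))
    rmse = np.hypot(bias, std)
    return 100.0 * bias, 100.0 * std, 100.0 * rmse


def compute_metrics(results, truth: ActivityImage, roi: ROIMask) -> MetricSeries:
    """Metric series from Q reconstruction results with recorded iterates.

    All results must share the same recorded iteration grid; metrics
    are computed at each recorded iteration.
    """
    results = list(results)
    if not results:
        raise ValueError("at least one reconstruction result is required")
    iters = sorted(results[0].recorded_iterates)
    for r in results[1:]:
        if sorted(r.recorded_iterates) != iters:
            raise ValueError("results do not share a recorded iteration grid")
    for r in results:
        img = r.final_image
        if img.grid_size != truth.grid_size:
            raise ValueError("reconstruction grid does not match the truth")
    ref, norm = _roi_truth(truth, roi)
    ii, jj = roi.indices()
    rows = []
    for k in iters:
        stack = np.stack([r.recorded_iterates[k].values[ii, jj] for r in results])
        bias, std, rmse = metric_record(stack, ref, norm)
        rows.append((k, bias, std, rmse))
    df = pd.DataFrame(rows, columns=["iteration", "bias", "stddev", "rmse"])
    return MetricSeries(df, roi, len(results))


def min_rmse(series: MetricSeries) -> tuple[int, float]:
    """Earliest iteration attaining the minimum RMSE, and that RMSE."""
    df = series.per_iteration
    idx = int(df["rmse"].to_numpy().argmin())  # argmin returns the first minimum
    return int(df["iteration"].iloc[idx]), float(df["rmse"].iloc[idx])


def bias_stddev_trajectory(series: MetricSeries) -> list[tuple[float, float]]:
    """Per-iteration (bias, stddev) path for tradeoff plots."""
    df = series.per_iteration
    return list(zip(df["bias"].tolist(), df["stddev"].tolist()))
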