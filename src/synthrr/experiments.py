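"""Config-driven orchestration of the simulation comparison studies.

A single :class:`ExperimentConfig` describes a study: phantom, PSF,
native and virtual scanner geometries, count levels, the input-image
iteration count K, realization counts Q, iteration budget and base
seed.  The four study drivers mirror the evaluation axes of the
method-comparison framework:

- :func:`run_method_comparison` — MLEM, MLEM+PSF, Richardson-Lucy,
  the synthesized method with PSF modelling ("proposed") and without
  ("proposed_noPSF"), at each count level, with per-ROI metric series.
- :func:`run_angle_sweep` — proposed-method performance versus the
  number of projection angles in the virtual geometry.
- :func:`run_sigma_sweep` — performance versus the line-thickness
  sigma of the virtual geometry.
- :func:`run_input_quality_sweep` — performance versus the iteration
  count K of the supplied MLEM input image.

Every run is exactly reproducible from its config: all randomness
derives from ``base_seed`` (realization q of count level i uses seed
``base_seed + 1000*i + q``).  Results are returned as pandas tables
(and written as CSV plus a YAML manifest when ``output_dir`` is set);
plotting is a separate, optional layer.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .metrics import MetricSeries, _roi_truth, metric_record, min_rmse
from .phantoms import (
    ActivityImage,
    ROIMask,
    make_derenzo,
    make_roi_masks,
    make_shepp_logan,
    make_thorax,
)
from .projectors import ProjectionGeometry, _operators, sensitivity_image
from .psf_models import gaussian_kernel
from .reconstruction import _em_run, _psf_ops, _uniform_circle_init
from .simulation import COUNT_LEVELS, CountLevel, count_scale, make_realizations

__all__ = [
    "ExperimentConfig",
    "ComparisonResult",
    "run_method_comparison",
    "run_angle_sweep",
    "run_sigma_sweep",
    "run_input_quality_sweep",
    "METHODS",
]

logger = logging.getLogger("synthrr.experiments")

METHODS = ("MLEM", "MLEM+PSF", "RL", "proposed", "proposed_noPSF")

#: the "standard number" of iterations at which snapshot images are kept
STANDARD_ITERATION = 64


@dataclass(frozen=True)
class ExperimentConfig:
    """Full description of one simulation study (seed-reproducible)."""

    phantom: str = "shepp-logan"  # {"shepp-logan", "thorax", "derenzo"}
    grid_size: int = 128
    pixel_size_mm: float = 1.0
    psf_fwhm_mm: float = 2.9
    n_native_angles: int = 180
    n_virtual_angles: int = 180
    line_sigma_px: float = 0.0
    count_levels: tuple = ("high", "mid", "low")
    count_level_totals: dict | None = None  # overrides COUNT_LEVELS totals
    K: int = 64
    Q: int = 10
    Q_small: int = 100
    n_iterations: int = 500
    epsilon: float = 1e-12
    base_seed: int = 1234
    output_dir: str | None = None

    def __post_init__(self) -> None:
        if self.phantom not in {"shepp-logan", "thorax", "derenzo"}:
            raise ValueError(f"unknown phantom {self.phantom!r}")
        if self.K < 1 or self.Q < 1 or self.n_iterations < 1:
            raise ValueError("K, Q and n_iterations must be >= 1")
        object.__setattr__(self, "count_levels", tuple(self.count_levels))

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ExperimentConfig":
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "ExperimentConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    # -- derived pieces -----------------------------------------------------

    def make_truth(self) -> ActivityImage:
        if self.phantom == "shepp-logan":
            return make_shepp_logan(self.grid_size, self.pixel_size_mm)
        if self.phantom == "thorax":
            return make_thorax(self.grid_size, self.pixel_size_mm)
        return make_derenzo(
            [1.1, 1.5, 2.3, 3.1, 3.9, 4.7], 4.0, self.grid_size, self.pixel_size_mm
        )

    def make_psf(self):
        return gaussian_kernel(self.psf_fwhm_mm, self.pixel_size_mm)

    def native_geometry(self) -> ProjectionGeometry:
        return ProjectionGeometry.native(
            self.grid_size, self.pixel_size_mm, self.n_native_angles
        )

    def virtual_geometry(
        self, n_angles: int | None = None, line_sigma_px: float | None = None
    ) -> ProjectionGeometry:
        return ProjectionGeometry.native(
            self.grid_size,
            self.pixel_size_mm,
            self.n_virtual_angles if n_angles is None else n_angles,
            self.line_sigma_px if line_sigma_px is None else line_sigma_px,
        )

    def level(self, name: str) -> CountLevel:
        if self.count_level_totals and name in self.count_level_totals:
            return CountLevel(name, float(self.count_level_totals[name]))
        return COUNT_LEVELS[name]

    def rois(self, truth: ActivityImage) -> dict[str, ROIMask]:
        if self.phantom == "thorax":
            g, m, s = make_roi_masks(truth)
            return {"global": g, "medium": m, "small": s}
        g = truth.grid_size
        return {
            "global": ROIMask(
                frozenset((i, j) for i in range(g) for j in range(g)), "global", g
            )
        }


# ---------------------------------------------------------------------------
# batched EM engine with streaming metrics


class _MetricCollector:
    """Streams (bias, stddev, rmse) rows per ROI during a batched EM run."""

    def __init__(self, truth: ActivityImage, rois: dict[str, ROIMask]):
        self.rois = rois
        self._prep = {}
        g = truth.grid_size
        for name, roi in rois.items():
            ref, norm = _roi_truth(truth, roi)
            ii, jj = roi.indices()
            self._prep[name] = (ii * g + jj, ref, norm)
        self.rows: dict[str, list] = {name: [] for name in rois}

    def __call__(self, k: int, x: np.ndarray) -> None:
        for name, (flat_idx, ref, norm) in self._prep.items():
            stack = x[flat_idx, :].T  # (Q, n_roi)
            self.rows[name].append((k,) + metric_record(stack, ref, norm))

    def series(self, Q: int) -> dict[str, MetricSeries]:
        out = {}
        for name, rows in self.rows.items():
            df = pd.DataFrame(rows, columns=["iteration", "bias", "stddev", "rmse"])
            out[name] = MetricSeries(df, self.rois[name], Q)
        return out


class _SnapshotCollector:
    """Keeps every iterate of realization 0 (for snapshot images)."""

    def __init__(self):
        self.iterates: dict[int, np.ndarray] = {}

    def __call__(self, k: int, x: np.ndarray) -> None:
        self.iterates[k] = x[:, 0].copy()


def _chain(*callbacks):
    active = [c for c in callbacks if c is not None]

    def cb(k, x):
        for c in active:
            c(k, x)

    return cb


def _projection_model(geometry, grid, pixel, psf):
    """(fwd, adj, sens) for the project-after-blur Poisson model."""
    fwd_p, adj_p = _operators(geometry, grid, pixel)
    blur, blur_adj = _psf_ops(psf, grid)
    sens = sensitivity_image(geometry, grid, psf, pixel).values.ravel()
    return (lambda x: fwd_p(blur(x))), (lambda y: blur_adj(adj_p(y))), sens


def _deconv_model(psf, grid):
    """(fwd, adj, sens) for the image-space deconvolution model."""
    blur, blur_adj = _psf_ops(psf, grid)
    sens = blur_adj(np.ones((grid * grid, 1)))[:, 0]
    return blur, blur_adj, sens


def _mlem_inputs(
    data: np.ndarray, geometry, grid, pixel, K: int, epsilon: float,
    snapshots_at: frozenset = frozenset(),
) -> tuple[np.ndarray, dict[int, np.ndarray]]:
    """Batch-MLEM the measured data for K iterations (no PSF model).

    Returns the theta(K) stack and, optionally, stacks snapshotted at
    intermediate iteration numbers.
    """
    fwd, adj, sens = _projection_model(geometry, grid, pixel, None)
    init = np.tile(_uniform_circle_init(grid), (1, data.shape[1]))
    taken: dict[int, np.ndarray] = {}

    def cb(k, x):
        if k in snapshots_at:
            taken[k] = x.copy()

    final, _, _ = _em_run(data, fwd, adj, sens, init, K, epsilon, callback=cb)
    return final, taken


def _run_method(
    method: str,
    *,
    data: np.ndarray,
    theta_k: np.ndarray | None,
    config: ExperimentConfig,
    psf,
    native_geometry,
    virtual_geometry,
    collector,
    n_iterations: int | None = None,
) -> None:
    """Dispatch one method's batched EM run, streaming into ``collector``."""
    grid, pixel = config.grid_size, config.pixel_size_mm
    n_it = config.n_iterations if n_iterations is None else n_iterations
    Q = data.shape[1] if method in ("MLEM", "MLEM+PSF") else theta_k.shape[1]
    if method == "MLEM":
        fwd, adj, sens = _projection_model(native_geometry, grid, pixel, None)
        run_data = data
        init = np.tile(_uniform_circle_init(grid), (1, Q))
    elif method == "MLEM+PSF":
        fwd, adj, sens = _projection_model(native_geometry, grid, pixel, psf)
        run_data = data
        init = np.tile(_uniform_circle_init(grid), (1, Q))
    elif method == "RL":
        fwd, adj, sens = _deconv_model(psf, grid)
        run_data = theta_k
        init = theta_k.copy()
    elif method in ("proposed", "proposed_noPSF"):
        kernel = psf if method == "proposed" else None
        geo_fwd, _ = _operators(virtual_geometry, grid, pixel)
        run_data = geo_fwd(theta_k)  # m_syn = S theta(K), noiseless
        fwd, adj, sens = _projection_model(virtual_geometry, grid, pixel, kernel)
        init = np.tile(_uniform_circle_init(grid), (1, Q))
    else:
        raise ValueError(f"unknown method {method!r}")
    logger.info("running %s: %d iterations, Q=%d", method, n_it, Q)
    _em_run(run_data, fwd, adj, sens, init, n_it, config.epsilon, callback=collector)


# ---------------------------------------------------------------------------
# study drivers


@dataclass
class ComparisonResult:
    """Tables and metric series from :func:`run_method_comparison`."""

    summary: pd.DataFrame
    series: dict  # (level, method, roi) -> MetricSeries
    snapshots: dict  # (level, method, kind) -> ActivityImage
    config: ExperimentConfig


def run_method_comparison(
    config: ExperimentConfig, methods: tuple = METHODS
) -> ComparisonResult:
    """Compare the reconstruction methods at every configured count level.

    For each (count level, method): per-ROI metric series over the
    iteration budget, a min-RMSE summary row per ROI, and snapshot
    images of realization 0 at the global min-RMSE iteration and at
    the standard iteration 64.  The thorax phantom additionally
    evaluates the medium ROI (with Q realizations) and the small ROI
    (with ``Q_small`` realizations); other phantoms use the global ROI
    only.
    """
    truth = config.make_truth()
    psf = config.make_psf()
    native = config.native_geometry()
    virtual = config.virtual_geometry()
    rois = config.rois(truth)
    big_rois = {n: r for n, r in rois.items() if n != "small"}

    series: dict = {}
    snapshots: dict = {}
    rows = []
    batches = [(big_rois, config.Q, 0)]
    if "small" in rois:
        batches.append(({"small": rois["small"]}, config.Q_small, 500))
    for li, level_name in enumerate(config.count_levels):
        level = config.level(level_name)
        # reconstructions live on the count scale of the data; the truth
        # is brought onto the same scale before computing bias/RMSE
        scale = count_scale(truth, psf, native, level)
        truth_scaled = truth.with_values(truth.values * scale)
        for batch_rois, Q, seed_off in batches:
            seed = config.base_seed + 1000 * li + seed_off
            real = make_realizations(truth, psf, native, level, Q, seed)
            data = real.stack()
            theta_k, _ = _mlem_inputs(
                data, native, config.grid_size, config.pixel_size_mm,
                config.K, config.epsilon,
            )
            for method in methods:
                coll = _MetricCollector(truth_scaled, batch_rois)
                snap = _SnapshotCollector() if seed_off == 0 else None
                _run_method(
                    method,
                    data=data,
                    theta_k=theta_k,
                    config=config,
                    psf=psf,
                    native_geometry=native,
                    virtual_geometry=virtual,
                    collector=_chain(coll, snap),
                )
                for roi_name, ms in coll.series(Q).items():
                    series[(level_name, method, roi_name)] = ms
                    it, val = min_rmse(ms)
                    rows.append((level_name, method, roi_name, Q, it, val))
                if snap is not None:
                    g = config.grid_size
                    it_min, _ = min_rmse(series[(level_name, method, "global")])
                    for kind, it in (
                        ("min_rmse", it_min),
                        ("standard", min(STANDARD_ITERATION, config.n_iterations)),
                    ):
                        snapshots[(level_name, method, kind)] = ActivityImage(
                            snap.iterates[it].reshape(g, g),
                            config.pixel_size_mm,
                            label=f"{method}@{kind}:{it}",
                        )
    summary = pd.DataFrame(
        rows,
        columns=["count_level", "method", "roi", "Q", "min_rmse_iteration",
                 "min_rmse_pct"],
    )
    result = ComparisonResult(summary, series, snapshots, config)
    _maybe_write_comparison(result)
    return result


def _sweep_common(config: ExperimentConfig):
    """Truth, PSF, native geometry, realizations and MLEM inputs for sweeps.

    Sweeps use the first configured count level.
    """
    truth = config.make_truth()
    psf = config.make_psf()
    native = config.native_geometry()
    rois = {"global": config.rois(truth)["global"]}
    level = config.level(config.count_levels[0])
    real = make_realizations(
        truth, psf, native, level, config.Q, config.base_seed
    )
    data = real.stack()
    scale = count_scale(truth, psf, native, level)
    truth_scaled = truth.with_values(truth.values * scale)
    return truth_scaled, psf, native, rois, level, data


def _min_rmse_of(method, *, config, data, theta_k, psf, native, virtual,
                 truth, rois) -> tuple[int, float]:
    coll = _MetricCollector(truth, rois)
    _run_method(
        method, data=data, theta_k=theta_k, config=config, psf=psf,
        native_geometry=native, virtual_geometry=virtual, collector=coll,
    )
    return min_rmse(coll.series(data.shape[1])["global"])


def _comparator_rows(config, data, theta_k, psf, native, truth, rois,
                     sweep_col: str) -> list:
    rows = []
    for method in ("MLEM", "MLEM+PSF", "RL"):
        it, val = _min_rmse_of(
            method, config=config, data=data, theta_k=theta_k, psf=psf,
            native=native, virtual=None, truth=truth, rois=rois,
        )
        rows.append((method, None, it, val))
    return rows


def run_angle_sweep(config: ExperimentConfig, max_angles_list) -> pd.DataFrame:
    """Proposed-method min-RMSE versus virtual-geometry angle count.

    Each entry N defines synthetic projection angles 1..N degrees in
    1-degree steps; the input image is always the MLEM K-iteration
    reconstruction at native sampling.  Comparator methods appear as
    reference rows (they do not depend on the synthetic angles).
    """
    max_angles_list = [int(n) for n in max_angles_list]
    if any(n < 1 or n > 180 for n in max_angles_list):
        raise ValueError("angle counts must lie in 1..180")
    truth, psf, native, rois, level, data = _sweep_common(config)
    theta_k, _ = _mlem_inputs(
        data, native, config.grid_size, config.pixel_size_mm,
        config.K, config.epsilon,
    )
    rows = _comparator_rows(config, data, theta_k, psf, native, truth, rois,
                            "max_angle_deg")
    for n in max_angles_list:
        virtual = config.virtual_geometry(n_angles=n)
        it, val = _min_rmse_of(
            "proposed", config=config, data=data, theta_k=theta_k, psf=psf,
            native=native, virtual=virtual, truth=truth, rois=rois,
        )
        rows.append(("proposed", n, it, val))
    df = pd.DataFrame(
        rows, columns=["method", "max_angle_deg", "min_rmse_iteration",
                       "min_rmse_pct"],
    )
    _maybe_write_table(config, df, "angle_sweep")
    return df


def run_sigma_sweep(config: ExperimentConfig, sigma_list) -> pd.DataFrame:
    """Proposed-method min-RMSE versus line-thickness sigma (pixels).

    Sigma widens the virtual scanner's line integrals by Gaussian
    blurring of the input image before projection; the identical blur
    is part of the virtual system model during the synthesized
    reconstruction, so the introduced blur is recovered.
    """
    sigma_list = [float(s) for s in sigma_list]
    if any(s < 0 for s in sigma_list):
        raise ValueError("sigma values must be nonnegative")
    truth, psf, native, rois, level, data = _sweep_common(config)
    theta_k, _ = _mlem_inputs(
        data, native, config.grid_size, config.pixel_size_mm,
        config.K, config.epsilon,
    )
    rows = _comparator_rows(config, data, theta_k, psf, native, truth, rois,
                            "sigma_px")
    for s in sigma_list:
        virtual = config.virtual_geometry(line_sigma_px=s)
        it, val = _min_rmse_of(
            "proposed", config=config, data=data, theta_k=theta_k, psf=psf,
            native=native, virtual=virtual, truth=truth, rois=rois,
        )
        rows.append(("proposed", s, it, val))
    df = pd.DataFrame(
        rows, columns=["method", "sigma_px", "min_rmse_iteration", "min_rmse_pct"],
    )
    _maybe_write_table(config, df, "sigma_sweep")
    return df


def run_input_quality_sweep(config: ExperimentConfig, K_list) -> pd.DataFrame:
    """RL and proposed-method min-RMSE versus input-image iterations K.

    One batched MLEM run to max(K_list) supplies the input image at
    every requested K; MLEM and MLEM+PSF reference rows are constant
    (they operate on the sinogram, not on an input image).
    """
    K_list = sorted(int(k) for k in K_list)
    if any(k < 1 for k in K_list):
        raise ValueError("K values must be >= 1")
    truth, psf, native, rois, level, data = _sweep_common(config)
    virtual = config.virtual_geometry()
    _, taken = _mlem_inputs(
        data, native, config.grid_size, config.pixel_size_mm,
        max(K_list), config.epsilon, snapshots_at=frozenset(K_list),
    )
    rows = []
    for method in ("MLEM", "MLEM+PSF"):
        it, val = _min_rmse_of(
            method, config=config, data=data, theta_k=None, psf=psf,
            native=native, virtual=virtual, truth=truth, rois=rois,
        )
        rows.extend((method, k, it, val) for k in K_list)
    for k in K_list:
        for method in ("RL", "proposed"):
            it, val = _min_rmse_of(
                method, config=config, data=data, theta_k=taken[k], psf=psf,
                native=native, virtual=virtual, truth=truth, rois=rois,
            )
            rows.append((method, k, it, val))
    df = pd.DataFrame(
        rows, columns=["method", "K", "min_rmse_iteration", "min_rmse_pct"],
    )
    _maybe_write_table(config, df, "input_quality_sweep")
    return df


# ---------------------------------------------------------------------------
# output


def _maybe_write_table(config: ExperimentConfig, df: pd.DataFrame, name: str) -> None:
    if config.output_dir is None:
        return
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    df.to_csv(out / f"{name}.csv", index=False)
    config.to_yaml(out / "manifest.yaml")


def _maybe_write_comparison(result: ComparisonResult) -> None:
    config = result.config
    if config.output_dir is None:
        return
    from .io import save_image

    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    result.summary.to_csv(out / "min_rmse_summary.csv", index=False)
    for (level, method, roi), ms in result.series.items():
        df = ms.per_iteration.copy()
        df["roi"] = roi
        df["method"] = method
        df["count_level"] = level
        df["seed_base"] = config.base_seed
        safe = method.replace("+", "_")
        df.to_csv(out / f"metrics_{level}_{safe}_{roi}.csv", index=False)
    for (level, method, kind), img in result.snapshots.items():
        safe = method.replace("+", "_")
        save_image(img, out / f"image_{level}_{safe}_{kind}.nii")
    config.to_yaml(out / "manifest.yaml")
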