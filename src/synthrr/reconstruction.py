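"""EM-family reconstruction: MLEM, MLEM+PSF, Richardson-Lucy, and
synthesized reconstruction.

All four algorithms are multiplicative expectation-maximisation
updates for a Poisson model ``data ~ Poisson(H theta)`` and share one
iteration engine; they differ only in the operator ``H`` and the data:

=======================  =======================  ====================
algorithm                forward operator H       data
=======================  =======================  ====================
MLEM                     X (projector)            measured sinogram m
MLEM+PSF                 X P (project o blur)     measured sinogram m
Richardson-Lucy          P (blur)                 input image theta(K)
synthesized recon        S P (virtual projector)  m_syn = S theta(K)
=======================  =======================  ====================

The generic update is ``theta <- theta / (H^T 1) * H^T(data / H theta)``,
which preserves nonnegativity and monotonically non-decreases the
Poisson log-likelihood of its data under its forward model.

The synthesized method is the package's namesake: an existing
reconstruction theta(K) — typically MLEM stopped at K iterations
without resolution modelling — is forward projected through a virtual
scanner S to synthesise noiseless, model-consistent sinogram data,
which are then reconstructed *with* the positron-range PSF in the
system model.  This recovers resolution like Richardson-Lucy
deconvolution but with the noise build-up damped by the tomographic
reconstruction operator.

The module follows a model/results organisation: construct a model
object from data, call :meth:`fit`, inspect the returned
:class:`EMResults`.  Thin functional wrappers (:func:`mlem`,
:func:`mlem_psf`, :func:`richardson_lucy`, :func:`synthesize_data`,
:func:`synthesized_recon`) cover the same operations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .phantoms import ActivityImage
from .projectors import (
    ProjectionGeometry,
    Sinogram,
    _operators,
    forward_project,
    sensitivity_image,
)
from .psf_models import PSFKernel, _convolve

__all__ = [
    "ReconConfig",
    "EMResults",
    "MLEM",
    "RichardsonLucy",
    "SynthesizedReconstruction",
    "mlem",
    "mlem_psf",
    "richardson_lucy",
    "synthesize_data",
    "synthesized_recon",
]


@dataclass(frozen=True)
class ReconConfig:
    """Iteration budget and numerical guards for an EM fit.

    ``epsilon`` is a relative division guard: denominators are clamped
    below at ``epsilon * max(denominator)``.  ``record_every`` selects
    which iterates are kept (None keeps only the final image).
    """

    n_iterations: int = 500
    epsilon: float = 1e-12
    record_every: int | None = None
    initial_image: ActivityImage | None = None

    def __post_init__(self) -> None:
        if self.n_iterations < 1:
            raise ValueError("n_iterations must be >= 1")
        if not (self.epsilon > 0):
            raise ValueError("epsilon must be positive")
        if self.record_every is not None and self.record_every < 1:
            raise ValueError("record_every must be >= 1 or None")


def _em_run(
    data: np.ndarray,
    fwd,
    adj,
    sens: np.ndarray,
    init: np.ndarray,
    n_iterations: int,
    epsilon: float,
    record_iters: frozenset = frozenset(),
    callback=None,
):
    """Generic multiplicative EM loop on flat (n, Q) stacks.

    Returns ``(final, records, loglik)`` where ``records`` maps the
    requested iteration numbers to copies of the iterate and ``loglik``
    is the per-iteration Poisson log-likelihood summed over
    realizations.  ``callback(k, x)`` runs after every update.
    """
    tiny = np.finfo(float).tiny
    sens_col = sens.reshape(-1, 1)
    alive = sens_col > 0
    inv_sens = np.where(alive, 1.0 / np.maximum(sens_col, tiny), 0.0)
    x = np.where(alive, init, 0.0)
    records: dict[int, np.ndarray] = {}
    loglik = np.empty(n_iterations)
    positive = data > 0
    for k in range(1, n_iterations + 1):
        proj = fwd(x)
        floor = np.maximum(epsilon * proj.max(axis=0, keepdims=True), tiny)
        safe = np.maximum(proj, floor)
        ratio = np.where(positive, data / safe, 0.0)
        x = x * inv_sens * adj(ratio)
        ll = np.where(positive, data * np.log(safe), 0.0) - proj
        loglik[k - 1] = float(ll.sum())
        if k in record_iters:
            records[k] = x.copy()
        if callback is not None:
            callback(k, x)
    return x, records, loglik


class EMResults:
    """Fit results: final image, recorded iterates, diagnostics.

    Attributes
    ----------
    final_image : ActivityImage
        The iterate after the last iteration.
    recorded_iterates : dict[int, ActivityImage]
        Iterates kept according to ``config.record_every`` (the final
        iteration is always included).
    log : pandas.DataFrame
        One row per iteration with the Poisson log-likelihood of the
        model's own data under its forward model.
    """

    def __init__(self, model, config, final_image, recorded_iterates, loglik):
        self.model = model
        self.config = config
        self.final_image = final_image
        self.recorded_iterates = recorded_iterates
        self.log = pd.DataFrame(
            {"iteration": np.arange(1, loglik.size + 1), "loglik": loglik}
        )

    @property
    def n_iterations(self) -> int:
        return self.config.n_iterations

    @property
    def loglik(self) -> np.ndarray:
        return self.log["loglik"].to_numpy()

    def iterate(self, k: int) -> ActivityImage:
        """The recorded iterate at iteration ``k``."""
        return self.recorded_iterates[k]

    def summary(self) -> str:
        img = self.final_image
        lines = [
            f"{type(self.model).__name__} reconstruction results",
            "=" * 44,
            f"iterations:        {self.n_iterations}",
            f"image grid:        {img.grid_size} x {img.grid_size} "
            f"({img.pixel_size_mm} mm/pixel)",
            f"total activity:    {img.total_activity:.6g}",
            f"data total:        {self.model.data_total:.6g}",
            f"final loglik:      {self.loglik[-1]:.6g}",
            f"recorded iterates: {sorted(self.recorded_iterates)!r}"
            if self.recorded_iterates
            else "recorded iterates: [final only]",
        ]
        return "\n".join(lines)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"<EMResults {type(self.model).__name__} "
            f"n_iterations={self.n_iterations}>"
        )


class _EMModel:
    """Shared fit machinery; subclasses define data and operators."""

    #: set by subclasses
    _grid: int
    _pixel: float
    _data_flat: np.ndarray  # (M, 1)

    def _ops(self):
        """Return (fwd, adj, sens_flat) for flat (n, Q) stacks."""
        raise NotImplementedError

    def _default_init_flat(self) -> np.ndarray:
        raise NotImplementedError

    @property
    def data_total(self) -> float:
        return float(self._data_flat.sum())

    def fit(self, config: ReconConfig | None = None, **kwargs) -> EMResults:
        """Run the EM iterations.

        Keyword arguments (``n_iterations``, ``epsilon``,
        ``record_every``, ``initial_image``) override fields of
        ``config``.
        """
        if config is None:
            config = ReconConfig(**kwargs)
        elif kwargs:
            from dataclasses import replace

            config = replace(config, **kwargs)
        fwd, adj, sens = self._ops()
        if config.initial_image is not None:
            init_img = config.initial_image
            if init_img.grid_size != self._grid:
                raise ValueError("initial image grid does not match the model")
            init = init_img.values.reshape(-1, 1)
        else:
            init = self._default_init_flat()
        record = _record_set(config.n_iterations, config.record_every)
        final, records, loglik = _em_run(
            self._data_flat,
            fwd,
            adj,
            sens,
            init,
            config.n_iterations,
            config.epsilon,
            record,
        )
        wrap = lambda flat: ActivityImage(
            flat.reshape(self._grid, self._grid), self._pixel, label=type(self).__name__
        )
        recorded = {k: wrap(v[:, 0]) for k, v in sorted(records.items())}
        return EMResults(self, config, wrap(final[:, 0]), recorded, loglik)


def _record_set(n_iterations: int, record_every: int | None) -> frozenset:
    if record_every is None:
        return frozenset({n_iterations})
    return frozenset(range(record_every, n_iterations + 1, record_every)) | {
        n_iterations
    }


def _uniform_circle_init(grid: int) -> np.ndarray:
    """Uniform ones inside the reconstruction circle, zero outside."""
    c = (grid - 1) / 2.0
    i = np.arange(grid)
    ii, jj = np.meshgrid(i, i, indexing="ij")
    inside = (ii - c) ** 2 + (jj - c) ** 2 <= (grid / 2.0) ** 2
    return inside.astype(float).reshape(-1, 1)


def _psf_ops(psf: PSFKernel | None, grid: int):
    """Image-space blur and its adjoint on flat (npix, Q) stacks."""
    if psf is None or psf.is_identity:
        ident = lambda z: z
        return ident, ident

    w = psf.weights

    def blur(flat):
        return _convolve(flat.reshape(grid, grid, -1), w).reshape(flat.shape)

    def blur_adj(flat):
        return _convolve(flat.reshape(grid, grid, -1), w[::-1, ::-1]).reshape(
            flat.shape
        )

    return blur, blur_adj


class MLEM(_EMModel):
    """Maximum-likelihood EM reconstruction of a measured sinogram.

    With a PSF kernel the blur enters the system model (MLEM+PSF, the
    reference standard for resolution recovery): the forward operator
    becomes project-after-blur and the sensitivity P^T X^T 1.
    """

    def __init__(
        self,
        m: Sinogram,
        geometry: ProjectionGeometry | None = None,
        psf: PSFKernel | None = None,
        grid_size: int | None = None,
        pixel_size_mm: float | None = None,
    ):
        geometry = m.geometry if geometry is None else geometry
        if geometry != m.geometry:
            raise ValueError("sinogram geometry does not match the model geometry")
        if m.counts.min() < 0:
            raise ValueError("sinogram has negative entries")
        self.data = m
        self.geometry = geometry
        self.psf = psf
        self._pixel = geometry.bin_size_mm if pixel_size_mm is None else pixel_size_mm
        if grid_size is None:
            from .projectors import _default_grid

            grid_size = (
                geometry.n_radial_bins if geometry.identity
                else _default_grid(geometry, self._pixel)
            )
        self._grid = int(grid_size)
        if psf is not None and not np.isclose(psf.pixel_size_mm, self._pixel):
            raise ValueError("PSF pixel size does not match the reconstruction grid")
        self._data_flat = m.counts.reshape(-1, 1)

    def _ops(self):
        fwd_p, adj_p = _operators(self.geometry, self._grid, self._pixel)
        blur, blur_adj = _psf_ops(self.psf, self._grid)
        sens = sensitivity_image(
            self.geometry, self._grid, self.psf, self._pixel
        ).values.ravel()
        return (lambda x: fwd_p(blur(x))), (lambda y: blur_adj(adj_p(y))), sens

    def _default_init_flat(self) -> np.ndarray:
        return _uniform_circle_init(self._grid)


class RichardsonLucy(_EMModel):
    """Richardson-Lucy deconvolution of a reconstructed image.

    The "data" are the pixels of the supplied reconstruction theta(K)
    and the forward model is the PSF blur alone; the default initial
    estimate is theta(K) itself.
    """

    def __init__(self, input_image: ActivityImage, psf: PSFKernel):
        if not np.isclose(psf.pixel_size_mm, input_image.pixel_size_mm):
            raise ValueError("PSF pixel size does not match the input image")
        self.input_image = input_image
        self.psf = psf
        self._grid = input_image.grid_size
        self._pixel = input_image.pixel_size_mm
        self._data_flat = input_image.values.reshape(-1, 1)

    def _ops(self):
        blur, blur_adj = _psf_ops(self.psf, self._grid)
        ones = np.ones((self._grid * self._grid, 1))
        sens = blur_adj(ones)[:, 0]
        return blur, blur_adj, sens

    def _default_init_flat(self) -> np.ndarray:
        return self._data_flat.copy()


class SynthesizedReconstruction(_EMModel):
    """Synthesized image reconstruction of an existing reconstruction.

    Forward projects ``input_image`` through the virtual scanner
    geometry to synthesise noiseless sinogram data (consistent with
    the virtual system model by construction), then reconstructs them
    with the PSF inside the system model.  Omitting the PSF gives the
    "noPSF" variant, which is plain MLEM applied to the synthetic data.
    """

    def __init__(
        self,
        input_image: ActivityImage,
        virtual_geometry: ProjectionGeometry,
        psf: PSFKernel | None = None,
    ):
        self.input_image = input_image
        self.geometry = virtual_geometry
        self.psf = psf
        self._grid = input_image.grid_size
        self._pixel = input_image.pixel_size_mm
        if psf is not None and not np.isclose(psf.pixel_size_mm, self._pixel):
            raise ValueError("PSF pixel size does not match the input image")
        self.synthetic_sinogram = forward_project(input_image, virtual_geometry)
        self._data_flat = self.synthetic_sinogram.counts.reshape(-1, 1)

    def _ops(self):
        fwd_p, adj_p = _operators(self.geometry, self._grid, self._pixel)
        blur, blur_adj = _psf_ops(self.psf, self._grid)
        sens = sensitivity_image(
            self.geometry, self._grid, self.psf, self._pixel
        ).values.ravel()
        return (lambda x: fwd_p(blur(x))), (lambda y: blur_adj(adj_p(y))), sens

    def _default_init_flat(self) -> np.ndarray:
        return _uniform_circle_init(self._grid)


# ---------------------------------------------------------------------------
# functional wrappers


def mlem(
    m: Sinogram,
    geometry: ProjectionGeometry | None = None,
    config: ReconConfig | None = None,
    grid_size: int | None = None,
    **kwargs,
) -> EMResults:
    """MLEM reconstruction of a measured sinogram."""
    return MLEM(m, geometry, None, grid_size).fit(config, **kwargs)


def mlem_psf(
    m: Sinogram,
    geometry: ProjectionGeometry | None = None,
    psf: PSFKernel | None = None,
    config: ReconConfig | None = None,
    grid_size: int | None = None,
    **kwargs,
) -> EMResults:
    """MLEM with the PSF in the system model (the reference standard)."""
    return MLEM(m, geometry, psf, grid_size).fit(config, **kwargs)


def richardson_lucy(
    input_image: ActivityImage,
    psf: PSFKernel,
    config: ReconConfig | None = None,
    **kwargs,
) -> EMResults:
    """Richardson-Lucy deconvolution of a reconstructed image."""
    return RichardsonLucy(input_image, psf).fit(config, **kwargs)


def synthesize_data(
    input_image: ActivityImage, virtual_geometry: ProjectionGeometry
) -> Sinogram:
    """Noiseless virtual-scanner projection of an existing reconstruction."""
    if input_image.values.min() < 0:
        raise ValueError("input image must be nonnegative")
    return forward_project(input_image, virtual_geometry)


def synthesized_recon(
    input_image: ActivityImage,
    virtual_geometry: ProjectionGeometry,
    psf: PSFKernel | None = None,
    config: ReconConfig | None = None,
    **kwargs,
) -> EMResults:
    """Synthesized reconstruction (optionally without PSF modelling)."""
    return SynthesizedReconstruction(input_image, virtual_geometry, psf).fit(
        config, **kwargs
    )
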