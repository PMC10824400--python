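"""Parallel-beam line-integral forward and back projection.

The projector realises the discrete Radon transform as an explicitly
materialised sparse matrix built once per (geometry, grid) pair: each
pixel centre is mapped to its signed radial coordinate
``s = x cos(phi) + y sin(phi)`` and its value is split between the two
neighbouring radial bins with linear-interpolation weights scaled by
the pixel size, so each column of the sinogram approximates a line
integral in mm.  Back projection is the exact transpose of the same
matrix — a matched pair, which the EM-family reconstructions assume.

An optional line-thickness parameter ``line_sigma_px`` widens the line
integrals by convolving the image with an isotropic Gaussian of that
sigma (in pixels) before projecting; its adjoint applies the same
symmetric blur after back projection.

A geometry may also be declared an identity operator, in which case
the "sinogram" is simply the image itself.  This degenerate virtual
scanner makes the synthesized-reconstruction update collapse to
Richardson-Lucy deconvolution, which the tests use as an algebraic
cross-check.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
from scipy import sparse
from scipy.ndimage import gaussian_filter

from .phantoms import ActivityImage
from .psf_models import PSFKernel, apply_psf_adjoint

__all__ = [
    "ProjectionGeometry",
    "Sinogram",
    "forward_project",
    "back_project",
    "sensitivity_image",
    "default_angles",
]


def default_angles(n: int = 180) -> tuple[float, ...]:
    """Projection angles 1..n degrees in 1-degree steps (native sampling)."""
    if not (1 <= n <= 180):
        raise ValueError("number of angles must be between 1 and 180")
    return tuple(float(a) for a in range(1, n + 1))


@dataclass(frozen=True)
class ProjectionGeometry:
    """A virtual or native parallel-beam scanner model.

    Parameters
    ----------
    angles_deg : tuple of float
        Strictly increasing projection angles, each in (0, 180].
    n_radial_bins : int
        Number of radial detector bins; must cover the image diagonal.
    bin_size_mm : float
        Radial sampling pitch in mm (defaults match the image pixel).
    line_sigma_px : float
        Gaussian line-thickness sigma in pixels; 0 means thin lines.
    identity : bool
        If True the geometry is the identity operator on images.
    """

    angles_deg: tuple = field(default_factory=default_angles)
    n_radial_bins: int = 183
    bin_size_mm: float = 1.0
    line_sigma_px: float = 0.0
    identity: bool = False

    def __post_init__(self) -> None:
        angles = tuple(float(a) for a in self.angles_deg)
        object.__setattr__(self, "angles_deg", angles)
        if len(angles) == 0:
            raise ValueError("at least one projection angle is required")
        if any(not (0.0 < a <= 180.0) for a in angles):
            raise ValueError("angles must lie in (0, 180] degrees")
        if any(b <= a for a, b in zip(angles, angles[1:])):
            raise ValueError("angles must be strictly increasing")
        if self.n_radial_bins < 1:
            raise ValueError("n_radial_bins must be positive")
        if not (self.bin_size_mm > 0):
            raise ValueError("bin_size_mm must be positive")
        if self.line_sigma_px < 0:
            raise ValueError("line_sigma_px must be nonnegative")

    @property
    def n_angles(self) -> int:
        return len(self.angles_deg)

    @property
    def sinogram_shape(self) -> tuple[int, int]:
        return (self.n_radial_bins, self.n_angles)

    @classmethod
    def native(
        cls,
        grid_size: int,
        pixel_size_mm: float = 1.0,
        n_angles: int = 180,
        line_sigma_px: float = 0.0,
    ) -> "ProjectionGeometry":
        """Geometry with 1-degree sampling and bins matching the pixel grid."""
        nb = int(math.ceil(grid_size * math.sqrt(2.0))) + 3
        nb += 1 - nb % 2  # odd, so a bin centre sits on the rotation axis
        return cls(default_angles(n_angles), nb, pixel_size_mm, line_sigma_px)

    @classmethod
    def identity_for(cls, grid_size: int, pixel_size_mm: float = 1.0) -> "ProjectionGeometry":
        """The identity 'scanner': sinogram == image (one pseudo-angle per column)."""
        angles = tuple(180.0 * (k + 1) / grid_size for k in range(grid_size))
        return cls(angles, grid_size, pixel_size_mm, 0.0, identity=True)

    def coverage_ok(self, grid_size: int, pixel_size_mm: float) -> bool:
        """True if every pixel's radial coordinate falls inside the bins."""
        half_extent = (grid_size - 1) / 2.0 * pixel_size_mm * math.sqrt(2.0)
        return half_extent <= (self.n_radial_bins - 1) / 2.0 * self.bin_size_mm


@dataclass(frozen=True)
class Sinogram:
    """Line-integral data on a (radial bin x angle) grid."""

    counts: np.ndarray
    geometry: ProjectionGeometry

    def __post_init__(self) -> None:
        c = np.asarray(self.counts, dtype=float)
        if c.shape != self.geometry.sinogram_shape:
            raise ValueError(
                f"counts shape {c.shape} does not match geometry "
                f"{self.geometry.sinogram_shape}"
            )
        if not np.all(np.isfinite(c)):
            raise ValueError("sinogram contains non-finite values")
        if c.min() < 0:
            raise ValueError("sinogram contains negative values")
        object.__setattr__(self, "counts", c)

    @property
    def total_counts(self) -> float:
        return float(self.counts.sum())


@lru_cache(maxsize=32)
def _system_matrix(
    geometry: ProjectionGeometry, grid_size: int, pixel_size_mm: float
) -> tuple[sparse.csr_matrix, sparse.csr_matrix]:
    """Sparse system matrix A (flat sinogram x flat image) and its transpose."""
    if not geometry.coverage_ok(grid_size, pixel_size_mm):
        raise ValueError(
            f"geometry with {geometry.n_radial_bins} bins of "
            f"{geometry.bin_size_mm} mm does not cover a {grid_size}-pixel "
            f"image at {pixel_size_mm} mm/pixel"
        )
    g, nb, na = grid_size, geometry.n_radial_bins, geometry.n_angles
    c = (g - 1) / 2.0
    j = np.arange(g)
    x = (j - c) * pixel_size_mm          # column -> x (right)
    y = (c - j) * pixel_size_mm          # row -> y (up)
    X, Y = np.meshgrid(x, y, indexing="xy")
    phi = np.deg2rad(np.asarray(geometry.angles_deg))

    npix = g * g
    pix_idx = np.arange(npix)
    rows, cols, vals = [], [], []
    for a, ph in enumerate(phi):
        s = X.ravel() * math.cos(ph) + Y.ravel() * math.sin(ph)
        t = s / geometry.bin_size_mm + (nb - 1) / 2.0
        k0 = np.floor(t).astype(np.int64)
        w1 = t - k0
        for k, w in ((k0, 1.0 - w1), (k0 + 1, w1)):
            keep = w > 0
            rows.append((k[keep] * na + a))
            cols.append(pix_idx[keep])
            vals.append(w[keep] * pixel_size_mm)
    A = sparse.coo_matrix(
        (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
        shape=(nb * na, npix),
    ).tocsr()
    return A, A.T.tocsr()


def _line_blur(flat: np.ndarray, grid_size: int, sigma_px: float) -> np.ndarray:
    """Isotropic Gaussian blur on flat (npix, Q) image stacks; self-adjoint."""
    if sigma_px <= 0:
        return flat
    stack = flat.reshape(grid_size, grid_size, -1)
    out = gaussian_filter(stack, sigma=(sigma_px, sigma_px, 0), mode="constant")
    return out.reshape(flat.shape)


def _operators(geometry: ProjectionGeometry, grid_size: int, pixel_size_mm: float):
    """(forward, adjoint) closures on flat (npix, Q) / (nbins, Q) arrays."""
    if geometry.identity:
        if geometry.n_radial_bins != grid_size or geometry.n_angles != grid_size:
            raise ValueError("identity geometry must match the image grid")
        eye = lambda z: z
        return eye, eye
    A, AT = _system_matrix(geometry, grid_size, float(pixel_size_mm))
    sig = geometry.line_sigma_px

    def fwd(xflat: np.ndarray) -> np.ndarray:
        return A @ _line_blur(xflat, grid_size, sig)

    def adj(yflat: np.ndarray) -> np.ndarray:
        return _line_blur(AT @ yflat, grid_size, sig)

    return fwd, adj


def forward_project(image: ActivityImage, geometry: ProjectionGeometry) -> Sinogram:
    """Discrete Radon transform of an activity image.

    With ``line_sigma_px > 0`` the image is first blurred with an
    isotropic Gaussian of that sigma, widening the effective line
    integrals.  Linear in the image.
    """
    fwd, _ = _operators(geometry, image.grid_size, image.pixel_size_mm)
    flat = fwd(image.values.reshape(-1, 1))[:, 0]
    shape = (
        image.values.shape
        if geometry.identity
        else geometry.sinogram_shape
    )
    return Sinogram(np.maximum(flat.reshape(shape), 0.0), geometry)


def back_project(
    sino: Sinogram,
    geometry: ProjectionGeometry | None = None,
    grid_size: int | None = None,
    pixel_size_mm: float | None = None,
) -> ActivityImage:
    """Exact adjoint of :func:`forward_project` with the same geometry."""
    geometry = geometry if geometry is not None else sino.geometry
    if geometry is not sino.geometry and geometry != sino.geometry:
        raise ValueError("sinogram does not match the requested geometry")
    pixel = geometry.bin_size_mm if pixel_size_mm is None else pixel_size_mm
    if grid_size is None:
        grid_size = geometry.n_radial_bins if geometry.identity else _default_grid(geometry, pixel)
    _, adj = _operators(geometry, grid_size, pixel)
    flat = adj(sino.counts.reshape(-1, 1))[:, 0]
    return ActivityImage(
        np.maximum(flat.reshape(grid_size, grid_size), 0.0), pixel, label="backprojection"
    )


def _default_grid(geometry: ProjectionGeometry, pixel_size_mm: float) -> int:
    """Largest square grid the radial bins fully cover."""
    extent = (geometry.n_radial_bins - 1) * geometry.bin_size_mm
    return int(math.floor(extent / (pixel_size_mm * math.sqrt(2.0)))) + 1


_SENS_CACHE: dict = {}


def _kernel_key(psf: PSFKernel | None):
    if psf is None:
        return None
    return (psf.model, psf.params, psf.pixel_size_mm, psf.weights.tobytes())


def sensitivity_image(
    geometry: ProjectionGeometry,
    grid_size: int,
    psf: PSFKernel | None = None,
    pixel_size_mm: float | None = None,
) -> ActivityImage:
    """Back projection of a unit sinogram, the EM normaliser.

    With a PSF this is the adjoint chain P^T applied after the
    transpose projector (the MLEM+PSF / synthesized-reconstruction
    denominator).  Results are cached per (geometry, grid, kernel).
    """
    pixel = geometry.bin_size_mm if pixel_size_mm is None else pixel_size_mm
    key = (geometry, grid_size, pixel, _kernel_key(psf))
    if key in _SENS_CACHE:
        return _SENS_CACHE[key]
    shape = (
        (grid_size, grid_size) if geometry.identity else geometry.sinogram_shape
    )
    ones = Sinogram(np.ones(shape), geometry)
    sens = back_project(ones, geometry, grid_size, pixel)
    if psf is not None and not psf.is_identity:
        sens = apply_psf_adjoint(sens, psf)
    _SENS_CACHE[key] = sens
    return sens
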