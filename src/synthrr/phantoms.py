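"""Digital 2-D activity phantoms and region-of-interest masks.

All validation data in this package are procedurally generated: the
high-contrast ("modified") Shepp-Logan head slice, a Derenzo-style
resolution phantom with sectors of graded rod diameters, and a
thorax-like slice (body, lungs, hot cardiac feature) that stands in for
an anatomical voxel phantom.  Generators are deterministic: identical
arguments always produce identical images.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ActivityImage",
    "ROIMask",
    "make_shepp_logan",
    "make_derenzo",
    "make_thorax",
    "make_roi_masks",
    "SHEPP_LOGAN_ELLIPSES",
]


@dataclass(frozen=True)
class ActivityImage:
    """A square 2-D grid of nonnegative activity values.

    Parameters
    ----------
    values : ndarray
        Square 2-D array of activity concentration (arbitrary units).
        Row index runs top-to-bottom, column index left-to-right.
    pixel_size_mm : float
        Physical edge length of one pixel, in mm.
    label : str
        Free-text provenance tag.
    """

    values: np.ndarray
    pixel_size_mm: float
    label: str = ""

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError(f"activity image must be square 2-D, got shape {v.shape}")
        if not np.all(np.isfinite(v)):
            raise ValueError("activity image contains non-finite values")
        if v.min() < 0:
            raise ValueError("activity image contains negative values")
        if not (self.pixel_size_mm > 0):
            raise ValueError("pixel_size_mm must be positive")
        object.__setattr__(self, "values", v)

    @property
    def grid_size(self) -> int:
        return self.values.shape[0]

    @property
    def total_activity(self) -> float:
        return float(self.values.sum())

    def with_values(self, values: np.ndarray, label: str | None = None) -> "ActivityImage":
        """New image on the same grid with different pixel values."""
        return dataclasses.replace(
            self, values=np.asarray(values, dtype=float),
            label=self.label if label is None else label,
        )


@dataclass(frozen=True)
class ROIMask:
    """A named set of pixel coordinates used when evaluating image metrics."""

    member_pixels: frozenset
    name: str  # one of {"global", "medium", "small"}
    grid_size: int

    def __post_init__(self) -> None:
        if self.name not in {"global", "medium", "small"}:
            raise ValueError(f"unknown ROI name {self.name!r}")
        pix = frozenset((int(i), int(j)) for i, j in self.member_pixels)
        for i, j in pix:
            if not (0 <= i < self.grid_size and 0 <= j < self.grid_size):
                raise ValueError(f"ROI pixel ({i},{j}) outside {self.grid_size}^2 grid")
        object.__setattr__(self, "member_pixels", pix)

    def __len__(self) -> int:
        return len(self.member_pixels)

    def to_mask(self) -> np.ndarray:
        """Boolean image-shaped mask."""
        m = np.zeros((self.grid_size, self.grid_size), dtype=bool)
        if self.member_pixels:
            ii, jj = zip(*sorted(self.member_pixels))
            m[list(ii), list(jj)] = True
        return m

    def indices(self) -> tuple[np.ndarray, np.ndarray]:
        """(rows, cols) index arrays in a deterministic order."""
        pix = sorted(self.member_pixels)
        ii = np.array([p[0] for p in pix], dtype=int)
        jj = np.array([p[1] for p in pix], dtype=int)
        return ii, jj


# High-contrast ("modified") Shepp-Logan parameter table:
# (intensity, semi-axis a, semi-axis b, centre x0, centre y0, rotation deg)
# in the conventional unit square [-1, 1]^2, y pointing up.  Intensities
# are signed; the rasterised sum is nonnegative everywhere.
SHEPP_LOGAN_ELLIPSES: tuple[tuple[float, float, float, float, float, float], ...] = (
    (1.00, 0.6900, 0.9200, 0.00, 0.0000, 0.0),
    (-0.80, 0.6624, 0.8740, 0.00, -0.0184, 0.0),
    (-0.20, 0.1100, 0.3100, 0.22, 0.0000, -18.0),
    (-0.20, 0.1600, 0.4100, -0.22, 0.0000, 18.0),
    (0.10, 0.2100, 0.2500, 0.00, 0.3500, 0.0),
    (0.10, 0.0460, 0.0460, 0.00, 0.1000, 0.0),
    (0.10, 0.0460, 0.0460, 0.00, -0.1000, 0.0),
    (0.10, 0.0460, 0.0230, -0.08, -0.6050, 0.0),
    (0.10, 0.0230, 0.0230, 0.00, -0.6060, 0.0),
    (0.10, 0.0230, 0.0460, 0.06, -0.6050, 0.0),
)


def _pixel_centre_grid(grid_size: int) -> tuple[np.ndarray, np.ndarray]:
    """Pixel-centre coordinates in the unit square [-1, 1]^2, y up."""
    c = (grid_size - 1) / 2.0
    half = grid_size / 2.0
    j = np.arange(grid_size)
    x = (j - c) / half
    y = (c - j) / half
    return np.meshgrid(x, y, indexing="xy")  # X varies with column, Y with row


def make_shepp_logan(grid_size: int, pixel_size_mm: float) -> ActivityImage:
    """Rasterise the high-contrast Shepp-Logan head phantom.

    Each pixel value is the signed sum of the intensities of every
    ellipse whose interior contains the pixel centre.
    """
    _check_grid(grid_size, pixel_size_mm, minimum=8)
    X, Y = _pixel_centre_grid(grid_size)
    img = np.zeros((grid_size, grid_size))
    for inten, a, b, x0, y0, phi_deg in SHEPP_LOGAN_ELLIPSES:
        phi = math.radians(phi_deg)
        xr = (X - x0) * math.cos(phi) + (Y - y0) * math.sin(phi)
        yr = -(X - x0) * math.sin(phi) + (Y - y0) * math.cos(phi)
        img += inten * ((xr / a) ** 2 + (yr / b) ** 2 <= 1.0)
    # the signed table sums to >= 0 everywhere; clip round-off only
    img = np.maximum(img, 0.0)
    return ActivityImage(img, pixel_size_mm, label="shepp-logan")


def make_derenzo(
    rod_diameters_mm,
    contrast_ratio: float,
    grid_size: int,
    pixel_size_mm: float,
    background_activity: float = 1.0,
) -> ActivityImage:
    """Derenzo-style rod phantom: one 60-degree sector per rod diameter.

    Rods are hexagonally packed discs with centre-to-centre spacing
    twice the rod diameter, at ``contrast_ratio`` times the background
    disc activity.  An empty diameter list yields the uniform
    background disc alone.
    """
    _check_grid(grid_size, pixel_size_mm, minimum=8)
    if not (contrast_ratio > 0):
        raise ValueError("contrast_ratio must be positive")
    diameters = sorted(float(d) for d in rod_diameters_mm)
    if any(d <= 0 for d in diameters):
        raise ValueError("rod diameters must be positive")
    if len(diameters) > 6:
        raise ValueError("at most six rod sectors are supported")

    fov_mm = grid_size * pixel_size_mm
    bg_radius = 0.46 * fov_mm  # background disc inside the square FOV
    X, Y = _pixel_centre_grid(grid_size)
    Xmm, Ymm = X * fov_mm / 2.0, Y * fov_mm / 2.0
    R = np.hypot(Xmm, Ymm)

    img = np.where(R <= bg_radius, background_activity, 0.0)

    r_inner = 0.12 * bg_radius  # keep sectors separated near the centre
    sector_width = math.pi / 3.0
    for k, d in enumerate(diameters):
        pitch = 2.0 * d  # standard convention: spacing = 2x diameter
        r_outer = bg_radius - d
        if r_inner + pitch > r_outer:
            raise ValueError(
                f"rod diameter {d} mm does not fit the field of view "
                f"({fov_mm:.1f} mm) at the requested grid"
            )
        centre_angle = (k + 0.5) * sector_width  # sectors tile the disc
        for cx, cy in _hex_lattice(pitch, r_inner, r_outer, centre_angle,
                                   sector_width, d):
            rod = (Xmm - cx) ** 2 + (Ymm - cy) ** 2 <= (d / 2.0) ** 2
            img[rod] = contrast_ratio * background_activity
    return ActivityImage(img, pixel_size_mm, label="derenzo")


def _hex_lattice(pitch, r_inner, r_outer, centre_angle, sector_width, diameter):
    """Hexagonal rod-centre lattice clipped to an annular sector.

    Rows advance radially along the sector bisector; within a row the
    centres are offset laterally by half a pitch on alternate rows.
    """
    ux = math.cos(centre_angle), math.sin(centre_angle)      # radial
    vx = -math.sin(centre_angle), math.cos(centre_angle)     # lateral
    row_step = pitch * math.sqrt(3.0) / 2.0
    centres = []
    n_rows = int((r_outer - r_inner) / row_step) + 1
    for row in range(n_rows):
        rad = r_inner + pitch / 2.0 + row * row_step
        if rad > r_outer - diameter / 2.0:
            break
        # lateral half-extent allowed so the whole rod stays in-sector
        margin = math.atan2(diameter, rad)  # angular clearance
        half_extent = rad * math.tan(max(sector_width / 2.0 - margin, 0.0))
        offset = (pitch / 2.0) if (row % 2) else 0.0
        n_side = int((half_extent - offset) / pitch) + 1
        laterals = sorted({s * (offset + t * pitch) for t in range(n_side)
                           for s in (-1.0, 1.0)
                           if offset + t * pitch <= half_extent})
        for lat in laterals:
            centres.append((rad * ux[0] + lat * vx[0], rad * ux[1] + lat * vx[1]))
    return centres


# thorax structures in the unit square [-1, 1]^2 (y up):
#   body ellipse, two lung ellipses, hot circular cardiac/lesion feature
_THORAX_BODY = (0.80, 0.62)            # semi-axes
_THORAX_LUNGS = ((-0.38, 0.14, 0.22, 0.30), (0.38, 0.14, 0.22, 0.30))  # (x0,y0,a,b)
_THORAX_LESION = (0.0, -0.22, 0.16)    # (x0, y0, radius)
_THORAX_LEVELS = {"body": 1.0, "lung": 0.3, "lesion": 4.0}


def make_thorax(grid_size: int, pixel_size_mm: float) -> ActivityImage:
    """Thorax-like slice: body, two low-activity lungs, one hot feature.

    Activity ordering is lung < body < hot feature, with zero
    background, giving at least four distinct levels.  The hot feature
    is sized to contain the 70-pixel medium ROI at any grid size >= 64.
    """
    _check_grid(grid_size, pixel_size_mm, minimum=64)
    X, Y = _pixel_centre_grid(grid_size)
    img = np.zeros((grid_size, grid_size))
    ba, bb = _THORAX_BODY
    img[(X / ba) ** 2 + (Y / bb) ** 2 <= 1.0] = _THORAX_LEVELS["body"]
    for x0, y0, a, b in _THORAX_LUNGS:
        img[((X - x0) / a) ** 2 + ((Y - y0) / b) ** 2 <= 1.0] = _THORAX_LEVELS["lung"]
    x0, y0, r = _THORAX_LESION
    lesion = (X - x0) ** 2 + (Y - y0) ** 2 <= r**2
    if lesion.sum() < 70 + 6:
        raise ValueError(f"grid {grid_size} too small to contain the ROI structures")
    img[lesion] = _THORAX_LEVELS["lesion"]
    return ActivityImage(img, pixel_size_mm, label="thorax")


def make_roi_masks(image: ActivityImage) -> tuple[ROIMask, ROIMask, ROIMask]:
    """Global, medium (70-pixel) and small (6-pixel) evaluation masks.

    The medium mask is the 70 pixels of the hot feature closest to its
    centroid; the small mask is a 2x3 pixel block immediately adjacent
    to the feature, inside the body.  Expects a ``make_thorax`` image.
    """
    v = image.values
    g = image.grid_size
    global_mask = ROIMask(
        frozenset((i, j) for i in range(g) for j in range(g)), "global", g
    )

    hot = v == v.max()
    if v.max() <= 0 or hot.sum() < 70:
        raise ValueError("image has no hot feature able to hold a 70-pixel ROI")
    ii, jj = np.nonzero(hot)
    ci, cj = ii.mean(), jj.mean()
    order = sorted(zip((ii - ci) ** 2 + (jj - cj) ** 2, ii, jj))
    medium = ROIMask(frozenset((int(i), int(j)) for _, i, j in order[:70]), "medium", g)

    # 2x3 block just right of the feature's rightmost extent on the centre rows
    ci_r = int(round(ci))
    j_edge = int(jj[ii == ci_r].max()) if np.any(ii == ci_r) else int(jj.max())
    small_pixels = {(ci_r + di, j_edge + 2 + dj) for di in (0, 1) for dj in (0, 1, 2)}
    small = ROIMask(frozenset(small_pixels), "small", g)
    if small.member_pixels & medium.member_pixels:
        raise AssertionError("small and medium ROIs unexpectedly overlap")
    return global_mask, medium, small


def _check_grid(grid_size: int, pixel_size_mm: float, minimum: int) -> None:
    if int(grid_size) != grid_size or grid_size < minimum:
        raise ValueError(f"grid_size must be an integer >= {minimum}")
    if not (pixel_size_mm > 0):
        raise ValueError("pixel_size_mm must be positive")
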