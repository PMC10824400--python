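"""Reading and writing images, sinograms and kernels.

Activity images travel as single-slice NIfTI volumes (pixel size in
the header zooms) or as plain CSV grids.  Sinograms use the same
containers plus a YAML sidecar recording the projection geometry
(angles, radial bins, bin size, line sigma), so a sinogram file pair
is self-describing.
"""

from __future__ import annotations

from pathlib import Path

import nibabel as nib
import numpy as np
import yaml

from .phantoms import ActivityImage
from .projectors import ProjectionGeometry, Sinogram
from .psf_models import PSFKernel

__all__ = [
    "save_image",
    "load_image",
    "save_sinogram",
    "load_sinogram",
    "save_kernel_csv",
]


def save_image(image: ActivityImage, path) -> Path:
    """Write an activity image as NIfTI (.nii) or CSV (.csv)."""
    path = Path(path)
    if path.suffix == ".csv":
        np.savetxt(path, image.values, delimiter=",")
    else:
        affine = np.diag([image.pixel_size_mm, image.pixel_size_mm, 1.0, 1.0])
        nib.save(nib.Nifti1Image(image.values[:, :, None], affine), str(path))
    return path


def load_image(path, pixel_size_mm: float | None = None, label: str = "") -> ActivityImage:
    """Read an activity image from NIfTI or CSV.

    CSV carries no pixel size; pass ``pixel_size_mm`` explicitly
    (defaults to 1.0 for CSV input).
    """
    path = Path(path)
    if path.suffix == ".csv":
        values = np.loadtxt(path, delimiter=",", ndmin=2)
        return ActivityImage(values, pixel_size_mm or 1.0, label or path.stem)
    img = nib.load(str(path))
    values = np.asarray(img.dataobj, dtype=float)
    if values.ndim == 3:
        if values.shape[2] != 1:
            raise ValueError("expected a single-slice NIfTI volume")
        values = values[:, :, 0]
    pix = pixel_size_mm if pixel_size_mm is not None else float(img.header.get_zooms()[0])
    return ActivityImage(values, pix, label or path.stem)


def _geometry_to_dict(g: ProjectionGeometry) -> dict:
    return {
        "angles_deg": list(g.angles_deg),
        "n_radial_bins": g.n_radial_bins,
        "bin_size_mm": g.bin_size_mm,
        "line_sigma_px": g.line_sigma_px,
        "identity": g.identity,
    }


def _geometry_from_dict(d: dict) -> ProjectionGeometry:
    return ProjectionGeometry(
        tuple(d["angles_deg"]),
        int(d["n_radial_bins"]),
        float(d["bin_size_mm"]),
        float(d.get("line_sigma_px", 0.0)),
        bool(d.get("identity", False)),
    )


def save_sinogram(sino: Sinogram, path) -> Path:
    """Write a sinogram plus its geometry sidecar ``<path>.geometry.yaml``."""
    path = Path(path)
    if path.suffix == ".csv":
        np.savetxt(path, sino.counts, delimiter=",")
    else:
        nib.save(nib.Nifti1Image(sino.counts[:, :, None], np.eye(4)), str(path))
    with open(path.with_suffix(path.suffix + ".geometry.yaml"), "w") as fh:
        yaml.safe_dump(_geometry_to_dict(sino.geometry), fh)
    return path


def load_sinogram(path) -> Sinogram:
    """Read a sinogram written by :func:`save_sinogram`."""
    path = Path(path)
    sidecar = path.with_suffix(path.suffix + ".geometry.yaml")
    if not sidecar.exists():
        raise FileNotFoundError(f"missing geometry sidecar {sidecar}")
    with open(sidecar) as fh:
        geometry = _geometry_from_dict(yaml.safe_load(fh))
    if path.suffix == ".csv":
        counts = np.loadtxt(path, delimiter=",", ndmin=2)
    else:
        counts = np.asarray(nib.load(str(path)).dataobj, dtype=float)[:, :, 0]
    return Sinogram(counts, geometry)


def save_kernel_csv(kernel: PSFKernel, path) -> Path:
    """Export kernel weights as CSV for inspection."""
    path = Path(path)
    np.savetxt(path, kernel.weights, delimiter=",")
    return path
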