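"""Poisson sinogram simulation.

Measured data are produced by the three-step protocol used throughout
the validation study: (1) blur the ground-truth image with the
positron-range PSF, (2) forward project the blurred image with the
parallel line-integral model, (3) draw independent Poisson counts per
sinogram bin.  The noiseless mean is globally scaled so its expected
total equals the requested count level; no attenuation, scatter,
randoms or normalisation effects are simulated.

Count levels default to 1e7 / 1e6 / 1e5 expected total counts
(high / mid / low) for a 128x128 phantom at 180 angles — spanning the
regimes from near-noiseless reconstruction down to severe Poisson
noise where post-reconstruction deconvolution degrades sharply.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .phantoms import ActivityImage
from .projectors import ProjectionGeometry, Sinogram, forward_project
from .psf_models import PSFKernel, apply_psf

__all__ = [
    "CountLevel",
    "RealizationSet",
    "COUNT_LEVELS",
    "count_scale",
    "expected_sinogram",
    "simulate_acquisition",
    "make_realizations",
]


@dataclass(frozen=True)
class CountLevel:
    """Expected total number of detected counts over the whole sinogram."""

    name: str
    total_expected_counts: float

    def __post_init__(self) -> None:
        if not (self.total_expected_counts > 0):
            raise ValueError("total_expected_counts must be positive")


#: default acquisition regimes, ordered high > mid > low
COUNT_LEVELS: dict[str, CountLevel] = {
    "high": CountLevel("high", 1e7),
    "mid": CountLevel("mid", 1e6),
    "low": CountLevel("low", 1e5),
}


def count_scale(
    truth: ActivityImage,
    psf: PSFKernel,
    geometry: ProjectionGeometry,
    level: CountLevel,
) -> float:
    """Global factor mapping the phantom's intensity scale to counts.

    Reconstructions of the simulated data estimate the *scaled*
    activity ``count_scale(...) * truth``; evaluation against the
    ground truth must use the same scale on both sides.
    """
    blurred = apply_psf(truth, psf)
    total = forward_project(blurred, geometry).total_counts
    if total <= 0:
        raise ValueError("phantom projects to an empty sinogram")
    return level.total_expected_counts / total


def expected_sinogram(
    truth: ActivityImage,
    psf: PSFKernel,
    geometry: ProjectionGeometry,
    level: CountLevel,
) -> Sinogram:
    """Noiseless mean of the acquisition: blurred, projected, scaled.

    The single global scale factor makes the sinogram total equal
    ``level.total_expected_counts`` exactly.
    """
    blurred = apply_psf(truth, psf)
    sino = forward_project(blurred, geometry)
    total = sino.total_counts
    if total <= 0:
        raise ValueError("phantom projects to an empty sinogram")
    scale = level.total_expected_counts / total
    return Sinogram(sino.counts * scale, geometry)


def simulate_acquisition(
    truth: ActivityImage,
    psf: PSFKernel,
    geometry: ProjectionGeometry,
    level: CountLevel,
    seed: int,
) -> Sinogram:
    """One noisy acquisition: independent Poisson counts per bin.

    Bit-reproducible for a given seed (PCG64 generator).
    """
    mean = expected_sinogram(truth, psf, geometry, level)
    rng = np.random.default_rng(int(seed))
    counts = rng.poisson(mean.counts).astype(float)
    return Sinogram(counts, geometry)


@dataclass(frozen=True)
class RealizationSet:
    """Q independent noisy acquisitions of one phantom.

    Realization ``q`` uses seed ``base_seed + q`` so any member can be
    regenerated in isolation.
    """

    sinograms: tuple
    base_seed: int
    count_level: CountLevel

    def __post_init__(self) -> None:
        if len(self.sinograms) < 1:
            raise ValueError("a realization set needs at least one sinogram")
        geo = self.sinograms[0].geometry
        if any(s.geometry != geo for s in self.sinograms):
            raise ValueError("all realizations must share one geometry")
        object.__setattr__(self, "sinograms", tuple(self.sinograms))

    @property
    def Q(self) -> int:
        return len(self.sinograms)

    def stack(self) -> np.ndarray:
        """Counts stacked as a flat (n_bins_total, Q) array."""
        return np.stack([s.counts.ravel() for s in self.sinograms], axis=1)


def make_realizations(
    truth: ActivityImage,
    psf: PSFKernel,
    geometry: ProjectionGeometry,
    level: CountLevel,
    Q: int,
    base_seed: int,
) -> RealizationSet:
    """Q independent acquisitions with seeds base_seed .. base_seed+Q-1."""
    if Q < 1:
        raise ValueError("Q must be at least 1")
    mean = expected_sinogram(truth, psf, geometry, level)  # computed once
    sinos = []
    for q in range(Q):
        rng = np.random.default_rng(int(base_seed) + q)
        sinos.append(Sinogram(rng.poisson(mean.counts).astype(float), geometry))
    return RealizationSet(tuple(sinos), int(base_seed), level)
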