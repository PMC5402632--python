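"""Periosteal auto-contouring: from grayscale image to a solid bone outline.

The fully-automated contour is a two-stage procedure: a first structure
approximation (light Gaussian smoothing plus a low per-mille threshold)
followed by a morphological closing with cavity fill, which bridges the
mouths of cortical interruptions and yields a solid volume bounded by the
periosteal surface.  The thin finger-joint cortex motivates the defaults:
threshold 105 per 1000 of the maximum possible voxel value and 7 closing
steps (radius/tibia protocols use 120 and 10).

The semi-automated pathway enters here too: an operator-corrected contour
solid, produced in any external tool, is loaded verbatim (after cavity
fill) in place of the automatic one.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from . import volume_io
from ._morphology import fill_cavities
from .volume_io import BinaryVolume, GrayscaleVolume, ValidationError

__all__ = [
    "ContourParams",
    "ContourSolid",
    "approximate_structure",
    "close_and_fill",
    "auto_contour",
    "load_corrected_contour",
]


@dataclass
class ContourParams:
    """Parameters of the structure approximation and closing.

    gauss_sigma : Gaussian smoothing sigma in voxels.
    gauss_support : truncation radius of the kernel in voxels (radius 1
        gives a 3x3x3 kernel with weights sampled from the Gaussian and
        renormalized to sum 1).
    threshold_permille : threshold as parts per 1000 of the acquisition's
        maximum possible voxel value.
    closing_steps : voxels of dilation, then cavity fill, then erosion.
    """

    gauss_sigma: float = 0.8
    gauss_support: int = 1
    threshold_permille: int = 105
    closing_steps: int = 7

    def __post_init__(self) -> None:
        if self.gauss_sigma <= 0 or self.gauss_support <= 0 or self.closing_steps <= 0:
            raise ValidationError("contour parameters must be strictly positive")
        if not 1 <= self.threshold_permille <= 1000:
            raise ValidationError("threshold_permille must be in [1, 1000]")


@dataclass
class ContourSolid:
    """Filled binary solid bounded by the periosteal surface."""

    solid: BinaryVolume


def _gauss_kernel_1d(sigma: float, support: int) -> np.ndarray:
    x = np.arange(-support, support + 1, dtype=float)
    k = np.exp(-0.5 * (x / sigma) ** 2)
    return k / k.sum()


def approximate_structure(gray: GrayscaleVolume, p: ContourParams) -> BinaryVolume:
    """First structure approximation: truncated-Gaussian smooth + threshold.

    Foreground = voxels whose smoothed intensity is at or above
    ``threshold_permille/1000 * intensity_max``.
    """
    k = _gauss_kernel_1d(p.gauss_sigma, p.gauss_support)
    smoothed = gray.data.astype(float)
    for axis in range(3):
        smoothed = ndimage.correlate1d(smoothed, k, axis=axis, mode="nearest")
    thresh = p.threshold_permille / 1000.0 * gray.intensity_max
    return BinaryVolume(data=smoothed >= thresh, voxel_size_mm=gray.voxel_size_mm)


def _ball_radius(steps: int) -> float:
    # a voxel belongs to the ball when its center lies inside the
    # continuous sphere of radius `steps` grown by half a voxel
    return steps + 0.5


def dilate_ball(mask: np.ndarray, steps: int) -> np.ndarray:
    """Euclidean-metric dilation by ``steps`` voxels of distance."""
    return ndimage.distance_transform_edt(~mask) <= _ball_radius(steps)


def erode_ball(mask: np.ndarray, steps: int) -> np.ndarray:
    """Euclidean-metric erosion by ``steps`` voxels of distance."""
    return ndimage.distance_transform_edt(mask) > _ball_radius(steps)


def close_and_fill(structure: BinaryVolume, closing_steps: int) -> ContourSolid:
    """Morphological closing with cavity fill.

    Dilate by ``closing_steps`` voxels, fill every background component not
    connected to the lattice border, erode back.  Dilation and erosion use
    the Euclidean ball of radius ``closing_steps`` (+ half a voxel of
    lattice discretization), which — unlike a city-block cross — restores a
    flush surface over the mouth of a narrow channel, so the later cortical
    mask keeps its constant thickness across interruption openings.  The
    volume is padded with background voxels beforehand so dilation never
    clips at the lattice border, and cropped afterwards.
    """
    if not structure.data.any():
        raise ValidationError("no bone found: structure approximation is empty")
    if closing_steps < 1:
        raise ValidationError("closing_steps must be >= 1")
    pad = closing_steps + 1
    padded = np.pad(structure.data, pad)
    closed = erode_ball(fill_cavities(dilate_ball(padded, closing_steps)), closing_steps)
    core = closed[pad:-pad, pad:-pad, pad:-pad]
    return ContourSolid(solid=BinaryVolume(data=core, voxel_size_mm=structure.voxel_size_mm))


def auto_contour(gray: GrayscaleVolume, p: ContourParams | None = None) -> ContourSolid:
    """Fully-automated periosteal contour of all bone in the field of view."""
    p = p or ContourParams()
    return close_and_fill(approximate_structure(gray, p), p.closing_steps)


def load_corrected_contour(path, reference: GrayscaleVolume | None = None) -> ContourSolid:
    """Load an operator-corrected contour solid (semi-automated pathway).

    The external solid is sanitized by filling any fully enclosed background
    cavities; otherwise it is taken verbatim.  When ``reference`` is given
    the lattice shapes must match.
    """
    bv = volume_io.read_binary(path)
    if reference is not None:
        if bv.shape != reference.shape:
            raise ValidationError(
                f"corrected contour shape {bv.shape} does not match "
                f"image shape {reference.shape}"
            )
        bv.voxel_size_mm = reference.voxel_size_mm
    filled = fill_cavities(bv.data)
    return ContourSolid(solid=BinaryVolume(data=filled, voxel_size_mm=bv.voxel_size_mm))
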