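"""Calibrated image containers and the shared low-level operators.

Every measurement in the pipeline starts from a multi-channel confocal
z-stack with physical voxel calibration.  This module owns the containers
(:class:`ImageStack`, :class:`Image2D`, :class:`BinaryImage`), lossless TIFF
round-tripping, and the small set of 2D operators each downstream stage
shares: maximum-intensity projection, median de-speckling, binarization and
area fraction.  Calibration (micrometres per voxel edge) is carried through
every operator and never silently altered.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import tifffile
from scipy import ndimage
from skimage.filters import threshold_otsu

__all__ = [
    "ImageStack",
    "Image2D",
    "BinaryImage",
    "read_stack",
    "write_stack",
    "max_projection",
    "despeckle",
    "enhance_contrast",
    "binarize",
    "area_fraction",
]


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class ImageStack:
    """A calibrated multi-channel voxel grid, axes ``(channel, z, y, x)``.

    Parameters
    ----------
    voxels
        Non-negative intensities, shape ``(C, Z, Y, X)``.
    calibration
        ``(dx, dy, dz)`` voxel edge lengths in micrometres; all positive.
        A confocal acquisition with a 0.5 µm z-step has ``dz = 0.5``.
    channels
        Ordered unique channel labels, one per leading-axis plane.
    """

    voxels: np.ndarray
    calibration: tuple[float, float, float]
    channels: tuple[str, ...]

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 4:
            raise ValueError(f"voxels must be 4D (C, Z, Y, X), got {self.voxels.ndim}D")
        self.calibration = tuple(float(v) for v in self.calibration)
        if len(self.calibration) != 3 or any(v <= 0 for v in self.calibration):
            raise ValueError(f"calibration must be three positive lengths, got {self.calibration}")
        self.channels = tuple(str(c) for c in self.channels)
        if len(self.channels) != self.voxels.shape[0]:
            raise ValueError(
                f"{len(self.channels)} channel names for {self.voxels.shape[0]} channel planes"
            )
        if len(set(self.channels)) != len(self.channels):
            raise ValueError(f"channel names must be unique: {self.channels}")
        if np.issubdtype(self.voxels.dtype, np.floating) and not np.all(np.isfinite(self.voxels)):
            raise ValueError("intensities must be finite")

    @property
    def shape(self) -> tuple[int, int, int, int]:
        return self.voxels.shape

    def channel_index(self, channel: str) -> int:
        try:
            return self.channels.index(channel)
        except ValueError:
            raise KeyError(f"unknown channel {channel!r}; stack has {self.channels}") from None

    def channel_voxels(self, channel: str) -> np.ndarray:
        """The 3D ``(Z, Y, X)`` grid of one channel."""
        return self.voxels[self.channel_index(channel)]

    @property
    def voxel_volume_um3(self) -> float:
        dx, dy, dz = self.calibration
        return dx * dy * dz


@dataclass
class Image2D:
    """A single 2D image inheriting ``(dx, dy)`` calibration from its stack."""

    pixels: np.ndarray
    calibration: tuple[float, float]

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2:
            raise ValueError(f"pixels must be 2D, got {self.pixels.ndim}D")
        self.calibration = tuple(float(v) for v in self.calibration)
        if any(v <= 0 for v in self.calibration):
            raise ValueError(f"calibration must be positive, got {self.calibration}")

    @property
    def pixel_area_um2(self) -> float:
        return self.calibration[0] * self.calibration[1]


@dataclass
class BinaryImage(Image2D):
    """An :class:`Image2D` whose pixels are boolean foreground flags."""

    def __post_init__(self) -> None:
        super().__post_init__()
        self.pixels = self.pixels.astype(bool)


# ---------------------------------------------------------------------------
# TIFF I/O
# ---------------------------------------------------------------------------

_META_VERSION = 1


def write_stack(stack: ImageStack, path: str | Path) -> Path:
    """Write a stack to a multi-page TIFF with a JSON metadata sidecar block.

    Calibration and channel order are stored in the TIFF's shaped-metadata
    JSON so that :func:`read_stack` round-trips losslessly.
    """
    path = Path(path)
    meta = {
        "axes": "CZYX",
        "calibration_um": list(stack.calibration),
        "channels": list(stack.channels),
        "meta_version": _META_VERSION,
    }
    tifffile.imwrite(path, stack.voxels, photometric="minisblack", metadata=meta)
    return path


def read_stack(
    path: str | Path,
    calibration: tuple[float, float, float] | None = None,
    channels: tuple[str, ...] | None = None,
) -> ImageStack:
    """Read a multi-channel TIFF back into an :class:`ImageStack`.

    Files written by :func:`write_stack` carry calibration and channel names
    in their metadata; for third-party TIFFs lacking them, ``calibration``
    (and optionally ``channels``) must be supplied.  Single-channel or
    single-slice files are promoted to 4D with unit axes.
    """
    path = Path(path)
    try:
        with tifffile.TiffFile(path) as tif:
            voxels = tif.asarray()
            meta = tif.shaped_metadata[0] if tif.shaped_metadata else {}
    except tifffile.TiffFileError as exc:
        raise ValueError(f"{path} is not a readable TIFF: {exc}") from exc

    while voxels.ndim < 4:
        voxels = voxels[np.newaxis]
    if voxels.ndim != 4:
        raise ValueError(f"cannot interpret {voxels.ndim}D TIFF data as (C, Z, Y, X)")

    if calibration is None:
        if "calibration_um" not in meta:
            raise ValueError(
                f"{path} carries no voxel calibration; pass calibration=(dx, dy, dz) in µm"
            )
        calibration = tuple(meta["calibration_um"])
    if channels is None:
        channels = tuple(meta.get("channels", (f"ch{i}" for i in range(voxels.shape[0]))))
    return ImageStack(voxels=voxels, calibration=calibration, channels=channels)


# ---------------------------------------------------------------------------
# operators
# ---------------------------------------------------------------------------

def max_projection(stack: ImageStack, channel: str) -> Image2D:
    """Maximum-intensity projection of one channel along z.

    Collapses the z-series to a 2D image whose every pixel is the maximum
    intensity over depth, the standard first step for counting and
    morphology on confocal stacks.
    """
    vol = stack.channel_voxels(channel)
    return Image2D(pixels=vol.max(axis=0), calibration=stack.calibration[:2])


def despeckle(img: Image2D) -> Image2D:
    """3×3 median filter: removes isolated single-pixel background noise."""
    return Image2D(
        pixels=ndimage.median_filter(img.pixels, size=3, mode="nearest"),
        calibration=img.calibration,
    )


def enhance_contrast(img: Image2D, low_pct: float = 0.1, high_pct: float = 99.9) -> Image2D:
    """Percentile contrast stretch onto [0, 1].

    Optional visualization aid for the morphology branch (bringing faint
    distal processes above threshold); off by default for quantification.
    Degenerate (constant) images are returned unchanged.
    """
    lo, hi = np.percentile(img.pixels, [low_pct, high_pct])
    if hi <= lo:
        return Image2D(pixels=img.pixels.copy(), calibration=img.calibration)
    stretched = np.clip((img.pixels.astype(float) - lo) / (hi - lo), 0.0, 1.0)
    return Image2D(pixels=stretched, calibration=img.calibration)


def binarize(img: Image2D, method: str = "otsu", threshold: float | None = None) -> BinaryImage:
    """Threshold an image to foreground/background.

    ``method="otsu"`` computes the threshold from a 256-bin histogram;
    ``method="fixed"`` uses the supplied ``threshold``, preserving the
    manual-threshold workflow.  A pixel is foreground iff its intensity is
    strictly greater than the threshold.
    """
    if method == "otsu":
        if img.pixels.min() == img.pixels.max():
            raise ValueError(
                "Otsu threshold is undefined for a constant image; use method='fixed'"
            )
        thr = threshold_otsu(img.pixels, nbins=256)
    elif method == "fixed":
        if threshold is None:
            raise ValueError("method='fixed' requires a threshold")
        thr = threshold
    else:
        raise ValueError(f"unknown method {method!r}; expected 'otsu' or 'fixed'")
    return BinaryImage(pixels=img.pixels > thr, calibration=img.calibration)


def area_fraction(binary: BinaryImage, roi: np.ndarray | None = None) -> float:
    """Foreground pixels over total (or ROI) pixels, in [0, 1].

    This is the astrogliosis readout: area occupied by thresholded
    GFAP-positive processes divided by the slice (or region) area.
    """
    mask = binary.pixels
    if roi is not None:
        roi = np.asarray(roi, dtype=bool)
        if roi.shape != mask.shape:
            raise ValueError(f"roi shape {roi.shape} != image shape {mask.shape}")
        if not roi.any():
            raise ValueError("roi is empty")
        return float(mask[roi].sum() / roi.sum())
    return float(mask.sum() / mask.size)
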