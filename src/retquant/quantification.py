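"""Field-level biomarker quantification.

One confocal field yields one row of measurements: microglia density
(cells per mm³ of imaged tissue), the percentage of ganglion neurons with
perinuclear cleaved caspase-3 puncta (apoptosis), the GFAP area fraction
(astrogliosis), and the list of detected protein aggregates (Aβ plaques /
pTau tangles) with 3D volume, equivalent spherical diameter and retinal
layer.  Aggregates are found by thresholding the channel, labelling
26-connected 3D components, and discarding components whose equivalent
diameter falls below a per-channel floor (0.58 µm for Aβ, 0.68 µm for
pTau — the smallest aggregates reported detectable).  All volumes are
computed in µm³ from the voxel calibration so anisotropic voxels (fine xy
sampling, 0.5 µm z-step) are handled everywhere.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.spatial import cKDTree
from skimage.filters import threshold_otsu

from .image_core import BinaryImage, Image2D, ImageStack, area_fraction, binarize, \
    despeckle, max_projection
from .morphometry import MorphometryConfig, segment_cells
from .synthetic import GroundTruth

__all__ = [
    "AggregateRecord",
    "FieldMeasurement",
    "QuantificationConfig",
    "MIN_DIAMETER_UM",
    "cell_density",
    "positive_fraction",
    "count_positive_cells",
    "detect_aggregates",
    "assign_layer",
    "summarize_field",
    "aggregates_to_frame",
    "measurements_to_frame",
]

#: Per-channel minimum equivalent spherical diameter (µm) below which a
#: detected component is discarded as sub-resolution.
MIN_DIAMETER_UM = {"Abeta": 0.58, "pTau": 0.68}


@dataclass
class AggregateRecord:
    """One detected 3D connected component of aggregated protein."""

    label: int
    channel: str
    voxel_count: int
    volume_um3: float
    equivalent_diameter_um: float
    centroid_um: tuple[float, float, float]  # (x, y, z)
    layer: str | None = None


@dataclass
class FieldMeasurement:
    """All scalar biomarkers of one field plus its aggregate list."""

    field_id: str
    genotype: str | None
    stage: str | None
    microglia_density_mm3: float
    n_microglia: int
    caspase_pct: float
    gfap_fraction: float
    aggregates: list[AggregateRecord] = field(default_factory=list)


@dataclass(frozen=True)
class QuantificationConfig:
    """Channel names and thresholds of the field-level measurements."""

    microglia_channel: str = "Iba1"
    gfap_channel: str = "GFAP"
    caspase_channel: str = "Casp3"
    aggregate_channels: tuple[str, ...] = ("Abeta", "pTau")
    caspase_radius_um: float = 5.0
    min_diameter_um: dict = field(default_factory=lambda: dict(MIN_DIAMETER_UM))
    threshold_method: str = "otsu"
    fixed_threshold: float | None = None
    morphometry: MorphometryConfig = field(default_factory=MorphometryConfig)


# ---------------------------------------------------------------------------
# closed-form measures
# ---------------------------------------------------------------------------

def cell_density(n_cells: int, field_area_um2: float, thickness_um: float) -> float:
    """Cells per mm³: count / (field area × thickness), rescaled by 1e9.

    The acquired field covers ``field_area_um2 × thickness_um`` µm³ of
    tissue; one mm³ is 1e9 µm³.
    """
    if field_area_um2 <= 0 or thickness_um <= 0:
        raise ValueError(
            f"field geometry must be positive, got area={field_area_um2}, "
            f"thickness={thickness_um}"
        )
    if n_cells < 0:
        raise ValueError(f"n_cells must be >= 0, got {n_cells}")
    return n_cells / (field_area_um2 * thickness_um) * 1e9


def positive_fraction(n_positive: int, n_total_ganglion: int) -> float:
    """Percentage of ganglion neurons that are marker-positive."""
    if n_total_ganglion <= 0:
        raise ValueError(f"total ganglion count must be positive, got {n_total_ganglion}")
    if not 0 <= n_positive <= n_total_ganglion:
        raise ValueError(f"n_positive={n_positive} outside [0, {n_total_ganglion}]")
    return 100.0 * n_positive / n_total_ganglion


def equivalent_diameter(volume_um3: float) -> float:
    """Diameter of the sphere with the given volume: (6V/π)^(1/3)."""
    return float((6.0 * volume_um3 / np.pi) ** (1.0 / 3.0))


# ---------------------------------------------------------------------------
# caspase-3 positivity
# ---------------------------------------------------------------------------

def _noise_floor(arr: np.ndarray, k: float = 4.0) -> float:
    """Background guard: mean + k·std of the data.

    Otsu always splits a histogram, even of a signal-free channel where it
    would turn half the background noise into foreground; requiring the
    threshold to clear the global mean by ``k`` standard deviations makes
    an empty channel yield (almost) no foreground, while any real structure
    pushes Otsu far above this floor.
    """
    return float(arr.mean() + k * arr.std())


def _detect_puncta_centroids(stack: ImageStack, channel: str,
                             min_area_um2: float = 0.2) -> np.ndarray:
    """Centroids (x, y) µm of bright puncta on the channel's projection.

    Components smaller than ``min_area_um2`` (well below a resolvable
    punctum) are treated as residual shot noise and dropped.
    """
    proj = despeckle(max_projection(stack, channel))
    if proj.pixels.min() == proj.pixels.max():
        return np.empty((0, 2))
    thr = max(float(threshold_otsu(proj.pixels, nbins=256)), _noise_floor(proj.pixels))
    binary = binarize(proj, "fixed", threshold=thr)
    labels, n = ndimage.label(binary.pixels, structure=np.ones((3, 3)))
    if n == 0:
        return np.empty((0, 2))
    dx, dy = proj.calibration
    areas = np.bincount(labels.ravel())[1:] * dx * dy
    keep = np.flatnonzero(areas >= min_area_um2) + 1
    if len(keep) == 0:
        return np.empty((0, 2))
    cents = ndimage.center_of_mass(binary.pixels, labels, keep)
    return np.array([[c * dx, r * dy] for r, c in cents])


def count_positive_cells(
    stack: ImageStack,
    ganglion_centers_um: np.ndarray,
    channel: str = "Casp3",
    radius_um: float = 5.0,
) -> tuple[int, list[int]]:
    """Ganglion neurons with ≥1 caspase punctum within ``radius_um``.

    Positivity follows the perinuclear-localization rule: a neuron is
    apoptotic if at least one detected punctum centroid lies within the
    given radius of its nucleus centroid.  Returns (count, positive
    indices into ``ganglion_centers_um``).
    """
    ganglion = np.asarray(ganglion_centers_um, dtype=float).reshape(-1, 2)
    puncta = _detect_puncta_centroids(stack, channel)
    if len(puncta) == 0 or len(ganglion) == 0:
        return 0, []
    tree = cKDTree(puncta)
    dists, _ = tree.query(ganglion, k=1)
    positive = np.flatnonzero(dists <= radius_um)
    return int(len(positive)), [int(i) for i in positive]


# ---------------------------------------------------------------------------
# aggregate volumetry
# ---------------------------------------------------------------------------

def _threshold_volume(vol: np.ndarray, method: str, threshold: float | None) -> np.ndarray:
    if method == "fixed":
        if threshold is None:
            raise ValueError("fixed threshold method requires a threshold")
        return vol > threshold
    if method == "otsu":
        if vol.min() == vol.max():
            return np.zeros_like(vol, dtype=bool)  # empty/constant channel: no signal
        # one global threshold from the whole stack applied slice by slice,
        # guarded against signal-free channels by the background floor
        return vol > max(float(threshold_otsu(vol, nbins=256)), _noise_floor(vol))
    raise ValueError(f"unknown threshold method {method!r}")


def detect_aggregates(
    stack: ImageStack,
    channel: str,
    threshold_method: str = "otsu",
    fixed_threshold: float | None = None,
    min_diameter_um: float | None = None,
) -> list[AggregateRecord]:
    """3D aggregate detection on one channel.

    Threshold → 26-connected 3D component labelling → per-component volume
    (voxel count × voxel volume) and equivalent spherical diameter →
    discard components below the channel's minimum-diameter floor.
    """
    vol = stack.channel_voxels(channel)
    if min_diameter_um is None:
        min_diameter_um = MIN_DIAMETER_UM.get(channel, 0.0)
    mask = _threshold_volume(vol, threshold_method, fixed_threshold)
    labels, n = ndimage.label(mask, structure=np.ones((3, 3, 3)))
    if n == 0:
        return []
    dx, dy, dz = stack.calibration
    voxel_vol = stack.voxel_volume_um3
    counts = np.bincount(labels.ravel())[1:]
    centroids = ndimage.center_of_mass(mask, labels, range(1, n + 1))
    records = []
    for lab, (count, (cz, cy, cx)) in enumerate(zip(counts, centroids), start=1):
        volume = float(count) * voxel_vol
        diam = equivalent_diameter(volume)
        if diam < min_diameter_um:
            continue
        records.append(AggregateRecord(
            label=lab, channel=channel, voxel_count=int(count), volume_um3=volume,
            equivalent_diameter_um=diam,
            centroid_um=((cx + 0.5) * dx, (cy + 0.5) * dy, (cz + 0.5) * dz),
        ))
    return records


def assign_layer(
    record: AggregateRecord,
    layer_boundaries: dict[str, tuple[float, float]],
) -> str:
    """Retinal layer of an aggregate from its centroid's y-band."""
    y = record.centroid_um[1]
    for name, (lo, hi) in layer_boundaries.items():
        if lo <= y < hi:
            record.layer = name
            return name
    raise ValueError(
        f"aggregate centroid y={y:.2f} µm lies outside all layer bands {layer_boundaries}"
    )


# ---------------------------------------------------------------------------
# field summary
# ---------------------------------------------------------------------------

def summarize_field(
    stack: ImageStack,
    truth: GroundTruth | None = None,
    config: QuantificationConfig = QuantificationConfig(),
    field_id: str = "",
    genotype: str | None = None,
    stage: str | None = None,
    ganglion_centers_um: np.ndarray | None = None,
    layer_boundaries: dict[str, tuple[float, float]] | None = None,
) -> FieldMeasurement:
    """All field-level biomarkers of one stack as a single measurement row.

    Ganglion-nucleus centroids and layer boundaries come either from the
    generator's ground truth or from an annotation source; only those two
    auxiliary inputs are consumed from ``truth`` — every measured quantity
    is recomputed from the image.
    """
    if truth is not None:
        if ganglion_centers_um is None:
            ganglion_centers_um = truth.ganglion_centers_um
        if layer_boundaries is None:
            layer_boundaries = truth.layer_boundaries

    dx, dy, dz = stack.calibration
    nz, ny, nx_ = stack.voxels.shape[1:]
    field_area = (nx_ * dx) * (ny * dy)
    thickness = nz * dz

    # microglia density: count all segmented cells in the field
    proj = despeckle(max_projection(stack, config.microglia_channel))
    cells = segment_cells(proj, config.morphometry)
    density = cell_density(len(cells), field_area, thickness)

    # caspase-positive percentage of ganglion neurons
    if ganglion_centers_um is not None and len(ganglion_centers_um) > 0:
        n_pos, _ = count_positive_cells(stack, ganglion_centers_um,
                                        config.caspase_channel, config.caspase_radius_um)
        caspase_pct = positive_fraction(n_pos, len(ganglion_centers_um))
    else:
        caspase_pct = 0.0

    # astrogliosis area fraction
    gproj = despeckle(max_projection(stack, config.gfap_channel))
    if gproj.pixels.min() == gproj.pixels.max():
        gfap = float((gproj.pixels > 0).mean())
    else:
        gfap = area_fraction(binarize(gproj, config.threshold_method, config.fixed_threshold))

    # aggregates
    aggregates: list[AggregateRecord] = []
    for channel in config.aggregate_channels:
        recs = detect_aggregates(stack, channel, config.threshold_method,
                                 config.fixed_threshold,
                                 config.min_diameter_um.get(channel))
        if layer_boundaries is not None:
            for r in recs:
                assign_layer(r, layer_boundaries)
        aggregates.extend(recs)

    return FieldMeasurement(
        field_id=field_id, genotype=genotype, stage=stage,
        microglia_density_mm3=density, n_microglia=len(cells),
        caspase_pct=caspase_pct, gfap_fraction=gfap, aggregates=aggregates,
    )


def aggregates_to_frame(measurements: Iterable[FieldMeasurement]) -> pd.DataFrame:
    rows = []
    for m in measurements:
        for a in m.aggregates:
            rows.append({
                "field_id": m.field_id, "genotype": m.genotype, "stage": m.stage,
                "channel": a.channel, "label": a.label, "voxel_count": a.voxel_count,
                "volume_um3": a.volume_um3,
                "equivalent_diameter_um": a.equivalent_diameter_um,
                "x_um": a.centroid_um[0], "y_um": a.centroid_um[1],
                "z_um": a.centroid_um[2], "layer": a.layer,
            })
    cols = ["field_id", "genotype", "stage", "channel", "label", "voxel_count",
            "volume_um3", "equivalent_diameter_um", "x_um", "y_um", "z_um", "layer"]
    return pd.DataFrame(rows, columns=cols)


def measurements_to_frame(measurements: Iterable[FieldMeasurement]) -> pd.DataFrame:
    cols = ["field_id", "genotype", "stage", "microglia_density_mm3", "n_microglia",
            "caspase_pct", "gfap_fraction", "n_aggregates"]
    return pd.DataFrame(
        [{**{c: getattr(m, c) for c in cols[:-1]}, "n_aggregates": len(m.aggregates)}
         for m in measurements],
        columns=cols,
    )
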