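"""Seeded synthetic confocal-stack generator with machine-readable ground truth.

The measurement pipeline in this package was designed for retinal confocal
z-stacks of an Alzheimer's mouse model (3xTg-AD vs non-transgenic controls)
that are not publicly deposited.  This module generates multi-channel stacks
with the same statistical structure the pipeline assumes — ramified
branching microglia (Iba1), ganglion-cell nuclei with perinuclear apoptotic
puncta (Hoechst / cleaved caspase-3), filamentous astrocyte signal with a
controllable area fraction (GFAP), and blob-like protein aggregates of
controllable size confined to retinal layers (Aβ / pTau) — together with
exact ground truth for every quantity the pipeline measures.

Microglia are sampled as random recursive bifurcating trees: a soma disk
with ``n_primary`` straight processes, each of which independently
bifurcates with probability ``branch_prob`` per level up to ``max_depth``.
The emitted :class:`CellSpec` stores the centerline polylines and the exact
topology (endpoints / junctions / branches / triple junctions) of the
centerline graph, which is the ground truth the skeleton morphometry is
benchmarked against.

Noise follows the standard fluorescence model: Poisson shot noise on the
signal plus Gaussian background.  All randomness flows from one integer
seed through ``numpy.random.SeedSequence`` keyed by (seed, subsystem,
index) so per-cell draws are independent of iteration order.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
from scipy import ndimage

from .image_core import ImageStack, write_stack

__all__ = [
    "CellParams",
    "CellSpec",
    "AggregateSpec",
    "AggregateTruth",
    "NoiseParams",
    "FieldSpec",
    "GroundTruth",
    "StagePreset",
    "DEFAULT_PRESETS",
    "DEFAULT_CHANNELS",
    "GeometryError",
    "generate_cell",
    "generate_field",
    "iter_stage_series",
    "generate_stage_series",
    "save_ground_truth",
    "load_ground_truth",
]

GT_SCHEMA_VERSION = 1

#: Channel order every generated field uses.
DEFAULT_CHANNELS = ("Hoechst", "Iba1", "GFAP", "Casp3", "Abeta", "pTau")

GENOTYPES = ("3xTg", "nonTg")
STAGES = ("pre", "early", "late")
LAYERS = ("IL", "OL")


class GeometryError(ValueError):
    """A requested geometry does not fit the raster it must be drawn on."""


# ---------------------------------------------------------------------------
# specs and ground-truth records
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CellParams:
    """Parameters of the random bifurcating-tree microglia model.

    All lengths in micrometres.  ``n_primary`` primary processes leave the
    soma at near-evenly spaced angles; at each level a process either
    terminates or splits into exactly two children (probability
    ``branch_prob``), children being shorter by ``child_len_frac``.
    """

    soma_radius_um: float = 2.0
    n_primary: int = 4
    branch_prob: float = 0.5
    max_depth: int = 3
    primary_len_um: tuple[float, float] = (8.0, 12.0)
    child_len_frac: float = 0.7
    min_segment_um: float = 3.5
    thickness_um: float = 0.8
    intensity: float = 100.0
    soma_intensity_factor: float = 2.0


@dataclass
class CellSpec:
    """Ground truth for one rendered microglia cell.

    ``tree`` holds the centerline polylines (each an ``(N, 2)`` array of
    (x, y) µm in patch coordinates) with per-segment thickness; the count
    fields are the exact topology of the centerline graph.
    """

    soma_center_um: tuple[float, float]
    soma_radius_um: float
    tree: list[tuple[np.ndarray, float]]
    n_branches: int
    n_endpoints: int
    n_junctions: int
    n_triple_junctions: int
    intensity: float
    border_touching: bool = False


@dataclass(frozen=True)
class AggregateSpec:
    """One planted ellipsoidal protein aggregate (sphere if radii equal)."""

    center_um: tuple[float, float, float]  # (x, y, z)
    radii_um: tuple[float, float, float]  # (rx, ry, rz)
    layer: str  # "IL" | "OL"
    channel: str  # "Abeta" | "pTau"
    intensity: float = 180.0


@dataclass
class AggregateTruth:
    spec: AggregateSpec
    voxel_count: int
    volume_um3: float


@dataclass(frozen=True)
class NoiseParams:
    """Poisson(signal × photon_scale)/photon_scale + N(bg_mean, bg_sigma).

    ``photon_scale = None`` disables shot noise; ``bg_sigma = 0`` with
    ``bg_mean = 0`` disables the additive background, so the default-free
    configuration is exactly the rendered signal.
    """

    photon_scale: float | None = 30.0
    bg_mean: float = 5.0
    bg_sigma: float = 2.0

    @property
    def noise_free(self) -> bool:
        return self.photon_scale is None and self.bg_mean == 0 and self.bg_sigma == 0


NO_NOISE = NoiseParams(photon_scale=None, bg_mean=0.0, bg_sigma=0.0)


@dataclass
class FieldSpec:
    """Everything needed to render one field deterministically.

    The retina slice is modelled as two horizontal bands: the inner layer
    (IL, containing the ganglion-cell layer) occupies ``y <
    il_fraction × size_um[1]`` and the outer layers (OL) the rest.
    """

    size_um: tuple[float, float] = (102.4, 102.4)
    n_slices: int = 6
    voxel_size_um: tuple[float, float, float] = (0.1, 0.1, 0.5)
    seed: int = 0
    n_microglia: int = 5
    cell_params: CellParams = field(default_factory=CellParams)
    cell_min_sep_um: float = 26.0
    cell_margin_um: float = 14.0
    n_ganglion: int = 30
    nucleus_radius_um: float = 2.5
    nucleus_min_sep_um: float = 8.0
    caspase_fraction: float = 0.05
    caspase_positive: tuple[int, ...] | None = None  # explicit override
    puncta_max_offset_um: float = 2.5
    gfap_fraction: float = 0.1
    aggregates: tuple[AggregateSpec, ...] = ()
    il_fraction: float = 0.45
    noise: NoiseParams = field(default_factory=NoiseParams)
    soma_overlap_tolerance: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.gfap_fraction <= 1.0:
            raise ValueError(f"gfap_fraction must lie in [0, 1], got {self.gfap_fraction}")
        if self.voxel_size_um[2] <= 0:
            raise ValueError("z-step must be positive")
        for agg in self.aggregates:
            if agg.layer not in LAYERS:
                raise ValueError(f"aggregate layer must be one of {LAYERS}, got {agg.layer!r}")

    @property
    def layer_boundaries(self) -> dict[str, tuple[float, float]]:
        y_b = self.il_fraction * self.size_um[1]
        return {"IL": (0.0, y_b), "OL": (y_b, self.size_um[1])}

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        dx, dy, _ = self.voxel_size_um
        nx_ = int(round(self.size_um[0] / dx))
        ny_ = int(round(self.size_um[1] / dy))
        return (self.n_slices, ny_, nx_)


@dataclass
class GroundTruth:
    """Machine-readable truth emitted alongside every rendered field."""

    cells: list[CellSpec]
    n_microglia: int
    n_ganglion_neurons: int
    ganglion_centers_um: np.ndarray  # (N, 2) of (x, y)
    caspase_positive: tuple[int, ...]
    n_caspase_positive: int
    realized_gfap_fraction: float
    aggregates: list[AggregateTruth]
    layer_boundaries: dict[str, tuple[float, float]]


# ---------------------------------------------------------------------------
# seeding
# ---------------------------------------------------------------------------

# subsystem keys for counter-based seed splitting
_S_CELL_PLACE, _S_CELL_GEOM, _S_NUCLEI, _S_CASP, _S_PUNCTA, _S_GFAP, _S_NOISE = range(7)


def _rng(seed: int, *key: int) -> np.random.Generator:
    """Child generator for one subsystem, independent of iteration order."""
    return np.random.default_rng(np.random.SeedSequence((int(seed),) + tuple(int(k) for k in key)))


# ---------------------------------------------------------------------------
# single-cell generation
# ---------------------------------------------------------------------------

def _segment_min_distance(p: np.ndarray, q: np.ndarray) -> tuple[float, np.ndarray]:
    """Min distance between 2-point segments and the midpoint of the gap."""
    best = (np.inf, None)
    for a, b in ((p, q), (q, p)):
        d = b[1] - b[0]
        denom = float(d @ d)
        for pt in a:
            t = 0.0 if denom == 0 else float(np.clip((pt - b[0]) @ d / denom, 0, 1))
            proj = b[0] + t * d
            dist = float(np.hypot(*(pt - proj)))
            if dist < best[0]:
                best = (dist, (pt + proj) / 2)
    return best


def _tree_self_crossing(segments, origin, soma_radius: float) -> bool:
    """True if two non-adjacent strokes would fuse when rendered.

    Pairs sharing a node (parent/child, siblings) are allowed, as are
    near-misses inside the soma disk, which absorbs them anyway.
    """
    origin = np.asarray(origin, dtype=float)
    for i in range(len(segments)):
        pi, ti = segments[i]
        for j in range(i + 1, len(segments)):
            pj, tj = segments[j]
            if any(np.allclose(a, b) for a in (pi[0], pi[-1]) for b in (pj[0], pj[-1])):
                continue
            dist, mid = _segment_min_distance(pi, pj)
            if dist < (ti + tj) / 2 + 0.6 and np.hypot(*(mid - origin)) > soma_radius:
                return True
    return False


def _sample_tree(params: CellParams, rng: np.random.Generator,
                 origin: tuple[float, float],
                 max_attempts: int = 50) -> list[tuple[np.ndarray, float]]:
    """Sample centerline polylines of one bifurcating tree rooted at origin.

    Trees whose strokes would cross (fusing into a non-tree raster) are
    rejected and redrawn, so the emitted topology is exactly what a perfect
    skeletonization of the render recovers.
    """
    for _ in range(max_attempts):
        segments = _sample_tree_once(params, rng, origin)
        if not _tree_self_crossing(segments, origin, params.soma_radius_um):
            return segments
    raise GeometryError(
        f"could not draw a non-self-crossing tree in {max_attempts} attempts; "
        "reduce n_primary, branch_prob or segment lengths"
    )


def _sample_tree_once(params: CellParams, rng: np.random.Generator,
                      origin: tuple[float, float]) -> list[tuple[np.ndarray, float]]:
    segments: list[tuple[np.ndarray, float]] = []
    ox, oy = origin
    n = params.n_primary
    if n <= 0:
        return segments
    base = rng.uniform(0, 2 * np.pi)
    # even spacing with bounded jitter keeps primaries angularly separated
    angles = base + 2 * np.pi * np.arange(n) / n + rng.uniform(-0.22, 0.22, n) * (2 * np.pi / n)
    stack: list[tuple[float, float, float, float, int]] = []  # x, y, angle, length, depth
    for ang in angles:
        length = params.soma_radius_um + rng.uniform(*params.primary_len_um)
        stack.append((ox, oy, float(ang), length, 1))
    while stack:
        x, y, ang, length, depth = stack.pop()
        tip = (x + length * np.cos(ang), y + length * np.sin(ang))
        segments.append((np.array([[x, y], [tip[0], tip[1]]]), params.thickness_um))
        child_len = length * params.child_len_frac
        if (depth < params.max_depth and child_len >= params.min_segment_um
                and rng.random() < params.branch_prob):
            spread = rng.uniform(0.35, 0.60, 2)  # rad; siblings separated by >=40 deg
            stack.append((tip[0], tip[1], ang - spread[0], child_len, depth + 1))
            stack.append((tip[0], tip[1], ang + spread[1], child_len, depth + 1))
    return segments


def centerline_topology(tree: list[tuple[np.ndarray, float]],
                        tol_um: float = 1e-6) -> tuple[int, int, int, int]:
    """Exact (branches, endpoints, junctions, triple junctions) of a centerline tree.

    Builds a graph whose nodes are the distinct polyline vertices (snapped
    to ``tol_um``) and condenses degree-2 nodes, so counts are those of the
    topological graph a perfect skeletonization would recover.
    """
    if not tree:
        return 0, 0, 0, 0
    g = nx.Graph()
    for polyline, _ in tree:
        pts = [tuple(np.round(np.asarray(p) / tol_um).astype(np.int64)) for p in polyline]
        for a, b in zip(pts[:-1], pts[1:]):
            if a != b:
                g.add_edge(a, b)
    degs = dict(g.degree())
    n_end = sum(1 for d in degs.values() if d == 1)
    n_junc = sum(1 for d in degs.values() if d >= 3)
    n_deg2 = sum(1 for d in degs.values() if d == 2)
    n_branches = g.number_of_edges() - n_deg2
    n_triple = sum(1 for d in degs.values() if d == 3)
    return n_branches, n_end, n_junc, n_triple


def _stamp_disk(img: np.ndarray, cy: float, cx: float, radius_px: float, value: float) -> None:
    r = int(np.ceil(radius_px))
    y0, y1 = int(np.floor(cy)) - r, int(np.ceil(cy)) + r + 1
    x0, x1 = int(np.floor(cx)) - r, int(np.ceil(cx)) + r + 1
    y0c, x0c = max(y0, 0), max(x0, 0)
    y1c, x1c = min(y1, img.shape[0]), min(x1, img.shape[1])
    if y0c >= y1c or x0c >= x1c:
        return
    yy, xx = np.mgrid[y0c:y1c, x0c:x1c]
    inside = (yy - cy) ** 2 + (xx - cx) ** 2 <= radius_px ** 2
    region = img[y0c:y1c, x0c:x1c]
    np.maximum(region, np.where(inside, value, 0.0), out=region)


def _render_cell(patch: np.ndarray, spec: CellSpec, pixel_size: float) -> None:
    """Rasterize soma disk plus thick strokes into ``patch`` (max-composited)."""
    cx, cy = spec.soma_center_um
    # soma rendered at twice the process intensity so the intensity-quantile
    # soma segmentation downstream has a core to latch onto
    _stamp_disk(patch, cy / pixel_size, cx / pixel_size,
                spec.soma_radius_um / pixel_size, spec.intensity * 2.0)
    for polyline, thickness in spec.tree:
        radius_px = max(thickness / 2.0 / pixel_size, 0.5)
        for (x0, y0), (x1, y1) in zip(polyline[:-1], polyline[1:]):
            seg_len = float(np.hypot(x1 - x0, y1 - y0))
            n_steps = max(int(np.ceil(seg_len / (0.5 * pixel_size))), 1)
            for t in np.linspace(0.0, 1.0, n_steps + 1):
                px = (x0 + t * (x1 - x0)) / pixel_size
                py = (y0 + t * (y1 - y0)) / pixel_size
                _stamp_disk(patch, py, px, radius_px, spec.intensity)


def generate_cell(
    params: CellParams,
    seed: int,
    pixel_size_um: float = 0.1,
    patch_size_um: tuple[float, float] | None = None,
) -> tuple[np.ndarray, CellSpec]:
    """Render one microglia cell and return (raster patch, ground-truth spec).

    With ``patch_size_um`` unset, the patch is auto-sized to fit the cell
    with a safety margin and the soma is placed at its centre.  With it
    set, any segment whose stroke would leave the patch raises
    :class:`GeometryError` naming the offending segment.
    """
    if params.n_primary < 0:
        raise ValueError(f"n_primary must be >= 0, got {params.n_primary}")
    if params.thickness_um < pixel_size_um:
        raise ValueError(
            f"stroke thickness {params.thickness_um} µm is below one pixel "
            f"({pixel_size_um} µm) after calibration"
        )
    rng = _rng(seed, _S_CELL_GEOM)
    tree = _sample_tree(params, rng, origin=(0.0, 0.0))

    pad = params.thickness_um + params.soma_radius_um + 2.0
    if patch_size_um is None:
        extent = params.soma_radius_um
        for polyline, _ in tree:
            extent = max(extent, float(np.abs(polyline).max()))
        half = extent + pad
        size = (2 * half, 2 * half)
        center = (half, half)
    else:
        size = patch_size_um
        center = (size[0] / 2.0, size[1] / 2.0)

    shifted = [(polyline + np.array(center), th) for polyline, th in tree]
    for idx, (polyline, th) in enumerate(shifted):
        lo = polyline.min(axis=0) - th / 2
        hi = polyline.max(axis=0) + th / 2
        if lo[0] < 0 or lo[1] < 0 or hi[0] > size[0] or hi[1] > size[1]:
            raise GeometryError(
                f"segment {idx} (from {tuple(np.round(polyline[0], 2))} to "
                f"{tuple(np.round(polyline[-1], 2))} µm) exceeds patch bounds {size}"
            )

    n_branches, n_end, n_junc, n_triple = centerline_topology(shifted)
    spec = CellSpec(
        soma_center_um=center,
        soma_radius_um=params.soma_radius_um,
        tree=shifted,
        n_branches=n_branches,
        n_endpoints=n_end,
        n_junctions=n_junc,
        n_triple_junctions=n_triple,
        intensity=params.intensity,
    )
    shape = (int(round(size[1] / pixel_size_um)), int(round(size[0] / pixel_size_um)))
    patch = np.zeros(shape, dtype=np.float64)
    _render_cell(patch, spec, pixel_size_um)
    return patch, spec


# ---------------------------------------------------------------------------
# field generation
# ---------------------------------------------------------------------------

def _sample_separated(rng: np.random.Generator, n: int,
                      lo: np.ndarray, hi: np.ndarray, min_sep: float,
                      max_tries: int = 2000) -> np.ndarray:
    """Best-effort blue-noise sampling of ``n`` points with pairwise separation."""
    pts: list[np.ndarray] = []
    for _ in range(n):
        best = None
        best_d = -1.0
        for _ in range(max_tries):
            cand = rng.uniform(lo, hi)
            if not pts:
                best = cand
                break
            d = min(float(np.hypot(*(cand - p))) for p in pts)
            if d >= min_sep:
                best = cand
                break
            if d > best_d:
                best_d, best = d, cand
        pts.append(np.asarray(best))
    return np.array(pts) if pts else np.empty((0, 2))


def _voxelize_ellipsoid(grid: np.ndarray, spec: AggregateSpec,
                        voxel: tuple[float, float, float]) -> int:
    """Add an ellipsoid to a (Z, Y, X) grid; returns voxel count."""
    dx, dy, dz = voxel
    cx, cy, cz = spec.center_um
    rx, ry, rz = spec.radii_um
    nz, ny, nx_ = grid.shape
    z0 = max(int((cz - rz) / dz) - 1, 0)
    z1 = min(int((cz + rz) / dz) + 2, nz)
    y0 = max(int((cy - ry) / dy) - 1, 0)
    y1 = min(int((cy + ry) / dy) + 2, ny)
    x0 = max(int((cx - rx) / dx) - 1, 0)
    x1 = min(int((cx + rx) / dx) + 2, nx_)
    if z0 >= z1 or y0 >= y1 or x0 >= x1:
        return 0
    zz, yy, xx = np.mgrid[z0:z1, y0:y1, x0:x1]
    zc = (zz + 0.5) * dz
    yc = (yy + 0.5) * dy
    xc = (xx + 0.5) * dx
    inside = (((xc - cx) / rx) ** 2 + ((yc - cy) / ry) ** 2 + ((zc - cz) / rz) ** 2) <= 1.0
    region = grid[z0:z1, y0:y1, x0:x1]
    np.maximum(region, np.where(inside, spec.intensity, 0.0), out=region)
    return int(inside.sum())


def _gfap_mask(rng: np.random.Generator, shape: tuple[int, int], fraction: float) -> np.ndarray:
    """Filamentous mask with area fraction ~exactly ``fraction``.

    An anisotropically smoothed Gaussian random field thresholded at its
    (1 − f) quantile yields elongated streaky structures reminiscent of
    astrocyte processes, with the target fraction hit by construction.
    """
    if fraction <= 0:
        return np.zeros(shape, dtype=bool)
    if fraction >= 1:
        return np.ones(shape, dtype=bool)
    noise = rng.standard_normal(shape)
    smooth = ndimage.gaussian_filter(noise, sigma=(1.5, 8.0))
    thr = np.quantile(smooth, 1.0 - fraction)
    return smooth > thr


def generate_field(spec: FieldSpec) -> tuple[ImageStack, GroundTruth]:
    """Render one multi-channel field and its ground truth.

    Deterministic for a fixed :class:`FieldSpec` (including its seed);
    channels are written in :data:`DEFAULT_CHANNELS` order.
    """
    nz, ny, nx_ = spec.grid_shape
    dx, dy, dz = spec.voxel_size_um
    stack = np.zeros((len(DEFAULT_CHANNELS), nz, ny, nx_), dtype=np.float32)
    ch = {name: stack[i] for i, name in enumerate(DEFAULT_CHANNELS)}
    seed = spec.seed
    sx, sy = spec.size_um
    y_boundary = spec.layer_boundaries["IL"][1]

    # --- microglia (Iba1) ------------------------------------------------
    place_rng = _rng(seed, _S_CELL_PLACE)
    m = spec.cell_margin_um
    centers = _sample_separated(
        place_rng, spec.n_microglia,
        np.array([m, m]), np.array([sx - m, sy - m]), spec.cell_min_sep_um,
    )
    cells: list[CellSpec] = []
    if len(centers) >= 2 and spec.soma_overlap_tolerance >= 0:
        r = spec.cell_params.soma_radius_um
        for i in range(len(centers)):
            for j in range(i + 1, len(centers)):
                if np.hypot(*(centers[i] - centers[j])) < 2 * r * (1 - spec.soma_overlap_tolerance):
                    warnings.warn(f"somata of cells {i} and {j} overlap", stacklevel=2)
    iba_plane = np.zeros((ny, nx_), dtype=np.float64)
    for i, (cx, cy) in enumerate(centers):
        geom_rng = _rng(seed, _S_CELL_GEOM, i)
        tree = _sample_tree(spec.cell_params, geom_rng, origin=(float(cx), float(cy)))
        border = False
        for polyline, th in tree:
            lo = polyline.min(axis=0) - th / 2
            hi = polyline.max(axis=0) + th / 2
            if lo[0] <= 0 or lo[1] <= 0 or hi[0] >= sx or hi[1] >= sy:
                border = True
        nb, ne, nj, nt = centerline_topology(tree)
        cell = CellSpec(
            soma_center_um=(float(cx), float(cy)),
            soma_radius_um=spec.cell_params.soma_radius_um,
            tree=tree,
            n_branches=nb, n_endpoints=ne, n_junctions=nj, n_triple_junctions=nt,
            intensity=spec.cell_params.intensity,
            border_touching=border,
        )
        cells.append(cell)
        _render_cell(iba_plane, cell, dx)
    # extrude the 2D render over the central slices (max projection recovers it)
    z_profile = np.zeros(nz)
    zc = nz // 2
    for k, w in ((zc - 1, 0.6), (zc, 1.0), (zc + 1, 0.6)):
        if 0 <= k < nz:
            z_profile[k] = w
    ch["Iba1"][:] = z_profile[:, None, None] * iba_plane[None, :, :]

    # --- ganglion nuclei (Hoechst) + apoptotic puncta (Casp3) -------------
    nuc_rng = _rng(seed, _S_NUCLEI)
    r_nuc = spec.nucleus_radius_um
    il_lo, il_hi = spec.layer_boundaries["IL"]
    nuclei = _sample_separated(
        nuc_rng, spec.n_ganglion,
        np.array([r_nuc, il_lo + r_nuc]), np.array([sx - r_nuc, il_hi - r_nuc]),
        spec.nucleus_min_sep_um,
    )
    for i, (cx, cy) in enumerate(nuclei):
        cz = (0.3 + 0.4 * nuc_rng.random()) * nz * dz
        _voxelize_ellipsoid(
            ch["Hoechst"],
            AggregateSpec((float(cx), float(cy), float(cz)),
                          (r_nuc, r_nuc, max(r_nuc, dz)), "IL", "Hoechst", intensity=150.0),
            spec.voxel_size_um,
        )
    if spec.caspase_positive is not None:
        positive = tuple(sorted(spec.caspase_positive))
        if any(i >= len(nuclei) for i in positive):
            raise ValueError("caspase_positive index out of range")
    else:
        casp_rng = _rng(seed, _S_CASP)
        marks = casp_rng.random(len(nuclei)) < spec.caspase_fraction
        positive = tuple(int(i) for i in np.flatnonzero(marks))
    punc_rng = _rng(seed, _S_PUNCTA)
    for i in positive:
        cx, cy = nuclei[i]
        for _ in range(int(punc_rng.integers(1, 3))):
            ang = punc_rng.uniform(0, 2 * np.pi)
            dist = punc_rng.uniform(0.8, spec.puncta_max_offset_um)
            px = float(np.clip(cx + dist * np.cos(ang), 0.6, sx - 0.6))
            py = float(np.clip(cy + dist * np.sin(ang), 0.6, sy - 0.6))
            pz = (0.3 + 0.4 * punc_rng.random()) * nz * dz
            _voxelize_ellipsoid(
                ch["Casp3"],
                AggregateSpec((px, py, pz), (0.5, 0.5, max(0.5, dz)), "IL", "Casp3",
                              intensity=200.0),
                spec.voxel_size_um,
            )

    # --- astrocytes (GFAP) ------------------------------------------------
    gfap_rng = _rng(seed, _S_GFAP)
    gfap = _gfap_mask(gfap_rng, (ny, nx_), spec.gfap_fraction)
    realized_gfap = float(gfap.sum() / gfap.size)
    for k in (zc - 1, zc):
        if 0 <= k < nz:
            ch["GFAP"][k][gfap] = 120.0

    # --- protein aggregates (Abeta / pTau) --------------------------------
    agg_truth: list[AggregateTruth] = []
    for agg in spec.aggregates:
        if agg.channel not in ("Abeta", "pTau"):
            raise ValueError(f"aggregate channel must be Abeta or pTau, got {agg.channel!r}")
        count = _voxelize_ellipsoid(ch[agg.channel], agg, spec.voxel_size_um)
        if count == 0:
            raise GeometryError(f"aggregate at {agg.center_um} voxelizes to zero volume")
        agg_truth.append(AggregateTruth(spec=agg, voxel_count=count,
                                        volume_um3=count * dx * dy * dz))

    # --- noise ------------------------------------------------------------
    noise = spec.noise
    if not noise.noise_free:
        noise_rng = _rng(seed, _S_NOISE)
        if noise.photon_scale:
            # Poisson(0) = 0: only voxels carrying signal need sampling
            nonzero = stack > 0
            stack[nonzero] = noise_rng.poisson(
                stack[nonzero].astype(np.float64) * noise.photon_scale
            ).astype(np.float32) / noise.photon_scale
        if noise.bg_sigma > 0 or noise.bg_mean != 0:
            bg = noise_rng.standard_normal(stack.shape, dtype=np.float32)
            stack += noise.bg_sigma * bg + noise.bg_mean
        np.clip(stack, 0.0, None, out=stack)

    image = ImageStack(voxels=stack,
                       calibration=spec.voxel_size_um,
                       channels=DEFAULT_CHANNELS)
    truth = GroundTruth(
        cells=cells,
        n_microglia=len(cells),
        n_ganglion_neurons=len(nuclei),
        ganglion_centers_um=nuclei,
        caspase_positive=positive,
        n_caspase_positive=len(positive),
        realized_gfap_fraction=realized_gfap,
        aggregates=agg_truth,
        layer_boundaries=spec.layer_boundaries,
    )
    return image, truth


# ---------------------------------------------------------------------------
# stage x genotype presets
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class StagePreset:
    """Per-(genotype, stage) generative parameters of the study design.

    ``aggregates`` maps channel → (n_IL, n_OL, (r_lo, r_hi)) sphere counts
    and radius range in µm.
    """

    n_primary: int
    branch_prob: float
    max_depth: int
    n_microglia: int
    caspase_fraction: float
    gfap_fraction: float
    aggregates: dict[str, tuple[int, int, tuple[float, float]]]
    primary_len_um: tuple[float, float] = (5.0, 7.0)


def _agg(n_il: int, n_ol: int, r: tuple[float, float]) -> dict:
    return {"Abeta": (n_il, n_ol, r), "pTau": (n_il, n_ol, r)}


#: Qualitative study conditions: transgenic microglia are hyper-ramified at
#: the pre-symptomatic stage and de-ramified late; microglia density rises
#: only late; astrogliosis is elevated early and normalises late; aggregates
#: exist only in transgenics, confined to the inner layer at the pre stage,
#: spreading to the outer layers and growing thereafter.
DEFAULT_PRESETS: dict[tuple[str, str], StagePreset] = {
    ("nonTg", "pre"): StagePreset(4, 0.45, 2, 5, 0.02, 0.08, _agg(0, 0, (0, 0))),
    ("nonTg", "early"): StagePreset(4, 0.45, 2, 5, 0.02, 0.08, _agg(0, 0, (0, 0))),
    ("nonTg", "late"): StagePreset(4, 0.45, 2, 5, 0.03, 0.08, _agg(0, 0, (0, 0))),
    # hyper-ramified surveillance state: more, longer, more branched processes
    ("3xTg", "pre"): StagePreset(5, 0.85, 2, 5, 0.08, 0.20, _agg(3, 0, (0.5, 0.8)),
                                 primary_len_um=(6.5, 8.5)),
    ("3xTg", "early"): StagePreset(4, 0.45, 2, 5, 0.12, 0.18, _agg(4, 2, (0.8, 1.2))),
    # de-ramified amoeboid-leaning state: fewer, shorter processes, more cells
    ("3xTg", "late"): StagePreset(3, 0.15, 2, 10, 0.18, 0.09, _agg(5, 4, (1.0, 1.4)),
                                  primary_len_um=(4.0, 5.5)),
}

#: Field geometry used for series generation; a down-scaled acquisition
#: (0.2 µm xy sampling over a 128 µm field) that keeps whole fields fast to
#: render while leaving every stroke >= 3 px wide.
SERIES_FIELD = dict(
    size_um=(128.0, 128.0),
    n_slices=6,
    voxel_size_um=(0.2, 0.2, 0.5),
)

_SERIES_CELL = CellParams(
    soma_radius_um=2.0,
    primary_len_um=(5.0, 7.0),
    child_len_frac=0.75,
    min_segment_um=3.0,
    thickness_um=0.7,
)


def _field_spec_for(preset: StagePreset, seed: int, field_seed: int,
                    field_kwargs: dict | None = None) -> FieldSpec:
    kwargs = dict(SERIES_FIELD, cell_min_sep_um=24.0, cell_margin_um=13.0)
    if field_kwargs:
        kwargs.update(field_kwargs)
    params = replace(_SERIES_CELL,
                     n_primary=preset.n_primary,
                     branch_prob=preset.branch_prob,
                     max_depth=preset.max_depth,
                     primary_len_um=preset.primary_len_um)
    spec = FieldSpec(seed=field_seed,
                     n_microglia=preset.n_microglia,
                     cell_params=params,
                     caspase_fraction=preset.caspase_fraction,
                     gfap_fraction=preset.gfap_fraction,
                     **kwargs)
    # plant aggregates with a dedicated stream so counts/radii are reproducible
    agg_rng = _rng(field_seed, 9)
    sx, sy = spec.size_um
    zmax = spec.n_slices * spec.voxel_size_um[2]
    bounds = spec.layer_boundaries
    aggs: list[AggregateSpec] = []
    for channel, (n_il, n_ol, (r_lo, r_hi)) in preset.aggregates.items():
        for layer, n in (("IL", n_il), ("OL", n_ol)):
            lo, hi = bounds[layer]
            for _ in range(n):
                r = float(agg_rng.uniform(r_lo, r_hi))
                cx = float(agg_rng.uniform(r + 0.5, sx - r - 0.5))
                cy = float(agg_rng.uniform(lo + r + 0.5, hi - r - 0.5))
                z_lo, z_hi = min(r, zmax / 2), max(zmax - r, zmax / 2)
                cz = float(agg_rng.uniform(z_lo, z_hi)) if z_hi > z_lo else zmax / 2
                aggs.append(AggregateSpec((cx, cy, cz), (r, r, r), layer, channel))
    return replace(spec, aggregates=tuple(aggs))


def iter_stage_series(
    presets: dict[tuple[str, str], StagePreset] | None = None,
    n_fields: int = 16,
    seed: int = 0,
    field_kwargs: dict | None = None,
):
    """Yield ``(meta dict, ImageStack, GroundTruth)`` for every field of the design.

    The full design is (genotype ∈ {3xTg, nonTg}) × (stage ∈ {pre, early,
    late}) × ``n_fields`` fields, the paper-scale sampling being 16 fields
    per condition.  Fields are generated lazily so callers can process them
    one at a time.
    """
    presets = DEFAULT_PRESETS if presets is None else presets
    for gi, genotype in enumerate(GENOTYPES):
        for si, stage in enumerate(STAGES):
            if (genotype, stage) not in presets:
                raise ValueError(f"preset table is missing cell ({genotype}, {stage})")
    for gi, genotype in enumerate(GENOTYPES):
        for si, stage in enumerate(STAGES):
            preset = presets[(genotype, stage)]
            for fi in range(n_fields):
                field_seed = int(
                    np.random.SeedSequence((int(seed), gi, si, fi)).generate_state(1)[0]
                    % (2 ** 31)
                )
                spec = _field_spec_for(preset, seed, field_seed, field_kwargs)
                stack, truth = generate_field(spec)
                meta = {
                    "field_id": f"{genotype}_{stage}_{fi:03d}",
                    "genotype": genotype,
                    "stage": stage,
                    "field_index": fi,
                    "seed": field_seed,
                }
                yield meta, stack, truth


def generate_stage_series(
    out_dir: str | Path,
    presets: dict[tuple[str, str], StagePreset] | None = None,
    n_fields: int = 16,
    seed: int = 0,
    field_kwargs: dict | None = None,
) -> pd.DataFrame:
    """Write the full stage×genotype dataset (TIFF + ground-truth JSON) to disk.

    Returns the series manifest, which is also written as
    ``manifest.csv`` in ``out_dir``.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for meta, stack, truth in iter_stage_series(presets, n_fields, seed, field_kwargs):
        tiff_path = out_dir / f"{meta['field_id']}.tiff"
        write_stack(stack, tiff_path)
        gt_path = out_dir / f"{meta['field_id']}.truth.json"
        save_ground_truth(truth, gt_path)
        rows.append({**meta, "tiff": tiff_path.name, "ground_truth": gt_path.name,
                     "n_microglia": truth.n_microglia,
                     "n_aggregates": len(truth.aggregates)})
    manifest = pd.DataFrame(rows)
    manifest.to_csv(out_dir / "manifest.csv", index=False)
    return manifest


# ---------------------------------------------------------------------------
# ground-truth serialization (versioned JSON sidecar)
# ---------------------------------------------------------------------------

def _cell_to_dict(c: CellSpec) -> dict:
    return {
        "soma_center_um": list(c.soma_center_um),
        "soma_radius_um": c.soma_radius_um,
        "tree": [{"polyline_um": p.tolist(), "thickness_um": t} for p, t in c.tree],
        "n_branches": c.n_branches,
        "n_endpoints": c.n_endpoints,
        "n_junctions": c.n_junctions,
        "n_triple_junctions": c.n_triple_junctions,
        "intensity": c.intensity,
        "border_touching": c.border_touching,
    }


def _cell_from_dict(d: dict) -> CellSpec:
    return CellSpec(
        soma_center_um=tuple(d["soma_center_um"]),
        soma_radius_um=d["soma_radius_um"],
        tree=[(np.asarray(s["polyline_um"], dtype=float), s["thickness_um"])
              for s in d["tree"]],
        n_branches=d["n_branches"], n_endpoints=d["n_endpoints"],
        n_junctions=d["n_junctions"], n_triple_junctions=d["n_triple_junctions"],
        intensity=d["intensity"], border_touching=d["border_touching"],
    )


def save_ground_truth(truth: GroundTruth, path: str | Path) -> Path:
    path = Path(path)
    doc = {
        "schema_version": GT_SCHEMA_VERSION,
        "cells": [_cell_to_dict(c) for c in truth.cells],
        "n_microglia": truth.n_microglia,
        "n_ganglion_neurons": truth.n_ganglion_neurons,
        "ganglion_centers_um": np.asarray(truth.ganglion_centers_um).tolist(),
        "caspase_positive": list(truth.caspase_positive),
        "n_caspase_positive": truth.n_caspase_positive,
        "realized_gfap_fraction": truth.realized_gfap_fraction,
        "aggregates": [
            {"center_um": list(a.spec.center_um), "radii_um": list(a.spec.radii_um),
             "layer": a.spec.layer, "channel": a.spec.channel,
             "intensity": a.spec.intensity,
             "voxel_count": a.voxel_count, "volume_um3": a.volume_um3}
            for a in truth.aggregates
        ],
        "layer_boundaries": {k: list(v) for k, v in truth.layer_boundaries.items()},
    }
    path.write_text(json.dumps(doc))
    return path


def load_ground_truth(path: str | Path) -> GroundTruth:
    doc = json.loads(Path(path).read_text())
    if doc.get("schema_version") != GT_SCHEMA_VERSION:
        raise ValueError(f"unsupported ground-truth schema {doc.get('schema_version')}")
    return GroundTruth(
        cells=[_cell_from_dict(d) for d in doc["cells"]],
        n_microglia=doc["n_microglia"],
        n_ganglion_neurons=doc["n_ganglion_neurons"],
        ganglion_centers_um=np.asarray(doc["ganglion_centers_um"], dtype=float),
        caspase_positive=tuple(doc["caspase_positive"]),
        n_caspase_positive=doc["n_caspase_positive"],
        realized_gfap_fraction=doc["realized_gfap_fraction"],
        aggregates=[
            AggregateTruth(
                spec=AggregateSpec(tuple(a["center_um"]), tuple(a["radii_um"]),
                                   a["layer"], a["channel"], a["intensity"]),
                voxel_count=a["voxel_count"], volume_um3=a["volume_um3"],
            )
            for a in doc["aggregates"]
        ],
        layer_boundaries={k: tuple(v) for k, v in doc["layer_boundaries"].items()},
    )
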