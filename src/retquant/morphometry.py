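"""Single-cell microglia ramification morphometry.

Microglia continuously remodel their processes: surveillant cells are
highly ramified, activated cells retract processes and enlarge their soma.
This module quantifies that state per cell from a maximum-intensity
projection, following the classical skeleton-analysis workflow: de-speckled
projection → binary mask → whole-cell segmentation → homotopic thinning to
a one-pixel skeleton → skeleton-graph construction → counts (branches,
endpoints, junctions, triple junctions), total process length, soma area,
arborization (scanning-domain) area, and the morphological index
arborization_area / soma_area, which falls as cells de-ramify.

Skeleton pixels are classified by their number of 8-connected skeleton
neighbours (1 → endpoint, 2 → slab, ≥3 → junction); 8-adjacent junction
pixels are merged into one junction node so thick crossings are not double
counted.  Two robustness knobs, both in µm so they are resolution
independent, clean up rasterization artefacts: leaf branches shorter than
``prune_um`` are removed (thinning spurs), and junction pairs closer than
``merge_um`` along the skeleton are collapsed into one node (a thick soma
thins to several nearby junctions rather than one).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import networkx as nx
import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.spatial import ConvexHull, QhullError
from skimage.measure import label, regionprops
from skimage.morphology import skeletonize as _sk_skeletonize, closing, disk

from .image_core import BinaryImage, Image2D, binarize, despeckle

__all__ = [
    "CellMask",
    "SkeletonGraph",
    "MorphometryRecord",
    "MorphometryConfig",
    "segment_cells",
    "skeletonize",
    "build_skeleton_graph",
    "soma_area",
    "arborization_area",
    "morphological_index",
    "analyze_cell",
    "analyze_projection",
    "records_to_frame",
]


@dataclass(frozen=True)
class MorphometryConfig:
    """Tunable parameters of the per-cell analysis (lengths in µm)."""

    binarize_method: str = "otsu"
    fixed_threshold: float | None = None
    min_cell_area_um2: float = 20.0
    soma_method: str = "otsu"
    soma_quantile: float = 0.90
    prune_um: float = 1.2
    merge_um: float = 1.2
    enhance: bool = False


@dataclass
class CellMask:
    """One segmented cell: a single 8-connected component of the binary mask."""

    mask: np.ndarray  # bool, full-image frame
    bbox: tuple[int, int, int, int]  # (min_row, min_col, max_row, max_col)
    border_touching: bool
    calibration: tuple[float, float]
    label: int = 0


@dataclass
class SkeletonGraph:
    """Condensed topological graph of a one-pixel-wide skeleton.

    Nodes are endpoints and (merged) junction clusters; edges are maximal
    slab paths between them, carrying their geodesic length in µm.
    """

    graph: nx.MultiGraph
    calibration: tuple[float, float]

    @property
    def endpoints(self) -> list[tuple[float, float]]:
        """Endpoint coordinates (x, y) in µm."""
        return [d["xy_um"] for _, d in self.graph.nodes(data=True) if d["kind"] == "endpoint"]

    @property
    def junctions(self) -> list[tuple[float, float]]:
        return [d["xy_um"] for _, d in self.graph.nodes(data=True) if d["kind"] == "junction"]

    @property
    def n_endpoints(self) -> int:
        return sum(1 for _, d in self.graph.nodes(data=True) if d["kind"] == "endpoint")

    @property
    def n_junctions(self) -> int:
        return sum(1 for _, d in self.graph.nodes(data=True) if d["kind"] == "junction")

    @property
    def n_branches(self) -> int:
        return self.graph.number_of_edges()

    @property
    def n_triple_junctions(self) -> int:
        return sum(
            1 for n, d in self.graph.nodes(data=True)
            if d["kind"] == "junction" and self.graph.degree(n) == 3
        )

    @property
    def branch_lengths_um(self) -> list[float]:
        return [d["length_um"] for _, _, d in self.graph.edges(data=True)]

    @property
    def total_length_um(self) -> float:
        return float(sum(self.branch_lengths_um))


@dataclass
class MorphometryRecord:
    """Per-cell ramification metrics, one row of the output table."""

    cell_id: int
    soma_area_um2: float
    arborization_area_um2: float
    morphological_index: float
    n_branches: int
    n_endpoints: int
    n_junctions: int
    n_triple_junctions: int
    n_primary_processes: int
    total_process_length_um: float


# ---------------------------------------------------------------------------
# segmentation
# ---------------------------------------------------------------------------

def segment_cells(
    projection: Image2D,
    config: MorphometryConfig = MorphometryConfig(),
) -> list[CellMask]:
    """Segment whole cells from a (despeckled) projection.

    Binarize → 8-connected labelling → discard components below the minimum
    area → flag components touching the image border.  Border-touching
    cells are kept in the list (they still count for density) but are
    excluded from per-cell morphometry downstream, since only cells fully
    contained in the field can be measured.
    """
    try:
        binary = binarize(projection, config.binarize_method, config.fixed_threshold)
    except ValueError:
        if projection.pixels.min() == projection.pixels.max() and projection.pixels.max() <= 0:
            return []
        raise
    labels = label(binary.pixels, connectivity=2)
    min_px = config.min_cell_area_um2 / projection.pixel_area_um2
    out: list[CellMask] = []
    for prop in regionprops(labels):
        if prop.area < min_px:
            continue
        mask = labels == prop.label
        r0, c0, r1, c1 = prop.bbox
        border = r0 == 0 or c0 == 0 or r1 == labels.shape[0] or c1 == labels.shape[1]
        out.append(CellMask(mask=mask, bbox=prop.bbox, border_touching=border,
                            calibration=projection.calibration, label=prop.label))
    return out


# ---------------------------------------------------------------------------
# skeletonization and graph construction
# ---------------------------------------------------------------------------

def _crossing_number(px: np.ndarray, r: int, c: int) -> tuple[int, int]:
    """(0→1 transitions around the pixel, neighbour count) in 8-connectivity."""
    ring = [(r - 1, c), (r - 1, c + 1), (r, c + 1), (r + 1, c + 1),
            (r + 1, c), (r + 1, c - 1), (r, c - 1), (r - 1, c - 1)]
    vals = [bool(px[p]) for p in ring]
    a = sum(1 for v, w in zip(vals, vals[1:] + vals[:1]) if (not v) and w)
    return a, sum(vals)


def _remove_thick_diagonals(px: np.ndarray) -> np.ndarray:
    """Delete simple pixels until no fully filled 2x2 block remains.

    Thinning algorithms occasionally leave 2x2 blocks at diagonal stroke
    crossings; a pixel inside such a block with crossing number 1 can be
    removed without changing connectivity or holes.
    """
    px = np.pad(px.astype(bool), 1)
    changed = True
    while changed:
        changed = False
        blocks = px[:-1, :-1] & px[:-1, 1:] & px[1:, :-1] & px[1:, 1:]
        for r, c in np.argwhere(blocks):
            for rr, cc in ((r, c), (r, c + 1), (r + 1, c), (r + 1, c + 1)):
                if not px[rr, cc]:
                    continue
                a, b = _crossing_number(px, rr, cc)
                if a == 1 and b >= 2:
                    px[rr, cc] = False
                    changed = True
                    break
            if changed:
                break
    return px[1:-1, 1:-1]


def skeletonize(mask: BinaryImage) -> BinaryImage:
    """Homotopic thinning to a one-pixel-wide, 8-connected skeleton.

    Preserves the number of connected components and holes of the input.
    """
    skel = _sk_skeletonize(mask.pixels)
    if (skel[:-1, :-1] & skel[:-1, 1:] & skel[1:, :-1] & skel[1:, 1:]).any():
        skel = _remove_thick_diagonals(skel)
    return BinaryImage(pixels=skel, calibration=mask.calibration)


_NEIGH = np.array([[1, 1, 1], [1, 0, 1], [1, 1, 1]])
_OFFSETS = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]


def _neighbor_counts(skel: np.ndarray) -> np.ndarray:
    return ndimage.convolve(skel.astype(np.uint8), _NEIGH, mode="constant")


def _step_um(p: tuple[int, int], q: tuple[int, int], dx: float, dy: float) -> float:
    return float(np.hypot((p[1] - q[1]) * dx, (p[0] - q[0]) * dy))


def build_skeleton_graph(
    skel: BinaryImage,
    prune_um: float = 0.0,
    merge_um: float = 0.0,
) -> SkeletonGraph:
    """Classify skeleton pixels and condense them into a topological graph.

    Raises if the input is not one pixel wide (contains a fully filled
    2×2 block).  See the module docstring for the meaning of ``prune_um``
    and ``merge_um``; both default to 0 (no cleanup).
    """
    px = skel.pixels.astype(bool)
    dx, dy = skel.calibration
    # Non-thin input: any fully filled 2x3 / 3x2 block cannot come from a
    # thinning pass.  Isolated 2x2 blocks are tolerated: at a diagonal
    # crossing no pixel of the block may be individually deletable without
    # disconnecting an arm, and all four classify as junction pixels, so
    # the cluster merge below absorbs them into one junction node.
    if (px[:-2, :-1] & px[:-2, 1:] & px[1:-1, :-1] & px[1:-1, 1:]
            & px[2:, :-1] & px[2:, 1:]).any() or \
       (px[:-1, :-2] & px[:-1, 1:-1] & px[:-1, 2:] & px[1:, :-2]
            & px[1:, 1:-1] & px[1:, 2:]).any():
        raise ValueError("skeleton is not one pixel wide (contains a filled thick block)")

    counts = _neighbor_counts(px)
    endpoint_px = px & (counts == 1)
    junction_px = px & (counts >= 3)
    slab_px = px & (counts == 2)
    # isolated pixels (counts == 0) represent fully collapsed blobs: no
    # endpoints, no branches — they simply do not enter the graph.

    junc_labels, _ = ndimage.label(junction_px, structure=np.ones((3, 3)))

    def node_of(p: tuple[int, int]):
        if endpoint_px[p]:
            return ("e", p)
        return ("j", int(junc_labels[p]))

    g = nx.MultiGraph()
    ep_coords = np.argwhere(endpoint_px)
    for r, c in ep_coords:
        g.add_node(("e", (int(r), int(c))), kind="endpoint",
                   pixels=[(int(r), int(c))])
    for lab in range(1, junc_labels.max() + 1):
        pix = [tuple(p) for p in np.argwhere(junc_labels == lab)]
        g.add_node(("j", lab), kind="junction", pixels=pix)

    terminal = endpoint_px | junction_px

    def neighbors(p):
        r, c = p
        for dr, dc in _OFFSETS:
            rr, cc = r + dr, c + dc
            if 0 <= rr < px.shape[0] and 0 <= cc < px.shape[1] and px[rr, cc]:
                yield (rr, cc)

    visited_slab = np.zeros_like(px, dtype=bool)
    seen_direct: set[frozenset] = set()

    def trace(start_terminal, first_slab):
        """Walk a slab chain from a terminal until the next terminal."""
        path = [start_terminal, first_slab]
        visited_slab[first_slab] = True
        prev, cur = start_terminal, first_slab
        while True:
            nxts = [q for q in neighbors(cur) if q != prev
                    and not (slab_px[q] and visited_slab[q])]
            term = [q for q in nxts if terminal[q]]
            # prefer a terminal not 8-adjacent to prev (avoid skipping back)
            if term:
                nxt = term[0]
                path.append(nxt)
                return path, nxt
            slabs = [q for q in nxts if slab_px[q]]
            if not slabs:
                return path, None  # dead end (shouldn't happen on clean skeletons)
            nxt = slabs[0]
            visited_slab[nxt] = True
            path.append(nxt)
            prev, cur = cur, nxt

    def path_length(path) -> float:
        return float(sum(_step_um(a, b, dx, dy) for a, b in zip(path[:-1], path[1:])))

    for term_pix in map(tuple, np.argwhere(terminal)):
        u = node_of(term_pix)
        for q in neighbors(term_pix):
            if slab_px[q] and not visited_slab[q]:
                path, end = trace(term_pix, q)
                if end is None:
                    continue
                v = node_of(end)
                g.add_edge(u, v, length_um=path_length(path), path=path)
            elif terminal[q]:
                v = node_of(q)
                if u == v:
                    continue  # same junction cluster
                key = frozenset((u, v))
                if key in seen_direct:
                    continue
                seen_direct.add(key)
                # direct terminal-terminal adjacency: zero-slab branch,
                # but only between distinct nodes and only once
                if not (u[0] == "j" and v[0] == "j"):
                    g.add_edge(u, v, length_um=_step_um(term_pix, q, dx, dy),
                               path=[term_pix, q])

    # slab-only cycles (holes): represent each as one self-looped branch
    for p in map(tuple, np.argwhere(slab_px & ~visited_slab)):
        if visited_slab[p]:
            continue
        cycle = [p]
        visited_slab[p] = True
        prev, cur = None, p
        while True:
            nxts = [q for q in neighbors(cur) if slab_px[q] and not visited_slab[q]]
            if not nxts:
                break
            nxt = nxts[0]
            visited_slab[nxt] = True
            cycle.append(nxt)
            prev, cur = cur, nxt
        g.add_node(("c", p), kind="cycle", pixels=cycle)
        g.add_edge(("c", p), ("c", p), length_um=path_length(cycle + [p]), path=cycle)

    _dissolve_degree2_junctions(g, dx, dy)
    if prune_um > 0:
        _prune_spurs(g, prune_um, dx, dy)
    if merge_um > 0:
        # tiny self-loops on a junction are crossing artefacts, not holes
        for u, v, k, d in list(g.edges(keys=True, data=True)):
            if u == v and d["length_um"] < merge_um:
                g.remove_edge(u, v, k)
        _merge_close_junctions(g, merge_um, dx, dy)

    for n, d in g.nodes(data=True):
        rr = np.array([p[0] for p in d["pixels"]], dtype=float)
        cc = np.array([p[1] for p in d["pixels"]], dtype=float)
        d["xy_um"] = (float(cc.mean() * dx), float(rr.mean() * dy))
    return SkeletonGraph(graph=g, calibration=skel.calibration)


def _dissolve_degree2_junctions(g: nx.MultiGraph, dx: float, dy: float) -> None:
    """Merge through junction nodes with exactly two incident branch ends.

    Corner artefacts of 8-connectivity can give a slab pixel three
    neighbours; after tracing, such a false junction carries two branches
    which are concatenated into one.
    """
    changed = True
    while changed:
        changed = False
        for n, d in list(g.nodes(data=True)):
            if d.get("kind") != "junction" or g.degree(n) != 2:
                continue
            edges = list(g.edges(n, keys=True, data=True))
            if len(edges) != 2:
                continue  # a self-loop contributes degree 2 with one edge
            (_, v1, k1, d1), (_, v2, k2, d2) = edges
            if v1 == n or v2 == n:
                continue
            length = d1["length_um"] + d2["length_um"]
            g.remove_edge(n, v1, k1)
            g.remove_edge(n, v2, k2)
            g.remove_node(n)
            g.add_edge(v1, v2, length_um=length,
                       path=d1["path"][::-1] + d2["path"])
            changed = True


def _prune_spurs(g: nx.MultiGraph, prune_um: float, dx: float, dy: float) -> None:
    """Iteratively remove leaf branches shorter than ``prune_um``.

    A component whose entire skeleton is shorter than the threshold (a
    collapsed blob) is removed outright, leaving no endpoints — matching
    the convention that a soma-only cell has zero branches.
    """
    changed = True
    while changed:
        changed = False
        for n, d in list(g.nodes(data=True)):
            if d.get("kind") != "endpoint" or n not in g:
                continue
            if g.degree(n) != 1:
                if g.degree(n) == 0:
                    g.remove_node(n)
                    changed = True
                continue
            (_, v, k, ed) = next(iter(g.edges(n, keys=True, data=True)))
            if ed["length_um"] < prune_um:
                g.remove_edge(n, v, k)
                g.remove_node(n)
                if g.degree(v) == 0 and v in g:
                    g.remove_node(v)
                changed = True
        _dissolve_degree2_junctions(g, dx, dy)
        # junctions reduced to a single branch end become endpoints
        for n, d in list(g.nodes(data=True)):
            if d.get("kind") == "junction" and g.degree(n) == 1:
                d["kind"] = "endpoint"
                changed = True


def _merge_close_junctions(g: nx.MultiGraph, merge_um: float, dx: float, dy: float) -> None:
    """Contract junction–junction branches shorter than ``merge_um``."""
    changed = True
    while changed:
        changed = False
        for u, v, k, d in list(g.edges(keys=True, data=True)):
            if u == v or u not in g or v not in g:
                continue
            du, dv = g.nodes[u], g.nodes[v]
            if du.get("kind") == "junction" and dv.get("kind") == "junction" \
                    and d["length_um"] < merge_um:
                pixels = du["pixels"] + dv["pixels"] + d["path"]
                g.remove_edge(u, v, k)
                for a, b, kk, dd in list(g.edges(v, keys=True, data=True)):
                    other = b if a == v else a
                    target = u if other == v else other
                    g.add_edge(u, target, length_um=dd["length_um"], path=dd["path"])
                g.remove_node(v)
                g.nodes[u]["pixels"] = pixels
                changed = True
                break
    _dissolve_degree2_junctions(g, dx, dy)


# ---------------------------------------------------------------------------
# areas and the morphological index
# ---------------------------------------------------------------------------

def soma_core_mask(
    projection: Image2D,
    cell: CellMask,
    method: str = "otsu",
    quantile: float = 0.90,
    closing_radius_px: int = 2,
) -> np.ndarray:
    """Binary mask of the soma intensity core (see :func:`soma_area`)."""
    vals = projection.pixels[cell.mask]
    if vals.size == 0:
        raise ValueError(f"cell {cell.label}: empty mask")
    if method == "otsu":
        if vals.min() == vals.max():
            return cell.mask.copy()
        from skimage.filters import threshold_otsu
        thr = float(threshold_otsu(vals, nbins=256))
    elif method == "quantile":
        thr = np.quantile(vals, quantile)
    else:
        raise ValueError(f"unknown soma method {method!r}")
    core = np.zeros_like(cell.mask)
    core[cell.mask] = projection.pixels[cell.mask] >= thr
    labels = label(core, connectivity=2)
    if labels.max() == 0:
        raise ValueError(f"cell {cell.label}: no intensity core above threshold")
    largest = np.argmax(np.bincount(labels.ravel())[1:]) + 1
    core = closing(labels == largest, disk(closing_radius_px))
    return ndimage.binary_fill_holes(core)


def soma_area(
    projection: Image2D,
    cell: CellMask,
    method: str = "otsu",
    quantile: float = 0.90,
    closing_radius_px: int = 2,
) -> float:
    """Soma area (µm²) via an intensity-core surrogate of the manual outline.

    The soma is the brightest compact region of the cell.  With
    ``method="otsu"`` (default) the in-mask intensity histogram is split at
    its Otsu threshold, which separates the bright soma mode from the
    dimmer processes independently of how large the arbor is; a cell with
    uniform intensity (no separable core) yields its whole mask.  With
    ``method="quantile"`` pixels at or above the given in-mask intensity
    quantile are kept instead.  Either way the largest connected component
    is closed morphologically and its pixel count converted to µm².
    """
    core = soma_core_mask(projection, cell, method, quantile, closing_radius_px)
    return float(core.sum() * projection.pixel_area_um2)


def arborization_area(graph: SkeletonGraph) -> float:
    """Scanning-domain area (µm²): convex hull of the process distal ends.

    The manual polygon traced through the distal end of each process is
    approximated by its tightest convex analogue, the convex hull of the
    skeleton endpoints.  Fewer than three endpoints, or collinear ones,
    give zero area.
    """
    pts = np.asarray(graph.endpoints, dtype=float)
    if len(pts) < 3:
        return 0.0
    try:
        hull = ConvexHull(pts)
    except QhullError:
        return 0.0  # degenerate (collinear) endpoint set
    return float(hull.volume)  # 2D ConvexHull: .volume is the area


def morphological_index(arborization_area_um2: float, soma_area_um2: float) -> float:
    """Arborization area over soma area; decreases as microglia de-ramify."""
    if soma_area_um2 <= 0:
        raise ValueError(f"soma area must be positive, got {soma_area_um2}")
    return arborization_area_um2 / soma_area_um2


# ---------------------------------------------------------------------------
# per-cell composition
# ---------------------------------------------------------------------------

def _n_primary_processes(graph: SkeletonGraph, cell: CellMask,
                         soma_center_px: tuple[float, float] | None,
                         soma_radius_um: float) -> int:
    """Branches incident to the soma region (an alternative process count)."""
    if soma_center_px is None:
        return 0
    dx, dy = graph.calibration
    cx_um, cy_um = soma_center_px
    n = 0
    for u, v, d in graph.graph.edges(data=True):
        for node in (u, v):
            x, y = graph.graph.nodes[node]["xy_um"]
            if np.hypot(x - cx_um, y - cy_um) <= soma_radius_um:
                n += 1
                break
    return n


def analyze_cell(
    projection: Image2D,
    cell: CellMask,
    config: MorphometryConfig = MorphometryConfig(),
    cell_id: int = 0,
) -> MorphometryRecord:
    """Full ramification record for one segmented, fully-contained cell."""
    if cell.border_touching:
        raise ValueError(
            f"cell {cell.label} touches the field border; only cells fully "
            "contained in the slice are analyzed"
        )
    skel = skeletonize(BinaryImage(pixels=cell.mask, calibration=cell.calibration))
    graph = build_skeleton_graph(skel, prune_um=config.prune_um, merge_um=config.merge_um)
    core = soma_core_mask(projection, cell, method=config.soma_method,
                          quantile=config.soma_quantile)
    s_area = float(core.sum() * projection.pixel_area_um2)
    rr, cc = np.nonzero(core)
    soma_xy = (float(cc.mean() * cell.calibration[0]),
               float(rr.mean() * cell.calibration[1]))
    # equivalent-disk radius plus one pixel of slack
    soma_radius_um = float(np.sqrt(s_area / np.pi)) + max(cell.calibration)

    a_area = arborization_area(graph)
    return MorphometryRecord(
        cell_id=cell_id,
        soma_area_um2=s_area,
        arborization_area_um2=a_area,
        morphological_index=morphological_index(a_area, s_area),
        n_branches=graph.n_branches,
        n_endpoints=graph.n_endpoints,
        n_junctions=graph.n_junctions,
        n_triple_junctions=graph.n_triple_junctions,
        n_primary_processes=_n_primary_processes(graph, cell, soma_xy, soma_radius_um),
        total_process_length_um=graph.total_length_um,
    )


def analyze_projection(
    projection: Image2D,
    config: MorphometryConfig = MorphometryConfig(),
) -> list[MorphometryRecord]:
    """Segment a projection and analyze every fully-contained cell."""
    from .image_core import enhance_contrast

    img = despeckle(projection)
    if config.enhance:
        img = enhance_contrast(img)
    records = []
    for i, cell in enumerate(segment_cells(img, config)):
        if cell.border_touching:
            continue
        try:
            records.append(analyze_cell(img, cell, config, cell_id=i))
        except ValueError:
            continue  # degenerate component (e.g. no intensity core)
    return records


def records_to_frame(records: Iterable[MorphometryRecord]) -> pd.DataFrame:
    """Morphometry records as a tidy table (one row per cell)."""
    cols = ["cell_id", "soma_area_um2", "arborization_area_um2", "morphological_index",
            "n_branches", "n_endpoints", "n_junctions", "n_triple_junctions",
            "n_primary_processes", "total_process_length_um"]
    return pd.DataFrame([{c: getattr(r, c) for c in cols} for r in records], columns=cols)
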