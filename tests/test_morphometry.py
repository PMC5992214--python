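import networkx as nx
import numpy as np
import pytest

from retquant.image_core import BinaryImage, Image2D
from retquant.morphometry import (MorphometryConfig, SkeletonGraph, analyze_cell,
                                  analyze_projection, arborization_area,
                                  build_skeleton_graph, morphological_index,
                                  segment_cells, skeletonize, soma_area)
from retquant.synthetic import CellParams, generate_cell

CAL = (0.2, 0.2)
CFG = MorphometryConfig(prune_um=1.2, merge_um=1.2)


def skel_from_array(rows, cal=CAL):
    return BinaryImage(np.array(rows, dtype=bool), cal)


def analyze_patch(patch, pixel_size, config=CFG):
    img = Image2D(patch, (pixel_size, pixel_size))
    cells = segment_cells(img, config)
    assert len(cells) == 1
    return analyze_cell(img, cells[0], config)


class TestSegmentCells:
    def test_blank_image_gives_empty_list(self):
        assert segment_cells(Image2D(np.zeros((16, 16)), CAL)) == []

    def test_centered_cell_not_border_touching(self, cell_patch):
        patch, _, px = cell_patch
        cells = segment_cells(Image2D(patch, (px, px)), CFG)
        assert len(cells) == 1 and not cells[0].border_touching

    def test_border_cell_flagged_and_excluded(self):
        px = np.zeros((40, 40))
        px[0:12, 5:9] = 100.0  # touches top border
        cells = segment_cells(Image2D(px, CAL), MorphometryConfig(min_cell_area_um2=0.5))
        assert len(cells) == 1 and cells[0].border_touching
        with pytest.raises(ValueError, match="border"):
            analyze_cell(Image2D(px, CAL), cells[0])

    def test_min_area_filter(self):
        px = np.zeros((30, 30))
        px[5, 5] = 100.0  # 1 px = 0.04 um2, below any sensible floor
        px[15:25, 15:25] = 100.0
        cells = segment_cells(Image2D(px, CAL), MorphometryConfig(min_cell_area_um2=1.0))
        assert len(cells) == 1


class TestSkeletonize:
    def test_one_pixel_line_unchanged(self):
        line = np.zeros((9, 9), dtype=bool)
        line[4, 1:8] = True
        out = skeletonize(BinaryImage(line, CAL))
        np.testing.assert_array_equal(out.pixels, line)

    def test_thick_bar_collapses_to_path_with_two_endpoints(self):
        bar = np.zeros((11, 20), dtype=bool)
        bar[4:7, 2:18] = True
        g = build_skeleton_graph(skeletonize(BinaryImage(bar, CAL)))
        assert g.n_endpoints == 2 and g.n_branches == 1 and g.n_junctions == 0

    def test_rendered_tree_stays_one_component(self, cell_patch):
        from skimage.measure import label

        patch, _, px = cell_patch
        skel = skeletonize(BinaryImage(patch > 0, (px, px)))
        assert label(skel.pixels, connectivity=2).max() == 1


class TestSkeletonGraph:
    def test_plus_shape_topology(self):
        s = np.zeros((17, 17), dtype=bool)
        s[8, :] = True
        s[:, 8] = True
        g = build_skeleton_graph(BinaryImage(s, CAL))
        assert (g.n_endpoints, g.n_junctions, g.n_branches) == (4, 1, 4)
        assert g.n_triple_junctions == 0  # degree 4

    def test_t_shape_topology(self):
        s = np.zeros((17, 17), dtype=bool)
        s[4, 2:15] = True
        s[4:14, 8] = True
        g = build_skeleton_graph(BinaryImage(s, CAL))
        assert (g.n_endpoints, g.n_junctions, g.n_branches) == (3, 1, 3)
        assert g.n_triple_junctions == 1

    def test_degree_sum_equals_twice_edges(self, cell_patch):
        patch, _, px = cell_patch
        g = build_skeleton_graph(skeletonize(BinaryImage(patch > 0, (px, px))),
                                 prune_um=1.2, merge_um=1.2)
        assert sum(dict(g.graph.degree()).values()) == 2 * g.graph.number_of_edges()

    def test_non_thin_input_rejected(self):
        blob = np.zeros((10, 10), dtype=bool)
        blob[2:8, 2:8] = True
        with pytest.raises(ValueError, match="one pixel wide"):
            build_skeleton_graph(BinaryImage(blob, CAL))

    def test_counts_match_generator_ground_truth(self, cell_patch):
        patch, spec, px = cell_patch
        g = build_skeleton_graph(skeletonize(BinaryImage(patch > 0, (px, px))),
                                 prune_um=1.2, merge_um=1.2)
        assert (g.n_branches, g.n_endpoints, g.n_junctions, g.n_triple_junctions) \
            == (spec.n_branches, spec.n_endpoints, spec.n_junctions,
                spec.n_triple_junctions)

    def test_rotation_by_90_degrees_is_lossless(self, cell_patch):
        patch, _, px = cell_patch

        def counts(p):
            g = build_skeleton_graph(skeletonize(BinaryImage(p > 0, (px, px))),
                                     prune_um=1.2, merge_um=1.2)
            return (g.n_branches, g.n_endpoints, g.n_junctions, g.n_triple_junctions)

        assert counts(patch) == counts(np.rot90(patch))


class TestAreas:
    def test_soma_disk_area_near_analytic(self):
        patch, _ = generate_cell(CellParams(n_primary=0, soma_radius_um=3.0),
                                 seed=7, pixel_size_um=0.1)
        img = Image2D(patch, (0.1, 0.1))
        cells = segment_cells(img, MorphometryConfig())
        area = soma_area(img, cells[0])
        assert area == pytest.approx(np.pi * 9.0, rel=0.10)

    def test_identical_somata_with_different_trees_match(self):
        areas = []
        for n_primary, seed in ((2, 5), (5, 9)):
            patch, _ = generate_cell(
                CellParams(n_primary=n_primary, branch_prob=0.8, soma_radius_um=2.5),
                seed=seed, pixel_size_um=0.2)
            img = Image2D(patch, CAL)
            cells = segment_cells(img, CFG)
            areas.append(soma_area(img, cells[0]))
        assert areas[0] == pytest.approx(areas[1], rel=0.05)

    def test_returned_core_contains_soma_center(self, cell_patch):
        # soma rendered at double process intensity must dominate the core
        patch, spec, px = cell_patch
        img = Image2D(patch, (px, px))
        cells = segment_cells(img, CFG)
        rec = analyze_cell(img, cells[0], CFG)
        assert rec.soma_area_um2 > 0
        assert rec.soma_area_um2 == pytest.approx(np.pi * spec.soma_radius_um ** 2,
                                                  rel=0.5)

    def test_square_hull_area(self):
        g = nx.MultiGraph()
        for i, xy in enumerate([(0, 0), (0, 10), (10, 0), (10, 10)]):
            g.add_node(i, kind="endpoint", xy_um=xy, pixels=[])
        assert arborization_area(SkeletonGraph(g, CAL)) == pytest.approx(100.0)

    def test_collinear_endpoints_give_zero(self):
        g = nx.MultiGraph()
        for i, xy in enumerate([(0, 0), (5, 5), (10, 10)]):
            g.add_node(i, kind="endpoint", xy_um=xy, pixels=[])
        assert arborization_area(SkeletonGraph(g, CAL)) == 0.0

    def test_hull_matches_monotone_chain_oracle(self, cell_patch):
        patch, _, px = cell_patch
        g = build_skeleton_graph(skeletonize(BinaryImage(patch > 0, (px, px))),
                                 prune_um=1.2, merge_um=1.2)
        pts = sorted(g.endpoints)

        def cross(o, a, b):
            return (a[0] - o[0]) * (b[1] - o[1]) - (a[1] - o[1]) * (b[0] - o[0])

        def hull_area(points):  # Andrew's monotone chain + shoelace
            lower, upper = [], []
            for p in points:
                while len(lower) >= 2 and cross(lower[-2], lower[-1], p) <= 0:
                    lower.pop()
                lower.append(p)
            for p in reversed(points):
                while len(upper) >= 2 and cross(upper[-2], upper[-1], p) <= 0:
                    upper.pop()
                upper.append(p)
            h = lower[:-1] + upper[:-1]
            return 0.5 * abs(sum(h[i][0] * h[(i + 1) % len(h)][1]
                                 - h[(i + 1) % len(h)][0] * h[i][1]
                                 for i in range(len(h))))

        assert arborization_area(g) == pytest.approx(hull_area(pts), rel=1e-9)

    def test_morphological_index_arithmetic(self):
        assert morphological_index(900.0, 45.0) == pytest.approx(20.0)
        assert morphological_index(0.0, 45.0) == 0.0
        with pytest.raises(ValueError):
            morphological_index(10.0, 0.0)


class TestAnalyzeCell:
    def test_soma_only_cell_record(self):
        patch, _ = generate_cell(CellParams(n_primary=0, soma_radius_um=3.0),
                                 seed=7, pixel_size_um=0.2)
        rec = analyze_patch(patch, 0.2)
        assert rec.n_branches == 0 and rec.morphological_index == 0.0

    def test_record_counts_match_cellspec(self):
        patch, spec = generate_cell(
            CellParams(n_primary=4, branch_prob=1.0, max_depth=2),
            seed=42, pixel_size_um=0.2)
        rec = analyze_patch(patch, 0.2)
        assert (rec.n_branches, rec.n_endpoints, rec.n_junctions,
                rec.n_triple_junctions) == (spec.n_branches, spec.n_endpoints,
                                            spec.n_junctions, spec.n_triple_junctions)
        assert rec.n_primary_processes >= 1
        assert rec.total_process_length_um > 0

    def test_determinism(self, cell_patch):
        patch, _, px = cell_patch
        assert analyze_patch(patch, px) == analyze_patch(patch, px)

    def test_scale_halving_preserves_counts_and_um_areas(self):
        params = CellParams(n_primary=3, branch_prob=0.7, thickness_um=0.8)
        recs = {}
        for px in (0.2, 0.1):
            patch, _ = generate_cell(params, seed=21, pixel_size_um=px)
            recs[px] = analyze_patch(patch, px)
        a, b = recs[0.2], recs[0.1]
        assert (a.n_branches, a.n_endpoints, a.n_junctions) \
            == (b.n_branches, b.n_endpoints, b.n_junctions)
        assert a.arborization_area_um2 == pytest.approx(b.arborization_area_um2, rel=0.1)
        assert a.soma_area_um2 == pytest.approx(b.soma_area_um2, rel=0.15)

    def test_high_ramification_preset_raises_mean_index(self):
        def mean_index(branch_prob, n_primary, length):
            idx = []
            for seed in range(6):
                patch, _ = generate_cell(
                    CellParams(n_primary=n_primary, branch_prob=branch_prob,
                               primary_len_um=length),
                    seed=seed, pixel_size_um=0.2)
                idx.append(analyze_patch(patch, 0.2).morphological_index)
            return np.mean(idx)

        assert mean_index(0.9, 5, (8.0, 12.0)) > mean_index(0.1, 3, (5.0, 7.0))


def test_analyze_projection_skips_border_cells(noise_free_field):
    from retquant.image_core import despeckle, max_projection

    (stack, truth), _ = noise_free_field
    proj = despeckle(max_projection(stack, "Iba1"))
    recs = analyze_projection(proj, CFG)
    n_contained = sum(1 for c in truth.cells if not c.border_touching)
    assert len(recs) == n_contained
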