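import numpy as np
import pytest
from scipy import stats as sps

from retquant.image_core import ImageStack
from retquant.quantification import (AggregateRecord, assign_layer, cell_density,
                                     count_positive_cells, detect_aggregates,
                                     equivalent_diameter, positive_fraction,
                                     summarize_field)
from retquant.synthetic import (AggregateSpec, FieldSpec, NO_NOISE, generate_field)


def empty_stack(channels=("Abeta",), shape=(4, 20, 20), cal=(0.1, 0.1, 0.5)):
    vox = np.zeros((len(channels),) + shape, dtype=np.float32)
    return ImageStack(vox, cal, channels)


class TestCellDensity:
    def test_hand_arithmetic(self):
        assert cell_density(0, 100.0, 10.0) == 0.0
        # one cell in 1e9 um3 (= 1 mm3) is one cell per mm3
        assert cell_density(1, 1e6, 1e3) == pytest.approx(1.0)
        assert cell_density(15, 212.0 * 212.0, 20.0) == pytest.approx(
            15 / (212 * 212 * 20) * 1e9)

    def test_linearity_in_count(self):
        assert cell_density(30, 500.0, 12.0) == pytest.approx(
            2 * cell_density(15, 500.0, 12.0))

    def test_nonpositive_geometry_errors(self):
        with pytest.raises(ValueError):
            cell_density(1, 0.0, 10.0)
        with pytest.raises(ValueError):
            cell_density(1, 10.0, -1.0)


class TestPositiveFraction:
    def test_hand_arithmetic(self):
        assert positive_fraction(0, 80) == 0.0
        assert positive_fraction(4, 80) == pytest.approx(5.0)

    def test_invalid_counts_error(self):
        with pytest.raises(ValueError):
            positive_fraction(5, 0)
        with pytest.raises(ValueError):
            positive_fraction(9, 8)

    def test_bernoulli_marks_within_binomial_ci(self):
        spec = FieldSpec(size_um=(96.0, 96.0), n_slices=2,
                         voxel_size_um=(0.4, 0.4, 0.5), seed=5, n_microglia=0,
                         n_ganglion=500, nucleus_min_sep_um=1.0,
                         caspase_fraction=0.1, gfap_fraction=0.0, noise=NO_NOISE)
        _, truth = generate_field(spec)
        pct = positive_fraction(truth.n_caspase_positive, truth.n_ganglion_neurons)
        half_width = 100 * sps.norm.ppf(0.995) * np.sqrt(0.1 * 0.9 / 500)
        assert abs(pct - 10.0) <= half_width


class TestCountPositiveCells:
    def test_no_puncta_counts_zero(self):
        stack = empty_stack(channels=("Casp3",))
        n, idx = count_positive_cells(stack, np.array([[1.0, 1.0]]))
        assert n == 0 and idx == []

    def test_punctum_on_centroid_counts_one(self):
        stack = empty_stack(channels=("Casp3",), shape=(2, 40, 40), cal=(0.2, 0.2, 0.5))
        stack.voxels[0, 0, 10:14, 10:14] = 200.0  # punctum at ~(2.4, 2.4) um
        n, idx = count_positive_cells(stack, np.array([[2.4, 2.4], [7.0, 7.0]]),
                                      radius_um=2.0)
        assert n == 1 and idx == [0]

    def test_missing_channel_errors(self):
        with pytest.raises(KeyError):
            count_positive_cells(empty_stack(), np.array([[0.0, 0.0]]))

    def test_noise_free_recovery_equals_ground_truth(self, noise_free_field):
        (stack, truth), _ = noise_free_field
        _, recovered = count_positive_cells(stack, truth.ganglion_centers_um,
                                            radius_um=5.0)
        assert sorted(recovered) == sorted(truth.caspase_positive)


class TestDetectAggregates:
    def test_empty_channel_gives_empty_list(self):
        assert detect_aggregates(empty_stack(), "Abeta") == []

    def test_single_voxel_below_diameter_floor(self):
        stack = empty_stack()
        stack.voxels[0, 1, 5, 5] = 100.0
        # one (0.1, 0.1, 0.5) voxel: V = 0.005 um3, d = (6*0.005/pi)^(1/3)
        assert equivalent_diameter(0.005) == pytest.approx(0.2122, abs=1e-3)
        assert detect_aggregates(stack, "Abeta", "fixed", fixed_threshold=10.0) == []
        unfiltered = detect_aggregates(stack, "Abeta", "fixed", fixed_threshold=10.0,
                                       min_diameter_um=0.0)
        assert len(unfiltered) == 1
        assert unfiltered[0].volume_um3 == pytest.approx(0.005)

    def test_rendered_sphere_volume(self):
        spec = FieldSpec(size_um=(25.6, 25.6), n_slices=10,
                         voxel_size_um=(0.1, 0.1, 0.5), seed=1, n_microglia=0,
                         n_ganglion=0, gfap_fraction=0.0,
                         aggregates=(AggregateSpec((12.0, 6.0, 2.5), (1.5, 1.5, 1.5),
                                                   "IL", "Abeta"),),
                         noise=NO_NOISE)
        stack, _ = generate_field(spec)
        recs = detect_aggregates(stack, "Abeta")
        assert len(recs) == 1
        assert recs[0].volume_um3 == pytest.approx(4 / 3 * np.pi * 1.5 ** 3, rel=0.15)

    def test_filter_monotone_in_floor(self, noise_free_field):
        (stack, _), _ = noise_free_field
        floors = [0.0, 0.58, 1.0, 2.0, 5.0]
        counts = [len(detect_aggregates(stack, "Abeta", min_diameter_um=f))
                  for f in floors]
        assert counts == sorted(counts, reverse=True)

    def test_volume_conservation_before_filtering(self, noise_free_field):
        (stack, _), _ = noise_free_field
        recs = detect_aggregates(stack, "Abeta", "fixed", fixed_threshold=0.0,
                                 min_diameter_um=0.0)
        total = sum(r.volume_um3 for r in recs)
        foreground = int((stack.channel_voxels("Abeta") > 0).sum())
        assert total == pytest.approx(foreground * stack.voxel_volume_um3)

    def test_diameter_consistent_with_volume(self, noise_free_field):
        (stack, _), _ = noise_free_field
        for r in detect_aggregates(stack, "Abeta"):
            assert r.equivalent_diameter_um == pytest.approx(
                (6 * r.volume_um3 / np.pi) ** (1 / 3))
            assert r.volume_um3 == pytest.approx(r.voxel_count * stack.voxel_volume_um3)


class TestAssignLayer:
    BOUNDS = {"IL": (0.0, 30.0), "OL": (30.0, 64.0)}

    def rec(self, y):
        return AggregateRecord(1, "Abeta", 10, 1.0, 1.0, (5.0, y, 1.0))

    def test_band_assignment(self):
        assert assign_layer(self.rec(10.0), self.BOUNDS) == "IL"
        assert assign_layer(self.rec(45.0), self.BOUNDS) == "OL"

    def test_outside_bands_errors(self):
        with pytest.raises(ValueError, match="outside"):
            assign_layer(self.rec(99.0), self.BOUNDS)

    def test_every_detected_aggregate_gets_one_layer(self, noise_free_field):
        (stack, truth), _ = noise_free_field
        for channel in ("Abeta", "pTau"):
            for r in detect_aggregates(stack, channel):
                layer = assign_layer(r, truth.layer_boundaries)
                assert layer in ("IL", "OL")
        # and layers match where the generator planted them
        got = {r.channel: assign_layer(r, truth.layer_boundaries)
               for ch in ("Abeta", "pTau") for r in detect_aggregates(stack, ch)}
        planted = {a.spec.channel: a.spec.layer for a in truth.aggregates}
        assert got == planted


class TestSummarizeField:
    def test_empty_field_is_all_zero(self):
        spec = FieldSpec(size_um=(25.6, 25.6), n_slices=2,
                         voxel_size_um=(0.2, 0.2, 0.5), seed=9, n_microglia=0,
                         n_ganglion=0, gfap_fraction=0.0, noise=NO_NOISE)
        stack, truth = generate_field(spec)
        m = summarize_field(stack, truth, field_id="empty")
        assert m.microglia_density_mm3 == 0.0
        assert m.caspase_pct == 0.0
        assert m.gfap_fraction == 0.0
        assert m.aggregates == []

    def test_same_field_twice_identical(self, noise_free_field):
        (stack, truth), _ = noise_free_field
        m1 = summarize_field(stack, truth, field_id="f")
        m2 = summarize_field(stack, truth, field_id="f")
        assert m1 == m2

    def test_recovers_generated_content(self, noise_free_field):
        (stack, truth), spec = noise_free_field
        m = summarize_field(stack, truth, field_id="f")
        assert m.n_microglia == truth.n_microglia
        assert m.gfap_fraction == pytest.approx(truth.realized_gfap_fraction, abs=0.02)
        assert len(m.aggregates) == len(truth.aggregates)
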