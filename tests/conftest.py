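import numpy as np
import pytest

from retquant.image_core import Image2D, ImageStack
from retquant.synthetic import (AggregateSpec, CellParams, FieldSpec, NO_NOISE,
                                generate_field)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def small_stack(rng):
    """A tiny random 2-channel stack with realistic calibration."""
    voxels = rng.uniform(0, 100, size=(2, 3, 16, 16))
    return ImageStack(voxels=voxels, calibration=(0.1, 0.1, 0.5),
                      channels=("Iba1", "GFAP"))


@pytest.fixture
def cell_patch():
    """One rendered mid-complexity microglia and its ground-truth spec."""
    from retquant.synthetic import generate_cell

    params = CellParams(n_primary=4, branch_prob=0.6, thickness_um=0.8)
    patch, spec = generate_cell(params, seed=42, pixel_size_um=0.2)
    return patch, spec, 0.2


@pytest.fixture(scope="session")
def noise_free_field():
    """A small noise-free field: channel supports equal ground-truth masks."""
    spec = FieldSpec(
        size_um=(64.0, 64.0), n_slices=4, voxel_size_um=(0.2, 0.2, 0.5),
        seed=77, n_microglia=2, cell_min_sep_um=24.0, cell_margin_um=13.0,
        cell_params=CellParams(n_primary=3, branch_prob=0.5,
                               primary_len_um=(5.0, 7.0), min_segment_um=3.0),
        n_ganglion=12, caspase_fraction=0.25, gfap_fraction=0.15,
        aggregates=(
            AggregateSpec((20.0, 10.0, 1.0), (1.0, 1.0, 1.0), "IL", "Abeta"),
            AggregateSpec((40.0, 50.0, 1.0), (0.8, 0.8, 0.8), "OL", "pTau"),
        ),
        noise=NO_NOISE,
    )
    return generate_field(spec), spec
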