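import logging

import numpy as np
import pytest

from phenoscope import AcquisitionSpec, CellSpec, generate_field, random_cells

logging.getLogger("phenoscope").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def small_spec():
    """A small, fast acquisition with default optics and noise."""
    return AcquisitionSpec(n_slices=12, frame_shape=(160, 160))


@pytest.fixture(scope="session")
def clean_spec():
    """Same geometry with PSF and noise disabled (pure rendering)."""
    return AcquisitionSpec(
        n_slices=12, frame_shape=(160, 160),
        psf_sigma_xy=0.0, psf_sigma_z=0.0, noise_read_sd=0.0, photon_scale=None,
    )


@pytest.fixture(scope="session")
def mixed_field(small_spec):
    """One rendered field of 12 cytoplasmic/nuclear cells plus truth."""
    cells = random_cells(
        small_spec, 12, seed=7, class_mix={"cytoplasmic": 0.5, "nuclear": 0.5}
    )
    return generate_field(small_spec, cells, seed=3)


@pytest.fixture()
def one_cell(small_spec):
    """Factory for single-cell fields at the frame center."""

    def make(spec=None, seed=5, **kwargs):
        spec = spec or small_spec
        ext = spec.extent_um
        defaults = dict(
            center=(ext[0] / 2, ext[1] / 2, ext[2] / 2), diameter=4.0
        )
        defaults.update(kwargs)
        return generate_field(spec, [CellSpec(**defaults)], seed=seed)

    return make
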