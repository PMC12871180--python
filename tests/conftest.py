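import numpy as np
import pytest

import morphgwr as mg


@pytest.fixture(scope="session")
def small_sample():
    """A small noisy spot with one spatially heterogeneous marker."""
    fields = {
        "het": (
            mg.FieldSpec("gaussian-bump", 1.0, 64.0, offset=4.0),
            mg.FieldSpec("zero-mean-sinusoid", 1.0, 128.0),
        )
    }
    return mg.simulate_sample(
        n_cells=120, shape=(256, 256), beta_fields=fields, noise_sd=0.2, seed=11
    )


@pytest.fixture(scope="session")
def small_cells(small_sample):
    return mg.build_cell_table(small_sample.label_image, small_sample.channels)


@pytest.fixture(scope="session")
def het_table():
    """Cell-level observation table with a sinusoidal slope field."""
    fields = {
        "m": (
            mg.FieldSpec("gaussian-bump", 1.0, 64.0, offset=2.0),
            mg.FieldSpec("zero-mean-sinusoid", 1.0, 128.0),
        )
    }
    coords, scores, resp, truth = mg.simulate_cell_table(
        n_cells=200, shape=(256, 256), beta_fields=fields, noise_sd=0.2, seed=5
    )
    return mg.ObservationTable.from_arrays(resp["m"], scores, coords), truth
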