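import numpy as np
import pytest

from thermopept.preprocess import ThermogramRecord, final_grid


@pytest.fixture
def analysis_grid():
    """The common 45-90 °C, 0.1 °C analysis grid."""
    return final_grid()


def make_final(values, grid=None, group="control", sample_id="s1"):
    """Wrap an array as a final-stage thermogram on the analysis grid."""
    if grid is None:
        grid = final_grid()
    return ThermogramRecord(
        sample_id=sample_id,
        group=group,
        temperatures=grid,
        values=np.asarray(values, dtype=float),
        stage="final",
    )


def gaussian(grid, center, sigma, height=1.0):
    return height * np.exp(-0.5 * ((grid - center) / sigma) ** 2)


@pytest.fixture
def make_final_record():
    return make_final


@pytest.fixture
def gaussian_curve():
    return gaussian
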