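import numpy as np
import pytest

from gdglcm.synthetic import CellImage, SynthConfig, generate_dataset


@pytest.fixture(scope="session")
def small_cells():
    """A dozen cells, enough to exercise the featurize/train plumbing."""
    return generate_dataset(SynthConfig(n_per_class=6, size_range=(20, 40), seed=123))


@pytest.fixture(scope="session")
def default_cells():
    """200 cells at the default size range (shared; treat as read-only)."""
    return generate_dataset(SynthConfig(n_per_class=100, seed=11))


def make_cell(pixels, mask=None, label="healthy", cell_id="c0"):
    return CellImage(pixels=np.asarray(pixels, dtype=float), mask=mask,
                     label=label, cell_id=cell_id)
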