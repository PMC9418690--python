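import warnings

import numpy as np
import pytest

from morphoscreen import pipeline
from morphoscreen.imaging import segment_field
from morphoscreen.presets import POPULATION_PRESETS
from morphoscreen.simulate import render_field


@pytest.fixture(autouse=True)
def _quiet_expected_warnings():
    # rendered fixtures intentionally hit degenerate-input warnings
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        yield


@pytest.fixture(scope="session")
def small_soft_field():
    """A 25-cell soft-substrate field with ground truth (session-cached)."""
    pop = POPULATION_PRESETS["control_soft"].with_(n_cells=25, seed=101)
    return render_field(pop, (768, 768))


@pytest.fixture(scope="session")
def segmented_soft_field(small_soft_field):
    fld, gt = small_soft_field
    cells, nuclei, removed = segment_field(fld)
    return fld, gt, cells, nuclei, removed


@pytest.fixture(scope="session")
def soft_classifier():
    """Exemplar classifier for the soft-substrate classes (session-cached)."""
    return pipeline.train_exemplar_classifier(
        pipeline.SOFT_CLASSES, n_per_class=12, seed=5
    )
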