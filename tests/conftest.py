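import numpy as np
import pytest

from latentpcm.pcm import ItemBank
from latentpcm.questionnaire import ItemSpec, ResponseMatrix
from latentpcm.simulate import default_items


@pytest.fixture
def items_bank():
    """Five 4-category items with spread locations, plus their true bank."""
    items, thr = default_items()
    bank = ItemBank([s.item_id for s in items], [thr[s.item_id] for s in items])
    return items, thr, bank


@pytest.fixture
def small_matrix():
    """A tiny 4-person, 3-item matrix with one missing cell."""
    vals = np.array([[0.0, 1.0, 2.0],
                     [1.0, 0.0, 1.0],
                     [2.0, 2.0, np.nan],
                     [1.0, 1.0, 0.0]])
    return ResponseMatrix(vals, np.array([1, 2, 3, 4]), ["A", "B", "C"])


@pytest.fixture
def dichotomous_specs():
    return [ItemSpec("A", 2), ItemSpec("B", 2)]
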