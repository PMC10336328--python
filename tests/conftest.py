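import numpy as np
import pytest

from thrombosim.histology import HistologySection, Label


def uniform_section(label: Label, n: int = 20, pixel_size_um: float = 100.0) -> HistologySection:
    """Square section entirely of one thrombus label (no background)."""
    return HistologySection(labels=np.full((n, n), np.uint8(label)),
                            pixel_size_um=pixel_size_um)


@pytest.fixture
def all_rbc_section() -> HistologySection:
    return uniform_section(Label.RBC)


@pytest.fixture
def all_fibrin_section() -> HistologySection:
    return uniform_section(Label.FIBRIN)


@pytest.fixture
def mixed_columns_section() -> HistologySection:
    """Left half RBC, right half fibrin; 20x20 at 100 um."""
    labels = np.full((20, 20), np.uint8(Label.RBC))
    labels[:, 10:] = np.uint8(Label.FIBRIN)
    return HistologySection(labels=labels, pixel_size_um=100.0)
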