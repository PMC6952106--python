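import numpy as np
import pytest

from placentometry.datamodel import LabelMap
from placentometry.synthgen import SynthConfig, make_nuclei


@pytest.fixture
def half_field():
    """100x100 field: left half MBS (code 1), right half SynT (code 3)."""
    pixels = np.zeros((100, 100), dtype=np.int32)
    pixels[:, :50] = 1
    pixels[:, 50:] = 3
    return LabelMap(pixels=pixels, pixel_size=1.0, legend={1: "MBS", 3: "SynT"})


@pytest.fixture(scope="session")
def stgc_dataset():
    """200 S-TGC nuclei (E16.5 ploidy distribution) + 50 amnion references."""
    cfg = SynthConfig(
        seed=42, nuclei_per_field={"S-TGC": 200, "amnion": 50}
    )
    img, nuclei, truth = make_nuclei(cfg)
    return img, nuclei, truth
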