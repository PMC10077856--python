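import numpy as np
import pytest

from saxskit import synth
from saxskit.readers import Diffractogram, PDHHeader


@pytest.fixture
def simple_diffractogram() -> Diffractogram:
    q = np.linspace(0.5, 5.0, 200)
    intensity = 1.0 + np.exp(-((q - 2.0) ** 2) / 0.02)
    return Diffractogram(q=q, intensity=intensity, label="simple")


@pytest.fixture
def pdh_header() -> PDHHeader:
    return PDHHeader(
        description="test sample",
        keyword_line="SAXS",
        int_block=[0, 0, 0, 0, 0, 0, 0, 0],
        real_blocks=[0.0, 1.0, 0.0, 0.0, 0.0, 0.154, 0.0, 0.0, 0.0, 0.0],
        extra_xml="<meta><instrument>test</instrument></meta>",
    )


@pytest.fixture
def hexagonal_truth() -> synth.GroundTruth:
    return synth.GroundTruth(phase="H1", a=2.87, n_reflections=3, snr=50.0, seed=1)


@pytest.fixture
def hexagonal_curve(hexagonal_truth) -> Diffractogram:
    return synth.generate(hexagonal_truth)
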