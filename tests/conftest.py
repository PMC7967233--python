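import warnings

import numpy as np
import pytest

from fmmseg import SynthConfig, make_case
from fmmseg import segment as _segment


@pytest.fixture
def solid_case():
    """A clean 10 mm solid-round isolated nodule at the lowest-noise setting."""
    return make_case(
        SynthConfig(
            category="solid-round",
            diameter_mm=10.0,
            tube_current_mA=197.0,
            rng_seed=12345,
        )
    )


@pytest.fixture
def segment_quiet():
    """Run the pipeline with pipeline warnings (empty-mask etc.) silenced."""

    def run(img, *args, **kwargs):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            return _segment(img, *args, **kwargs)

    return run


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
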