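import warnings

import numpy as np
import pytest

from roit import PhantomParams, generate_phantom_pair
from roit.pipeline import ScaleSpec


@pytest.fixture(scope="session")
def phantom():
    """One default-condition phantom pair (full histology render)."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return generate_phantom_pair(PhantomParams(seed=1))


@pytest.fixture(scope="session")
def phantom_fast():
    """Default-condition phantom without the histology render (geometry
    only; bit-identical ROIs/landmarks to the rendered pair)."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return generate_phantom_pair(PhantomParams(seed=1),
                                     render_histology=False)


def reversed_spec(pair):
    return ScaleSpec(source_line=pair.lines.target_line,
                     target_line=pair.lines.source_line)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
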