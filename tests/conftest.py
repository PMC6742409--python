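import numpy as np
import pytest

from cortexstim import (ActivationParams, FieldSource, make_fiber,
                        synthesize_arbor)


@pytest.fixture
def anodal_plate():
    """Default surface electrode: 150 μm square plate, +100 μA."""
    return FieldSource(kind="square_plate", current_ua=100.0)


@pytest.fixture
def point_source():
    return FieldSource(kind="point", center=(0.0, 0.0, 0.0),
                       current_ua=100.0)


@pytest.fixture
def params():
    return ActivationParams()


@pytest.fixture
def horizontal_fiber():
    """400 μm horizontal fiber at 60 μm depth, 1 μm sampling."""
    return make_fiber((-200.0, 0.0, 60.0), (1.0, 0.0, 0.0), 400.0, 1.0)


@pytest.fixture
def vertical_fiber():
    """400 μm vertical fiber starting 20 μm below the electrode center."""
    return make_fiber((0.0, 0.0, 20.0), (0.0, 0.0, 1.0), 400.0, 1.0)


@pytest.fixture
def small_arbor():
    return synthesize_arbor("vertical_dominant", seed=7)
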