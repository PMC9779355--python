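import numpy as np
import pytest

from habicon.grids import GridLayer, EnvStack


def make_layer(values, cellsize=1.0, origin=None, mask=None, kind="continuous"):
    values = np.asarray(values, dtype=float)
    if origin is None:
        origin = (0.0, values.shape[0] * cellsize)
    if mask is None:
        mask = np.zeros(values.shape, dtype=bool)
    return GridLayer(values, cellsize, origin, mask, "test", kind)


@pytest.fixture
def layer_factory():
    return make_layer


@pytest.fixture(scope="session")
def strong_signal_landscape():
    """Synthetic landscape with one dominant variable; shared because the
    downstream fits are the expensive part of the suite."""
    from habicon.synthetic import SyntheticSpec, landscape_and_presences

    spec = SyntheticSpec(
        shape=(50, 50), n_continuous=3, smoothness=5,
        true_response={"Bio1": 20.0}, intercept=-24.0,
        n_presences=150, seed=1,
    )
    return landscape_and_presences(spec)
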