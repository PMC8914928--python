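import numpy as np
import pytest

import spatialaq as sa


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture
def smooth_field():
    """A strongly autocorrelated synthetic field at desk scale."""
    return sa.simulate_field(
        sa.FieldSpec(bbox=(0, 0, 1000, 1000), n_points=200,
                     covariance="exponential", range_=250.0, sill=100.0,
                     nugget=1.0, mean=60.0, seed=42)
    )


@pytest.fixture
def small_layer(smooth_field):
    """Aggregated hexagon layer (non-empty cells only) with weights."""
    layer = sa.make_hex_grid(smooth_field.bbox(), 150.0)
    agg = sa.aggregate(smooth_field, layer).nonempty()
    W = sa.contiguity_weights(agg, style="row-standardized")
    return agg, W
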