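import numpy as np
import pandas as pd
import pytest

from nichemap import simulate


@pytest.fixture(scope="session")
def small_tissue():
    """One compact region with all placement kinds, reused across tests."""
    cfg = simulate.SimTissueConfig(
        image_shape=(320, 320),
        n_regions=1,
        tumor_nests=(((110.0, 110.0), 60.0),),
        cell_types=(
            simulate.CellTypeSpec("Tumor", 60, ("in_nest",)),
            simulate.CellTypeSpec("IL4I1 TAM", 40, ("ring", 30.0, 8.0)),
            simulate.CellTypeSpec("SPP1 TAM", 40, ("ring", 36.0, 8.0)),
            simulate.CellTypeSpec("FOLR2 TRM", 40, ("ring", 80.0, 10.0)),
            simulate.CellTypeSpec("Stroma", 40, ("uniform",)),
        ),
        markers=simulate._DEFAULT_MARKERS,
        marker_model=simulate.make_marker_model(
            {**simulate._DEFAULT_POSITIVE, "Stroma": ()},
            simulate._DEFAULT_MARKERS,
            separation=3.0,
        ),
        seed=11,
    )
    return simulate.simulate_tissue(cfg)


@pytest.fixture()
def random_cells():
    """Random typed point pattern over two regions (no images)."""
    rng = np.random.default_rng(42)
    n = 500
    return pd.DataFrame(
        {
            "cell_id": np.arange(1, n + 1),
            "region_id": np.repeat([0, 1], n // 2),
            "x_um": rng.uniform(0, 300, n),
            "y_um": rng.uniform(0, 300, n),
            "cell_type": rng.choice(["Tumor", "IL4I1 TAM", "FOLR2 TRM", "Stroma"], n),
        }
    )
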