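import numpy as np
import pandas as pd
import pytest

from memic import (
    CellTable,
    ChamberMeta,
    OpeningSpec,
    SceneParams,
    assign_distance,
    generate_scene,
)


@pytest.fixture(scope="session")
def noiseless_scene():
    """Small noiseless scene with integer intensities: exact measurement fixture."""
    params = SceneParams(
        field_width=600,
        field_height=400,
        n_cells=40,
        noise_sd=0.0,
        min_center_spacing=16,
        nuclear_intensity=2000,
        background_level=100,
        reporter_functions={"gfp": lambda x: float(int(x))},  # integer-valued
        rng_seed=7,
    )
    return generate_scene(params)


@pytest.fixture(scope="session")
def noisy_scene():
    """SNR-5 scene with a linear reporter gradient."""
    params = SceneParams(
        field_width=1000,
        field_height=600,
        n_cells=150,
        noise_sd=380.0,
        min_center_spacing=15,
        reporter_functions={"gfp": lambda x: 200 + 1.5 * x},
        rng_seed=21,
    )
    return generate_scene(params)


def make_table(distances, values, value_col="v", assign=True):
    """Cell table on a line: one cell per (distance, value) pair."""
    distances = np.asarray(distances, dtype=float)
    df = pd.DataFrame(
        {
            "cell_id": np.arange(1, len(distances) + 1),
            "x_um": distances,
            "y_um": 0.0,
            "area_um2": 1.0,
            value_col: np.asarray(values, dtype=float),
        }
    )
    table = CellTable(df=df, meta=ChamberMeta())
    if assign:
        table = assign_distance(table, OpeningSpec("left", 0.0))
    return table
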