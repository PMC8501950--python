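import numpy as np
import pandas as pd
import pytest

from qibckit import CellTable, SceneConfig, make_scene, render_scene


@pytest.fixture(scope="session")
def noiseless_config():
    # background 0 so measured means equal true means exactly
    return SceneConfig(
        field_shape=(512, 512),
        n_nuclei=25,
        radius_range=(9.0, 13.0),
        noise_sd=0.0,
        background_level=0.0,
        dapi_per_c=500_000.0,
        seed=11,
    )


@pytest.fixture(scope="session")
def noiseless_scene(noiseless_config):
    return make_scene(noiseless_config)


@pytest.fixture(scope="session")
def noiseless_field(noiseless_scene):
    return render_scene(noiseless_scene)


@pytest.fixture(scope="session")
def noisy_field_and_scene():
    config = SceneConfig(
        field_shape=(1024, 1024),
        n_nuclei=50,
        radius_range=(10.0, 14.0),
        noise_sd=220.0,
        background_level=100.0,
        dapi_per_c=1_000_000.0,
        seed=7,
    )
    scene = make_scene(config)
    return render_scene(scene), scene


def make_cell_table(
    totals,
    channel_means=None,
    condition="",
    channels=("DAPI", "EdU", "PCNA"),
    field_id="f0",
):
    """Build a CellTable directly from per-nucleus values (test helper)."""
    totals = np.asarray(totals, dtype=float)
    n = totals.size
    data = {
        "field_id": [field_id] * n,
        "label": np.arange(1, n + 1),
        "area": np.full(n, 100, dtype=int),
        "centroid_row": np.zeros(n),
        "centroid_col": np.zeros(n),
        "total_dapi": totals,
        "border_touching": [False] * n,
        "condition": [condition] * n,
    }
    channel_means = channel_means or {}
    for ch in channels:
        data[f"mean_{ch}"] = np.asarray(
            channel_means.get(ch, np.full(n, 1.0)), dtype=float
        )
    return CellTable(pd.DataFrame(data), tuple(channels))
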