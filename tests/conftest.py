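import numpy as np
import pytest

import npcstorm as ns


@pytest.fixture
def small_field():
    """A compact simulated nucleus (2.5 µm disk) for fast clustering tests."""
    params = ns.NPCFieldParams(roi=ns.disk_roi(2500.0), seed=7)
    table, truth = ns.simulate_npc_field(params)
    return table, truth, params


@pytest.fixture
def default_field():
    """One full-size simulated nucleus at default imaging statistics."""
    params = ns.NPCFieldParams(seed=11)
    table, truth = ns.simulate_npc_field(params)
    return table, truth, params


def make_table(x, y, sigma=None, frame=None, frame_count=None):
    """Hand-built localization table for arithmetic-level tests."""
    import pandas as pd

    n = len(x)
    df = pd.DataFrame(
        {
            "frame": np.asarray(frame if frame is not None else np.ones(n), np.int64),
            "x": np.asarray(x, float),
            "y": np.asarray(y, float),
            "sigma": np.asarray(sigma if sigma is not None else np.full(n, 150.0)),
        }
    )
    fc = frame_count if frame_count is not None else (int(df["frame"].max()) if n else 0)
    return ns.LocalizationTable(df, source_id="test", frame_count=fc)
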