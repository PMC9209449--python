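import numpy as np
import pandas as pd
import pytest

import epicarp as e


@pytest.fixture(scope="session")
def small_dataset():
    """A compact two-fruit, two-stage synthetic study used across modules."""
    params = e.SimulationParams(
        fruit_types=("cherry", "raspberry"),
        n_stages=2,
        n_replicates=3,
        n_phylotypes=60,
        depth_mean=3000,
        background_spike_prevalence=0.0,
        seed=42,
    )
    return e.simulate_dataset(params)


@pytest.fixture()
def toy_table():
    """A tiny hand-written count table (3 phylotypes x 4 samples)."""
    return pd.DataFrame(
        {
            "s1": [10, 0, 5],
            "s2": [0, 8, 2],
            "s3": [4, 4, 4],
            "s4": [1, 0, 0],
        },
        index=pd.Index(["p1", "p2", "p3"], name="phylotype_id"),
        dtype=np.int64,
    )


@pytest.fixture()
def paired_metadata():
    """Minimal valid metadata: 2 pairs (4 samples), one fruit, one stage."""
    rows = []
    for rep in (1, 2):
        for spiked, suffix in ((False, "N"), (True, "S")):
            rows.append(
                {
                    "sample_id": f"pair{rep}_{suffix}",
                    "pair_id": f"pair{rep}",
                    "fruit_type": "cherry",
                    "ripening_stage": 1,
                    "replicate": rep,
                    "spiked": spiked,
                    "site_x_km": 0.0,
                    "site_y_km": 0.0,
                    "mean_radius_mm": 10.0,
                    "fruits_per_sample": 10,
                }
            )
    return pd.DataFrame(rows).set_index("sample_id")
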