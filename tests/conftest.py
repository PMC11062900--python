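import numpy as np
import pandas as pd
import pytest

from ermeta import RunConfig, TruthConfig, simulate_database
from ermeta.effects import compute_effect_sizes


@pytest.fixture
def rng():
    return np.random.default_rng(20261001)


@pytest.fixture(scope="session")
def small_truth():
    """A small synthetic database shared by read-only tests."""
    cfg = TruthConfig(n_sites=6, n_experiments=12, n_datasets=30,
                      moderator_slopes={"TN": -0.3}, seed=42)
    flux, drivers, truth = simulate_database(cfg)
    return cfg, flux, drivers, truth


@pytest.fixture(scope="session")
def small_effects(small_truth):
    _, flux, _, _ = small_truth
    effects, _ = compute_effect_sizes(flux)
    return effects[effects["es_type"] == "SMD"].reset_index(drop=True)


@pytest.fixture
def toy_flux():
    """Six plot-day rows, two plots per treatment, one dataset."""
    rows = []
    for plot, trt, vals in [("p1", "control", [1.0, 3.0]),
                            ("p2", "control", [2.0, 2.0]),
                            ("p3", "warmed", [2.5, 3.5]),
                            ("p4", "warmed", [3.0, 3.0])]:
        for i, v in enumerate(vals):
            rows.append({"site_id": "S0", "experiment_id": "E0",
                         "plot_id": plot, "treatment": trt,
                         "date": f"2015-07-{10+i:02d}", "er_value": v,
                         "er_unit": "gCO2 m-2 d-1"})
    df = pd.DataFrame(rows)
    df["date"] = pd.to_datetime(df["date"])
    df["year"] = 2015
    return df


@pytest.fixture
def default_config():
    return RunConfig()
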