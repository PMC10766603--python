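import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("default")

import trawlkit as tk


@pytest.fixture(scope="session")
def backbone():
    return tk.default_backbone()


@pytest.fixture(scope="session")
def small_survey():
    """A small deterministic synthetic survey with its ground truth."""
    cfg = tk.SimConfig(seed=7, n_years=10, core_cells=4, transient_cells=2)
    return tk.generate_survey(cfg)


@pytest.fixture()
def raw_long_frame():
    """Hand-built long-format table: 2 hauls, 3 catch rows."""
    return pd.DataFrame(
        {
            "haul_id": ["H1", "H1", "H2"],
            "survey": ["SYN"] * 3,
            "survey_unit": ["SYN-1"] * 3,
            "latitude": [54.0, 54.0, 54.2],
            "longitude": [6.0, 6.0, 6.1],
            "year": [2000, 2000, 2001],
            "month": [6, 6, 6],
            "day": [1, 1, 2],
            "gear": ["OTB"] * 3,
            "gear_category": ["otter"] * 3,
            "quality_flag": ["valid"] * 3,
            "haul_dur": [30.0, 30.0, 45.0],
            "area_swept": [0.05, 0.05, 0.08],
            "verbatim_name": ["Gadus morhua", "Clupea harengus", "Gadus morhua"],
            "num": [10.0, 5.0, 2.0],
            "wgt": [12.0, 0.5, 2.5],
        }
    )


def make_dataset(frame: pd.DataFrame) -> tk.SurveyDataset:
    return tk.dataset_from_frame(frame)


def make_hauls(**overrides) -> dict:
    """One complete haul record as a plain mapping, fields overridable."""
    base = {
        "haul_id": "H1",
        "survey": "SYN",
        "survey_unit": "SYN-1",
        "latitude": 54.0,
        "longitude": 6.0,
        "year": 2000,
        "month": 6,
        "day": 1,
        "gear": "OTB",
        "gear_category": "otter",
        "quality_flag": "valid",
        "haul_dur": 30.0,
        "area_swept": 0.05,
        "depth": 80.0,
    }
    base.update(overrides)
    return base


@pytest.fixture()
def complete_haul():
    return make_hauls()
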