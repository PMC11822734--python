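import numpy as np
import pandas as pd
import pytest

from metabodrift.drift import ModelSpec, ModelStore, fit_all
from metabodrift.simulate import (
    SyntheticParameter,
    SyntheticTimecourseConfig,
    simulate_timecourse,
)


@pytest.fixture(scope="session")
def small_params():
    """Two parameters with fast and slow drift, for quick fits."""
    return (
        SyntheticParameter(
            name="fast",
            c0=2.0,
            baseline_cv=0.15,
            noise_cv=0.02,
            slopes={
                ("EDTA", "pre"): 0.5,
                ("EDTA", "post"): 0.25,
                ("Serum", "pre"): 0.4,
                ("Serum", "post"): 0.1,
            },
        ),
        SyntheticParameter(
            name="slow",
            c0=1.0,
            baseline_cv=0.10,
            noise_cv=0.02,
            slopes={
                ("EDTA", "pre"): -0.01,
                ("EDTA", "post"): -0.005,
                ("Serum", "pre"): -0.008,
                ("Serum", "post"): -0.004,
            },
        ),
    )


@pytest.fixture(scope="session")
def small_config(small_params):
    return SyntheticTimecourseConfig(
        n_donors=10,
        parameters=small_params,
        materials=("EDTA", "Serum"),
        seed=42,
    )


@pytest.fixture(scope="session")
def small_timecourse(small_config):
    data, truth = simulate_timecourse(small_config)
    return data, truth


@pytest.fixture(scope="session")
def small_store(small_timecourse):
    data, _ = small_timecourse
    store, skipped = fit_all(data, ModelSpec())
    assert len(skipped) == 0
    return store


def make_line_data(
    intercepts, slope, times=(0.0, 1.0, 2.0, 3.0), parameter="p", material="EDTA", phase="pre"
):
    """Noise-free per-donor lines: value = intercept_i + slope * t."""
    rows = []
    for i, b in enumerate(intercepts):
        for t in times:
            rows.append(
                {
                    "donor_id": f"d{i}",
                    "material": material,
                    "phase": phase,
                    "time_h": t,
                    "parameter": parameter,
                    "value": b + slope * t,
                }
            )
    return pd.DataFrame(rows)
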