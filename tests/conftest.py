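"""Shared fixtures: synthetic studies at several scales.

The expensive 48-nest studies are session scoped and shared between the
acceptance tests and the module tests that need realistic data.
"""

import numpy as np
import pandas as pd
import pytest

from nestrhythm import (GeneratorConfig, apply_exclusions, extract_study,
                        generate_study, prepare_covariates)


@pytest.fixture(scope="session")
def default_config():
    return GeneratorConfig(seed=1)


@pytest.fixture(scope="session")
def default_study(default_config):
    """The default 48-nest pattern-mode study."""
    return generate_study(default_config)


@pytest.fixture(scope="session")
def default_extraction(default_study):
    """(bouts-with-exclusions, gaps) extracted from the default study."""
    bouts, gaps = extract_study(default_study)
    bouts = apply_exclusions(bouts, default_study.metadata)
    return bouts, gaps


@pytest.fixture(scope="session")
def model_study():
    """A 48-nest model-mode study for coefficient recovery."""
    return generate_study(GeneratorConfig(seed=2, mode="model"))


@pytest.fixture(scope="session")
def model_extraction(model_study):
    bouts, gaps = extract_study(model_study)
    bouts = apply_exclusions(bouts, model_study.metadata)
    return bouts, gaps


@pytest.fixture(scope="session")
def model_covariates(model_study, model_extraction):
    bouts, _ = model_extraction
    cov = prepare_covariates(bouts, model_study.metadata)
    return cov.dropna(subset=["prev_c"])


@pytest.fixture(scope="session")
def small_study():
    """A cheap 6-nest study for unit-level checks."""
    return generate_study(GeneratorConfig(seed=5, n_nests=6))


def make_ideal_bouts(n_days=8, female_first=True, bout_h=12.0,
                     nest_id="TN1", t0=0.0):
    """Hand-built perfectly alternating bout table (no gaps, no breaks)."""
    rows = []
    t = t0
    sex = "F" if female_first else "M"
    for k in range(int(n_days * 24 / bout_h)):
        rows.append({
            "nest_id": nest_id, "sex": sex, "tag": f"{nest_id}{sex}",
            "start": t, "end": t + bout_h * 3600,
            "length_min": bout_h * 60, "constancy": 1.0,
            "median_z_temp": 0.0, "day_of_incubation": t / 86400 + 0.25,
            "gap_s": 0.0, "disturbance": 0, "n_reads": 100,
            "previous_bout_length": bout_h * 60 if k else np.nan,
            "bout_order": k,
        })
        t += bout_h * 3600
        sex = "M" if sex == "F" else "F"
    return pd.DataFrame(rows)
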