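import numpy as np
import pytest
from hypothesis import settings

import gliomorph as gm
from gliomorph.pipeline import measure_cohort

settings.register_profile("ci", derandomize=True, max_examples=25,
                          deadline=None)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def cal_unit():
    """1 µm/px calibration (pixel counts are areas in µm²)."""
    return gm.CalibrationSpec(1.0)


def tiny_config(seed: int = 3) -> gm.CohortConfig:
    """A reduced three-group cohort: 2 samples/group, 120x100 µm fields."""
    cfg = gm.default_cohort_config(seed=seed)
    for g in cfg.group_specs:
        g.n_samples = 2
    cfg.field_width_um = 120.0
    cfg.field_height_um = 100.0
    return cfg


@pytest.fixture(scope="session")
def tiny_cohort():
    return gm.generate_cohort(tiny_config())


@pytest.fixture(scope="session")
def tiny_measured(tiny_cohort):
    """(nucleus frame, field frame, sample records) of the tiny cohort."""
    return measure_cohort(tiny_cohort, n_nuclei=20)
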