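import numpy as np
import pytest

import vidphen as v


@pytest.fixture(scope="session")
def schema():
    return v.load_schema()


@pytest.fixture(scope="session")
def severity(schema):
    return v.LatentSeverityModel.default(schema, severity_shift=1.0)


@pytest.fixture(scope="session")
def sheets_small(schema, severity):
    """A 450-child score-sheet cohort (300 affected, 150 unaffected)."""
    cfg = v.CohortConfig(n_affected=300, n_unaffected=150, seed=11)
    return v.generate_training_sheets(cfg, severity, schema)


@pytest.fixture(scope="session")
def lr5_small(schema, sheets_small):
    spec = v.registry_specs(seed=0)["LR5"]
    return v.train_model(sheets_small, spec, schema.model_subsets["LR5"])


@pytest.fixture(scope="session")
def adtree8_small(schema, sheets_small):
    spec = v.registry_specs(seed=0)["ADTree8"]
    return v.train_model(sheets_small, spec, schema.model_subsets["ADTree8"])


@pytest.fixture(scope="session")
def cohort9(schema, severity):
    """A 50-video cohort tagged by a full pool of 9 noisy raters."""
    cfg = v.CohortConfig(n_affected=25, n_unaffected=25, seed=21)
    noise = v.RaterNoiseModel(error_rate=0.2, missing_rate=0.0)
    return v.generate_video_cohort(cfg, severity, noise, 9, schema)
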