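import numpy as np
import pandas as pd
import pytest

from osteomap.cohort import CohortTable, default_schema
from osteomap.pipeline import PipelineConfig, run_pipeline
from osteomap.simulate import GeneratorConfig, sample_cohort


@pytest.fixture(scope="session")
def schema():
    return default_schema()


@pytest.fixture(scope="session")
def small_table(schema):
    """Hand-built 5-record table with in-range values."""
    rng = np.random.default_rng(123)
    data = {"patient_id": [f"P{i}" for i in range(5)]}
    for v in schema.continuous:
        lo, hi = v.min_allowed, v.max_allowed
        data[v.name] = np.round(lo + rng.random(5) * (hi - lo), 4)
    data["SDI"] = np.array([0, 1, 6, 0, 3], dtype=float)
    data["Romberg"] = [0, 1, 1, 0, 0]
    data["Fracture"] = [0, 1, 1, 0, 1]
    return CohortTable(schema, pd.DataFrame(data))


@pytest.fixture(scope="session")
def cohort_125():
    """Default synthetic cohort at the study's sample size."""
    return sample_cohort(GeneratorConfig(n_records=125, seed=0))


@pytest.fixture(scope="session")
def pipeline_run(tmp_path_factory):
    """One fixed-seed default pipeline run shared across tests."""
    outdir = tmp_path_factory.mktemp("run") / "out"
    cfg = PipelineConfig(outdir=str(outdir), seed=0, verbosity="quiet")
    report = run_pipeline(cfg)
    return cfg, report
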