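import numpy as np
import pytest

from lcrsv.pipeline import PipelineConfig, run_pipeline
from lcrsv.simulate import ClassError, SimConfig


@pytest.fixture
def genome():
    return {"chr1": 10_000, "chr2": 8_000}


@pytest.fixture(scope="session")
def small_sim_config():
    """A compact study configuration used by the end-to-end fixtures."""
    return SimConfig(
        seed=7,
        n_chroms=2,
        chrom_len=300_000,
        lcr_count=90,
        segdup_count=2,
        segdup_len=6_000,
        truth_sv_counts={
            "LCR": {"INS": 50, "DEL": 30},
            "SegDup": {"INS": 5, "DEL": 5},
            "Other": {"INS": 20, "DEL": 10},
        },
    )


@pytest.fixture(scope="session")
def pipeline_result(small_sim_config):
    return run_pipeline(PipelineConfig(sim=small_sim_config))


@pytest.fixture(scope="session")
def zero_error_result(small_sim_config):
    import dataclasses

    zero = {c: ClassError(fdr=0.0, fnr=0.0, jitter_sd=0.0, length_sd=0.0)
            for c in ("LCR", "SegDup", "Other")}
    cfg = dataclasses.replace(small_sim_config, error_model=zero)
    return run_pipeline(PipelineConfig(sim=cfg))
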