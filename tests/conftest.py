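import pytest

from phagetx import PipelineConfig, default_dataset, run_pipeline

DATASET_SEED = 7


@pytest.fixture(scope="session")
def dataset():
    """Default synthetic study: genome, genes, planted truth, both libraries."""
    return default_dataset(seed=DATASET_SEED)


@pytest.fixture(scope="session")
def pipeline_result(tmp_path_factory):
    cfg = PipelineConfig(
        outdir=str(tmp_path_factory.mktemp("pipeline")),
        seed=DATASET_SEED,
        motif_shuffles=0,
    )
    return run_pipeline(cfg)
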