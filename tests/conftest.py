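import pytest

from stemloop.pipeline import PipelineConfig, run_pipeline
from stemloop.synthetic import synthetic_dataset


@pytest.fixture(scope="session")
def dataset():
    """One complete synthetic two-library study with ground truth."""
    return synthetic_dataset(seed=1)


@pytest.fixture(scope="session")
def transcripts(dataset):
    return {r.id: str(r.seq) for r in dataset.transcripts}


@pytest.fixture(scope="session")
def pipeline_result(dataset, transcripts):
    """The full pipeline run once over the session dataset."""
    cfg = PipelineConfig(adapter=dataset.adapter)
    return run_pipeline(
        cfg,
        libraries=dataset.libraries,
        transcripts=transcripts,
        mature_db=dataset.mature_db,
        ncrna_set=dataset.ncrna_set,
        degradome_reads=dataset.degradome,
    )
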