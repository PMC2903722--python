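import pytest

from rbmed import PipelineConfig, generate_corpus, run_pipeline


@pytest.fixture(scope="session")
def corpus_dir(tmp_path_factory):
    """The default fixture corpus (decoys included, no noise seed)."""
    d = tmp_path_factory.mktemp("corpus")
    generate_corpus(d)
    return d


@pytest.fixture(scope="session")
def pipeline(corpus_dir):
    """One full pipeline run over the default corpus, shared by read-only tests."""
    cfg = PipelineConfig.load(corpus_dir / "pipeline.yaml")
    return run_pipeline(cfg)
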