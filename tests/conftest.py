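import pathlib
import tempfile

import pytest

from occc_molpro.knowledge import KnowledgeBase
from occc_molpro.pipeline import PipelineConfig, run_pipeline
from occc_molpro.synthetic import CohortSpec, generate_cohort, write_bundle


@pytest.fixture(scope="session")
def default_bundle():
    """The default synthetic cohort replica (seed 42), generated once."""
    return generate_cohort(CohortSpec(), seed=42)


@pytest.fixture(scope="session")
def bundle_dir(default_bundle, tmp_path_factory):
    d = tmp_path_factory.mktemp("cohort") / "in"
    write_bundle(default_bundle, d)
    return d


@pytest.fixture(scope="session")
def pipeline_result(default_bundle, bundle_dir, tmp_path_factory):
    out = tmp_path_factory.mktemp("report")
    return run_pipeline(PipelineConfig(input_dir=bundle_dir, output_dir=out))


@pytest.fixture()
def kb():
    return KnowledgeBase()
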