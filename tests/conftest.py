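import pytest

from rsrna.config import PipelineConfig
from rsrna.pipeline import PipelineInputs, run_pipeline
from rsrna.simulate import GeneratorConfig, generate_bundle


@pytest.fixture(scope="session")
def bundle_noiseless():
    """Synthetic bundle with deterministic (noiseless) counts, seed 1."""
    return generate_bundle(GeneratorConfig(rng_seed=1, nb_dispersion=None))


@pytest.fixture(scope="session")
def bundle_nb():
    """Synthetic bundle with negative-binomial counts at defaults, seed 1."""
    return generate_bundle(GeneratorConfig(rng_seed=1))


@pytest.fixture(scope="session")
def result_noiseless(bundle_noiseless):
    return run_pipeline(PipelineConfig(), PipelineInputs.from_bundle(bundle_noiseless))


@pytest.fixture(scope="session")
def result_nb(bundle_nb):
    return run_pipeline(PipelineConfig(), PipelineInputs.from_bundle(bundle_nb))


@pytest.fixture(scope="session")
def records_by_seq_noiseless(result_noiseless):
    return {r.sequence: r for r in result_noiseless.records}


@pytest.fixture(scope="session")
def records_by_seq_nb(result_nb):
    return {r.sequence: r for r in result_nb.records}
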