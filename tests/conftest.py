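import pytest

from srnacompare.pipeline import run_experiment
from srnacompare.simulate import SyntheticSpec, generate_experiment


@pytest.fixture(scope="session")
def small_spec():
    return SyntheticSpec(total_reads=20_000)


@pytest.fixture(scope="session")
def experiment(small_spec):
    return generate_experiment(small_spec, seed=7)


@pytest.fixture(scope="session")
def pipeline_result(experiment):
    return run_experiment(experiment)
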