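import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))

from tissamp16s import mocksim, pipeline


@pytest.fixture(scope="session")
def small_mock():
    """6-strain mock (one primer dropout), taxonomy and reference."""
    spec, tax = mocksim.synth_reference_set(6, seed=1, primer_dropout=[5])
    ref = mocksim.reference_alignment(spec)
    return spec, tax, ref


@pytest.fixture(scope="session")
def small_run(small_mock):
    spec, tax, ref = small_mock
    cfg = mocksim.SeqRunConfig(kit="v2", depth=3000, seed=2, index_seq="AAAAAA")
    return mocksim.simulate_run(spec, cfg)


@pytest.fixture(scope="session")
def small_pipeline_result(small_mock, small_run):
    spec, tax, ref = small_mock
    return pipeline.run_pipeline(
        small_run.pairs, ref, tax, pipeline.RunConfig(kit="v2", seed=3)
    )
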