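import numpy as np
import pytest

from mrsd import (
    GeneratorConfig,
    ReferenceSet,
    generate_annotation_fixture,
    generate_reference_set,
)


@pytest.fixture(scope="session")
def small_synth():
    """A small synthetic cohort shared across unit tests."""
    return generate_reference_set(
        GeneratorConfig(n_samples=40, n_genes=15, seed=7)
    )


@pytest.fixture(scope="session")
def annotation_fixture(tmp_path_factory):
    return generate_annotation_fixture(tmp_path_factory.mktemp("annot"))


@pytest.fixture()
def case_and_controls(small_synth):
    """First cohort sample as a case, the rest as controls."""
    ref = small_synth.reference_set
    case = ref.sample_counts(ref.samples[0].sample_id)
    controls = ReferenceSet(
        list(ref.samples[1:]), list(ref.junctions), ref.counts[1:], "controls"
    )
    return case, controls
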