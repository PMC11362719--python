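import dataclasses

import pytest

from abxddd.cost import MRP, add_costs
from abxddd.datasets import load_bundled_registry
from abxddd.ddd import annotate
from abxddd.synthetic import generate, study_profile


@pytest.fixture(scope="session")
def registry():
    return load_bundled_registry()


@pytest.fixture(scope="session")
def small_dataset(registry):
    """Default-sized draw (~1.1k records) of the study-like profile."""
    return generate(study_profile(seed=7), registry)


@pytest.fixture(scope="session")
def dataset_10k(registry):
    """A >=10,000-record draw of the study-like profile."""
    cfg = dataclasses.replace(study_profile(seed=11), products_per_molecule=27)
    ds = generate(cfg, registry)
    assert ds.n_records >= 10_000
    return ds


@pytest.fixture(scope="session")
def annotated_10k(dataset_10k, registry):
    return annotate(dataset_10k.all_records(), registry)


@pytest.fixture(scope="session")
def costed_10k(annotated_10k):
    frame, _ = annotated_10k
    return add_costs(frame, MRP)
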