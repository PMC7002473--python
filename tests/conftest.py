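import numpy as np
import pytest

from prrkit.seqio import Label
from prrkit.synthetic import SyntheticConfig, generate_families


@pytest.fixture(scope="session")
def default_dataset():
    """The generator's default study conditions: 20 families x 5 per class."""
    cfg = SyntheticConfig()
    records, family_of = generate_families(cfg)
    return cfg, records, family_of


@pytest.fixture(scope="session")
def default_labels(default_dataset):
    _, records, _ = default_dataset
    return np.array([1 if r.label is Label.POSITIVE else 0 for r in records])


def labels_of(records):
    return np.array([1 if r.label is Label.POSITIVE else 0 for r in records])
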