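import pytest
from hypothesis import settings

from seroinkit import synth

settings.register_profile("fixed", derandomize=True, deadline=None)
settings.load_profile("fixed")


@pytest.fixture(scope="session")
def balanced_dataset():
    """Seed-42 balanced synthetic dataset (10 per class) with truth table."""
    records, truth = synth.make_dataset(synth.balanced_counts(10), seed=42)
    return records, truth


@pytest.fixture(scope="session")
def acceptance_dataset():
    """The full 300-record (100 per class) seed-42 dataset."""
    records, truth = synth.make_dataset(synth.balanced_counts(100), seed=42)
    return records, truth
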