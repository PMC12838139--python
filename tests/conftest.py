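import pytest

from specprime.compstats import records_to_trivial_alignment
from specprime.fixtures import SyntheticFamilySpec, generate_family
from specprime.profile import alignment_from_rows, site_profile


@pytest.fixture(scope="session")
def family():
    """Default synthetic four-species family (seed 1) plus planted truth."""
    records, truth = generate_family(SyntheticFamilySpec(seed=1))
    return records, truth


@pytest.fixture(scope="session")
def family_alignment(family):
    records, _ = family
    return records_to_trivial_alignment(records)


@pytest.fixture(scope="session")
def family_profile(family_alignment):
    return site_profile(family_alignment)


@pytest.fixture
def toy_alignment():
    """4x12 alignment with a single diagnostic column (6) for species T."""
    rows = [
        ("t1", "T", "ACGTAAACGTAC"),
        ("o1", "U", "ACGTAGACGTAC"),
        ("o2", "V", "ACGTAGACGTAC"),
        ("o3", "W", "ACGTAGACGTAC"),
    ]
    return alignment_from_rows(rows)
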