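import pytest

from gstassoc import generate_fixture, genotype_counts


@pytest.fixture(scope="session")
def study_records():
    """The joint 208-subject fixture reproducing the published
    demographic, genotype, gene-gene and gene-smoking margins."""
    return generate_fixture("paper-all")


@pytest.fixture(scope="session")
def gstp1_counts(study_records):
    return genotype_counts(study_records, "gstp1")
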