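import pytest

from seqentropy import (
    Alphabet,
    EntropySpec,
    SequenceRecord,
    extract_table,
    make_benchmark,
)


@pytest.fixture(scope="session")
def separable_records():
    records, _ = make_benchmark("separable_pair", n_per_class=50, seed=11)
    return records


@pytest.fixture(scope="session")
def separable_table(separable_records):
    return extract_table(separable_records, EntropySpec(family="tsallis", q=2.0, k_max=10))


@pytest.fixture(scope="session")
def multiclass_records():
    records, _ = make_benchmark("multiclass3", n_per_class=30, seed=5)
    return records


@pytest.fixture
def dna_record():
    return SequenceRecord(id="s", residues="ACGTACGT", alphabet=Alphabet.DNA)
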