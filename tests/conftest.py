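import numpy as np
import pytest

from bittersel.io import HaplotypeAlignment, PopulationMap, SequenceRecord


@pytest.fixture
def tiny_alignment() -> HaplotypeAlignment:
    """Four chromosomes, two populations, one private and one shared haplotype."""
    return HaplotypeAlignment(
        [
            SequenceRecord("a1", "AAA"),
            SequenceRecord("a2", "AAT"),
            SequenceRecord("b1", "TAA"),
            SequenceRecord("b2", "TAT"),
        ]
    )


@pytest.fixture
def tiny_map() -> PopulationMap:
    return PopulationMap([("a1", "p1"), ("a2", "p1"), ("b1", "p2"), ("b2", "p2")])


@pytest.fixture
def kii_like_alignment() -> tuple[HaplotypeAlignment, PopulationMap]:
    """80 chromosomes with the observed coding-allele counts of the focal
    population (32+17+1+6+23+1) plus a second population sharing every
    haplotype except the 23-copy one, which stays population-private."""
    haps = {
        "A": ("AAAA", 32),
        "B": ("AAAT", 17),
        "F": ("AATA", 1),
        "J": ("ATAA", 6),
        "K": ("TAAA", 23),  # private to the focal population
        "Q": ("ATAT", 1),
    }
    records = []
    assignments = []
    i = 0
    for name, (seq, count) in haps.items():
        for _ in range(count):
            i += 1
            rid = f"kii_{name}_{i:03d}"
            records.append(SequenceRecord(rid, seq))
            assignments.append((rid, "focal"))
    for name, seq in [("A", "AAAA"), ("B", "AAAT"), ("F", "AATA"), ("J", "ATAA"), ("Q", "ATAT")]:
        rid = f"nbr_{name}"
        records.append(SequenceRecord(rid, seq))
        assignments.append((rid, "neighbor"))
    return HaplotypeAlignment(records), PopulationMap(assignments)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(2024)
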