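import dataclasses
import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))

from pathcover import (
    CPDB_LIKE,
    EnrichedPathwaySet,
    GeneSetCollection,
    Pathway,
    generate_collection,
)


def make_collection(*sets: tuple[str, list[str]], source: str = "unknown"):
    return GeneSetCollection(
        [Pathway(id=i, source=source, genes=frozenset(g)) for i, g in sets]
    )


@pytest.fixture
def tiny_collection():
    """The worked four-pathway instance traced by hand in the cover tests."""
    return make_collection(
        ("S1", ["1", "2", "3", "4"]),
        ("S2", ["3", "4", "5"]),
        ("S3", ["5", "6"]),
        ("S4", ["6", "7"]),
    )


@pytest.fixture
def disjoint_collection():
    return make_collection(
        ("D1", ["a", "b"]), ("D2", ["c", "d"]), ("D3", ["e", "f", "g"])
    )


@pytest.fixture
def nested_enrichment():
    """Three enriched pathways where B's DE genes are a subset of A's."""
    a = Pathway("A", "unknown", frozenset({"g1", "g2", "g3"}))
    b = Pathway("B", "unknown", frozenset({"g2", "g3"}))
    c = Pathway("C", "unknown", frozenset({"g3", "g4"}))
    return EnrichedPathwaySet(
        entries=[(a, 0.001), (b, 0.002), (c, 0.003)],
        de_universe=frozenset({"g1", "g2", "g3", "g4"}),
    )


@pytest.fixture(scope="session")
def benchmark_collection():
    """The default cpdb_like synthetic benchmark instance."""
    return generate_collection(CPDB_LIKE)


@pytest.fixture(scope="session")
def benchmark_grid():
    """Ten seeded benchmark instances for behavioral-signature checks."""
    return [
        generate_collection(dataclasses.replace(CPDB_LIKE, seed=s))
        for s in range(10)
    ]
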