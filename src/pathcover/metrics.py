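"""Redundancy and size-structure metrics for pathway collections.

The central quantity is the **overlap score**: the mean number of pathways
each gene belongs to, computed as ``Σ_i |s_i| / |∪_i s_i|``.  A pairwise
disjoint collection scores exactly 1, so 1 is the floor of removable
redundancy; the **reduction percentage** normalises against that floor,

    reduction % = 100 · (original − new) / (original − 1),

i.e. the fraction of removable redundancy actually removed.  When a cover
run stops short of full gene coverage, the score of the resulting
sub-collection is taken over the genes it covers (a gene belonging to zero
selected pathways would otherwise drag the mean below the disjoint floor).

Also here: Jaccard pair statistics, pathway-size summaries and per-source
composition, bundled into a serialisable :class:`MetricsReport`.
"""

from __future__ import annotations

import itertools
import json
from collections import Counter
from dataclasses import dataclass, field
from typing import NamedTuple, Optional, Set

import numpy as np

from .io import GeneSetCollection

__all__ = [
    "overlap_score",
    "reduction_percent",
    "jaccard",
    "jaccard_distribution",
    "JaccardDistribution",
    "size_stats",
    "SizeStats",
    "source_composition",
    "MetricsReport",
    "summarize",
]


def overlap_score(collection: GeneSetCollection) -> float:
    """Mean pathway membership per gene, Σ|s_i| / |universe|.

    Counts only genes present in at least one pathway of ``collection``, so
    a cover-set sub-collection is scored over the genes it covers.
    """
    if len(collection) == 0:
        raise ValueError("overlap score undefined for an empty collection")
    return sum(p.size for p in collection) / len(collection.universe)


def reduction_percent(original_score: float, new_score: float) -> float:
    """Percentage of removable redundancy removed, unrounded.

    Normalised by ``original − 1`` because an entirely discrete collection
    scores 1, not 0; e.g. (12.4, 4.1) → 72.8, conventionally reported as 73.
    """
    if original_score <= 1:
        raise ValueError("reduction undefined: original score must exceed 1")
    if new_score < 1:
        raise ValueError("new score cannot fall below the disjoint floor of 1")
    return 100.0 * (original_score - new_score) / (original_score - 1.0)


def jaccard(a: Set[str], b: Set[str]) -> float:
    """|a ∩ b| / |a ∪ b|."""
    if not a and not b:
        raise ValueError("Jaccard undefined for two empty sets")
    return len(a & b) / len(a | b)


class JaccardDistribution(NamedTuple):
    """Histogram of all unordered pathway-pair Jaccard similarities.

    ``counts`` histograms the pairs over ``edges`` (right-closed bins on
    [0, 1]); fully disjoint pairs are additionally reported separately in
    ``zero_pairs`` since they dominate sparse collections.
    """

    counts: np.ndarray
    edges: np.ndarray
    max_value: float
    zero_pairs: int
    n_pairs: int


def jaccard_distribution(
    collection: GeneSetCollection, bins: int = 20
) -> JaccardDistribution:
    """Score every unordered pathway pair and bin the similarities."""
    if len(collection) < 2:
        raise ValueError("need at least two pathways for a pair distribution")
    values = np.fromiter(
        (
            jaccard(a.genes, b.genes)
            for a, b in itertools.combinations(collection.pathways, 2)
        ),
        dtype=float,
    )
    edges = np.linspace(0.0, 1.0, bins + 1)
    # right-closed bins (0, e1], (e1, e2], ...; exact zeros fall in bin 0
    idx = np.clip(np.searchsorted(edges, values, side="left") - 1, 0, bins - 1)
    counts = np.bincount(idx, minlength=bins)
    return JaccardDistribution(
        counts=counts,
        edges=edges,
        max_value=float(values.max()),
        zero_pairs=int((values == 0.0).sum()),
        n_pairs=len(values),
    )


class SizeStats(NamedTuple):
    mean: float
    sd: float
    max: int
    median: float


def size_stats(collection: GeneSetCollection) -> SizeStats:
    """Pathway-size summary; SD is the sample SD (n−1), 0 for one pathway."""
    sizes = np.array([p.size for p in collection])
    sd = float(sizes.std(ddof=1)) if len(sizes) > 1 else 0.0
    return SizeStats(
        mean=float(sizes.mean()),
        sd=sd,
        max=int(sizes.max()),
        median=float(np.median(sizes)),
    )


def source_composition(collection: GeneSetCollection) -> dict[str, float]:
    """Per-source pathway proportions; values sum to 1."""
    counts = Counter(p.source for p in collection)
    total = len(collection)
    return {src: n / total for src, n in sorted(counts.items())}


@dataclass
class MetricsReport:
    """Serialisable redundancy summary of a collection (or cover result)."""

    overlap_score: float
    n_pathways: int
    n_genes_covered: int
    size_mean: float
    size_sd: float
    size_max: int
    size_median: float
    jaccard_max: float
    jaccard_histogram: list[int]
    jaccard_bin_edges: list[float]
    source_composition: dict[str, float]
    provenance: dict = field(default_factory=dict)

    def to_json(self, indent: int = 2) -> str:
        return json.dumps(self.__dict__, indent=indent)


def summarize(
    collection: GeneSetCollection,
    bins: int = 20,
    provenance: Optional[dict] = None,
) -> MetricsReport:
    """Compute the full :class:`MetricsReport` for a collection."""
    stats = size_stats(collection)
    if len(collection) >= 2:
        jd = jaccard_distribution(collection, bins=bins)
        jmax, jcounts, jedges = jd.max_value, jd.counts, jd.edges
    else:
        jmax, jcounts, jedges = 0.0, np.zeros(bins, dtype=int), np.linspace(0, 1, bins + 1)
    return MetricsReport(
        overlap_score=overlap_score(collection),
        n_pathways=len(collection),
        n_genes_covered=len(collection.universe),
        size_mean=stats.mean,
        size_sd=stats.sd,
        size_max=stats.max,
        size_median=stats.median,
        jaccard_max=jmax,
        jaccard_histogram=[int(c) for c in jcounts],
        jaccard_bin_edges=[float(e) for e in jedges],
        source_composition=source_composition(collection),
        provenance=provenance or {},
    )
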