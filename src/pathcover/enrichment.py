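"""Redundancy reduction for pathway-enrichment results.

Enriched pathways arrive already scored (adjusted p-values), so the cover
value of a pathway is simply ``v_i = (1 − p_i) · b``, where the indicator
``b`` is 1 while the pathway still contains an uncovered differentially
expressed (DE) gene and 0 otherwise.  Taking the argmax repeatedly is
equivalent to a single walk down the p-value-sorted list that keeps a
pathway iff it contributes at least one DE gene not covered by a more
enriched retained pathway.  The walk preserves the enrichment order: the
output is the input ranking with redundant entries deleted, never a
re-ranking.

All set logic operates on the DE restriction ``s_i ∩ de_universe`` — genes
that are not differentially expressed play no role here.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np

from .io import EnrichedPathwaySet

__all__ = [
    "RetainedEntry",
    "RemovedEntry",
    "EnrichmentCoverResult",
    "OverlapMatrix",
    "enrichment_cover",
    "asymmetric_overlap_matrix",
    "coverage_fraction",
]


@dataclass(frozen=True)
class RetainedEntry:
    pathway_id: str
    p_value: float
    new_de_genes: int


@dataclass(frozen=True)
class RemovedEntry:
    pathway_id: str
    p_value: float
    #: Earliest retained pathway at which the cumulative retained union
    #: already covers this pathway's DE genes (reporting aid only).
    covered_by: Optional[str]


@dataclass(frozen=True)
class EnrichmentCoverResult:
    """Retained/removed split of an enrichment ranking.

    ``retained`` keeps the ascending p-value order; after a full walk the
    retained pathways jointly cover every DE gene (``de_covered``), because
    removed entries by definition contributed nothing new.
    """

    retained: tuple[RetainedEntry, ...]
    removed: tuple[RemovedEntry, ...]
    de_covered: frozenset[str]

    @property
    def retained_ids(self) -> list[str]:
        return [e.pathway_id for e in self.retained]

    def report_rows(self) -> list[dict]:
        """Rows for the retained/removed TSV, in enrichment order."""
        status = {e.pathway_id: ("retained", e) for e in self.retained}
        status.update({e.pathway_id: ("removed", e) for e in self.removed})
        rows = []
        ordered = sorted(
            status.items(), key=lambda kv: (kv[1][1].p_value, kv[0])
        )
        for rank, (pid, (kind, entry)) in enumerate(ordered, start=1):
            rows.append(
                {
                    "rank": rank,
                    "pathway_id": pid,
                    "p_adjusted": entry.p_value,
                    "status": kind,
                    "new_de_genes": getattr(entry, "new_de_genes", 0),
                    "covered_by": getattr(entry, "covered_by", "") or "",
                }
            )
        return rows


def enrichment_cover(enriched: EnrichedPathwaySet) -> EnrichmentCoverResult:
    """Select the most enriched pathways that cover all DE genes.

    Walks the entries in ascending ``(p_value, id)`` order; a pathway is
    retained iff its DE-restricted gene set still intersects the uncovered
    set R, i.e. its indicator b equals 1 when reached.  Ties in p-value are
    resolved by pathway id, and each tied pathway is judged in that order.

    Raises
    ------
    ValueError
        If the DE universe is empty (nothing to cover).
    """
    if not enriched.de_universe:
        raise ValueError("the DE universe is empty; nothing to cover")
    uncovered = set(enriched.de_universe)
    retained: list[RetainedEntry] = []
    retained_sets: list[tuple[str, frozenset[str]]] = []
    removed: list[RemovedEntry] = []
    for pathway, pv in enriched.entries:
        de_genes = pathway.genes & enriched.de_universe
        new = de_genes & uncovered
        if new:
            retained.append(RetainedEntry(pathway.id, pv, len(new)))
            retained_sets.append((pathway.id, frozenset(de_genes)))
            uncovered -= new
        else:
            removed.append(
                RemovedEntry(pathway.id, pv, _covering_witness(de_genes, retained_sets))
            )
    return EnrichmentCoverResult(
        retained=tuple(retained),
        removed=tuple(removed),
        de_covered=frozenset(enriched.de_universe - uncovered),
    )


def _covering_witness(
    de_genes: frozenset[str], retained_sets: Sequence[tuple[str, frozenset[str]]]
) -> Optional[str]:
    """Id of the earliest retained pathway completing cover of ``de_genes``."""
    remaining = set(de_genes)
    for pid, genes in retained_sets:
        remaining -= genes
        if not remaining:
            return pid
    return None


@dataclass(frozen=True)
class OverlapMatrix:
    """Asymmetric overlap between DE-restricted pathway gene sets.

    Entry (row A, column B) is the fraction of A's DE genes also found in
    B: ``|A ∩ B ∩ DE| / |A ∩ DE|``.  The diagonal is 1 and the matrix is
    generally not symmetric — a subset pathway overlaps its superset fully
    while the converse fraction is smaller.
    """

    ids: tuple[str, ...]
    values: np.ndarray

    def to_tsv(self) -> str:
        lines = ["\t".join(["", *self.ids])]
        for pid, row in zip(self.ids, self.values):
            lines.append("\t".join([pid, *(f"{v:.4f}" for v in row)]))
        return "\n".join(lines) + "\n"


def asymmetric_overlap_matrix(
    ids: Sequence[str], enriched: EnrichedPathwaySet
) -> OverlapMatrix:
    """Pairwise asymmetric overlap over the given pathways, DE-restricted.

    Raises
    ------
    ValueError
        If a pathway has no DE genes (its overlap row is undefined).
    KeyError
        If an id does not resolve among the enriched entries.
    """
    de_sets = []
    for pid in ids:
        s = enriched.pathway(pid).genes & enriched.de_universe
        if not s:
            raise ValueError(f"pathway {pid!r} shares no gene with the DE universe")
        de_sets.append(s)
    n = len(ids)
    values = np.zeros((n, n))
    for i, a in enumerate(de_sets):
        for j, b in enumerate(de_sets):
            values[i, j] = len(a & b) / len(a)
    return OverlapMatrix(ids=tuple(ids), values=values)


def coverage_fraction(
    enriched: EnrichedPathwaySet, ids: Sequence[str], top_n: int
) -> float:
    """Fraction of the DE universe covered by the first ``top_n`` pathways.

    ``top_n`` beyond the list length is clamped; the denominator is always
    the full DE universe (DE genes mappable to at least one enriched
    pathway).
    """
    if top_n < 1:
        raise ValueError("top_n must be >= 1")
    union: set[str] = set()
    for pid in list(ids)[: min(top_n, len(ids))]:
        union |= enriched.pathway(pid).genes
    return len(union & enriched.de_universe) / len(enriched.de_universe)


def coverage_trace(
    enriched: EnrichedPathwaySet,
    before_ids: Sequence[str],
    after_ids: Sequence[str],
) -> list[dict]:
    """Per-n coverage of the original vs the reduced ranking (TSV rows)."""
    n_max = max(len(before_ids), len(after_ids))
    rows = []
    for n in range(1, n_max + 1):
        rows.append(
            {
                "n": n,
                "coverage_before": coverage_fraction(enriched, before_ids, n),
                "coverage_after": coverage_fraction(enriched, after_ids, n),
            }
        )
    return rows
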