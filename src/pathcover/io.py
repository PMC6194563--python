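"""Reading and writing gene-set collections and enrichment tables.

The on-disk formats are deliberately plain:

* **GMT** (Broad/MSigDB convention) — one gene set per line, tab separated:
  ``identifier<TAB>description<TAB>gene1<TAB>gene2...``.  Aggregated pathway
  resources such as ConsensusPathDB are distributed this way; the description
  field usually carries the source database, which we recover when it matches
  a known vocabulary.
* **Enrichment table** — TSV with a header containing at least ``pathway_id``
  and ``p_adjusted`` columns (p-values are assumed already corrected for
  multiple testing; this package never computes or corrects them).
* **Gene list** — one symbol per line.

All parsers return the validated in-memory types (:class:`Pathway`,
:class:`GeneSetCollection`, :class:`EnrichedPathwaySet`) that the cover
engine, enrichment cover and metrics modules operate on.
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Iterable, Iterator, Union

import pandas as pd

__all__ = [
    "Pathway",
    "GeneSetCollection",
    "EnrichedPathwaySet",
    "DEFAULT_SOURCE_VOCABULARY",
    "read_gmt",
    "write_gmt",
    "read_gene_list",
    "write_gene_list",
    "read_enrichment_table",
    "write_enrichment_table",
]

#: Source databases recognised in the GMT description field.  These are the
#: databases that contribute pathways to ConsensusPathDB-style aggregates.
DEFAULT_SOURCE_VOCABULARY: frozenset[str] = frozenset(
    {
        "BioCarta",
        "EHMN",
        "HumanCyc",
        "INOH",
        "KEGG",
        "NetPath",
        "PharmGKB",
        "PID",
        "Reactome",
        "Signalink",
        "SMPDB",
        "Wikipathways",
    }
)

TextSource = Union[str, Path, IO[str]]


@dataclass(frozen=True)
class Pathway:
    """A named gene set.

    Pathways are treated purely as sets of gene symbols; topology plays no
    role in any algorithm here.

    Parameters
    ----------
    id
        Unique, non-empty identifier within a collection.
    source
        Label of the database of origin (e.g. ``"KEGG"``); ``"unknown"``
        when the origin cannot be determined.
    genes
        Non-empty, duplicate-free set of gene symbols.
    """

    id: str
    source: str
    genes: frozenset[str]

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("pathway id must be non-empty")
        if not isinstance(self.genes, frozenset):
            object.__setattr__(self, "genes", frozenset(self.genes))
        if not self.genes:
            raise ValueError(f"pathway {self.id!r} has an empty gene set")

    @property
    def size(self) -> int:
        """Number of genes, |s_i|."""
        return len(self.genes)


@dataclass
class GeneSetCollection:
    """An ordered collection of pathways together with its gene universe.

    The *universe* U is exactly the union of all member gene sets.  Pathway
    identifiers are unique; lookup by id is O(1).

    ``metadata`` carries optional provenance (for instance the latent gene
    modules recorded by the synthetic generator); it never affects equality
    of the biological content and is not serialised to GMT.
    """

    pathways: list[Pathway]
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.pathways:
            raise ValueError("a collection must contain at least one pathway")
        self._by_id: dict[str, Pathway] = {}
        for p in self.pathways:
            if p.id in self._by_id:
                raise ValueError(f"duplicate pathway id {p.id!r}")
            self._by_id[p.id] = p
        self.universe: frozenset[str] = frozenset().union(
            *(p.genes for p in self.pathways)
        )

    def __len__(self) -> int:
        return len(self.pathways)

    def __iter__(self) -> Iterator[Pathway]:
        return iter(self.pathways)

    def __contains__(self, pathway_id: str) -> bool:
        return pathway_id in self._by_id

    def __getitem__(self, pathway_id: str) -> Pathway:
        return self._by_id[pathway_id]

    @property
    def ids(self) -> list[str]:
        return [p.id for p in self.pathways]

    @property
    def mean_size(self) -> float:
        """Mean pathway size over the whole collection."""
        return sum(p.size for p in self.pathways) / len(self.pathways)

    def subset(self, ids: Iterable[str]) -> "GeneSetCollection":
        """New collection containing ``ids`` in the given order."""
        return GeneSetCollection([self[i] for i in ids])


@dataclass
class EnrichedPathwaySet:
    """Enrichment-analysis output ready for redundancy reduction.

    ``entries`` pairs each enriched pathway with its adjusted p-value and is
    sorted ascending by ``(p_value, pathway.id)`` — the deterministic order
    in which the enrichment set cover considers pathways.  ``de_universe``
    holds the differentially expressed (DE) genes that map to at least one
    entry; it is the universe all enrichment-cover logic works over.
    """

    entries: list[tuple[Pathway, float]]
    de_universe: frozenset[str]

    def __post_init__(self) -> None:
        for p, pv in self.entries:
            if not (0.0 <= pv <= 1.0):
                raise ValueError(
                    f"p-value {pv!r} for pathway {p.id!r} outside [0, 1]"
                )
        self.entries = sorted(self.entries, key=lambda e: (e[1], e[0].id))
        self.de_universe = frozenset(self.de_universe)

    def __len__(self) -> int:
        return len(self.entries)

    @property
    def ids(self) -> list[str]:
        return [p.id for p, _ in self.entries]

    def pathway(self, pathway_id: str) -> Pathway:
        for p, _ in self.entries:
            if p.id == pathway_id:
                return p
        raise KeyError(pathway_id)


def _open_text(source: TextSource, mode: str = "r"):
    """Return (stream, needs_close) for a path or an already open stream."""
    if isinstance(source, (str, Path)):
        return open(source, mode, encoding="utf-8"), True
    return source, False


def read_gmt(
    source: TextSource,
    *,
    source_vocabulary: frozenset[str] = DEFAULT_SOURCE_VOCABULARY,
    uppercase: bool = False,
) -> GeneSetCollection:
    """Parse a GMT file or stream into a :class:`GeneSetCollection`.

    The description field (column 2) becomes the pathway's ``source`` when it
    matches ``source_vocabulary`` (case-insensitively); otherwise the source
    is ``"unknown"``.  Duplicate gene symbols within a line are collapsed.
    Blank lines and lines starting with ``#`` are skipped.

    Parameters
    ----------
    uppercase
        If true, gene symbols are upper-cased at parse time.  By default
        symbols are matched as exact, case-sensitive strings.

    Raises
    ------
    ValueError
        On a line with fewer than three fields, a line with no genes, or a
        duplicate pathway identifier.
    """
    vocab_lookup = {v.casefold(): v for v in source_vocabulary}
    stream, close = _open_text(source)
    try:
        pathways: list[Pathway] = []
        seen: set[str] = set()
        for lineno, raw in enumerate(stream, start=1):
            line = raw.rstrip("\n").rstrip("\r")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(
                    f"line {lineno}: expected at least 3 tab-separated fields "
                    f"(id, description, genes...), got {len(fields)}"
                )
            pid, description = fields[0].strip(), fields[1].strip()
            genes = {g.strip() for g in fields[2:] if g.strip()}
            if uppercase:
                genes = {g.upper() for g in genes}
            if not genes:
                raise ValueError(f"line {lineno}: pathway {pid!r} has no genes")
            if pid in seen:
                raise ValueError(f"duplicate pathway id {pid!r}")
            seen.add(pid)
            src = vocab_lookup.get(description.casefold(), "unknown")
            pathways.append(Pathway(id=pid, source=src, genes=frozenset(genes)))
        return GeneSetCollection(pathways)
    finally:
        if close:
            stream.close()


def write_gmt(collection: GeneSetCollection, dest: TextSource) -> None:
    """Write a collection as GMT, genes in lexicographic order.

    The lexicographic gene order makes the output byte-stable, so identical
    collections serialise identically; ``read_gmt(write_gmt(c))`` reproduces
    ids, sources and gene sets.
    """
    stream, close = _open_text(dest, "w")
    try:
        for p in collection:
            stream.write("\t".join([p.id, p.source, *sorted(p.genes)]) + "\n")
    finally:
        if close:
            stream.close()


def gmt_dumps(collection: GeneSetCollection) -> str:
    """Serialise a collection to a GMT string (convenience wrapper)."""
    buf = _io.StringIO()
    write_gmt(collection, buf)
    return buf.getvalue()


def read_gene_list(source: TextSource) -> frozenset[str]:
    """Read a one-symbol-per-line gene list; blanks and ``#`` lines skipped."""
    stream, close = _open_text(source)
    try:
        return frozenset(
            line.strip()
            for line in stream
            if line.strip() and not line.lstrip().startswith("#")
        )
    finally:
        if close:
            stream.close()


def write_gene_list(genes: Iterable[str], dest: TextSource) -> None:
    stream, close = _open_text(dest, "w")
    try:
        for g in sorted(genes):
            stream.write(g + "\n")
    finally:
        if close:
            stream.close()


def read_enrichment_table(
    source: TextSource,
    collection: GeneSetCollection,
    de_genes: Iterable[str],
) -> EnrichedPathwaySet:
    """Load an enrichment-result table against its collection and DE list.

    The table must carry ``pathway_id`` and ``p_adjusted`` columns.  Entries
    whose pathway shares no gene with ``de_genes`` are dropped (they cannot
    contribute to covering the DE universe); the DE universe becomes the DE
    genes found in at least one retained entry.

    Raises
    ------
    ValueError
        If a pathway id does not resolve in ``collection``, a p-value falls
        outside [0, 1], or ``de_genes`` is empty.
    """
    de = frozenset(de_genes)
    if not de:
        raise ValueError("the DE gene list is empty")
    stream, close = _open_text(source)
    try:
        table = pd.read_csv(stream, sep="\t")
    finally:
        if close:
            stream.close()
    for col in ("pathway_id", "p_adjusted"):
        if col not in table.columns:
            raise ValueError(f"enrichment table is missing column {col!r}")
    entries: list[tuple[Pathway, float]] = []
    for row in table.itertuples(index=False):
        pid = str(row.pathway_id)
        pv = float(row.p_adjusted)
        if pid not in collection:
            raise ValueError(f"pathway id {pid!r} not present in the collection")
        if not (0.0 <= pv <= 1.0):
            raise ValueError(f"p-value {pv!r} for pathway {pid!r} outside [0, 1]")
        pathway = collection[pid]
        if pathway.genes & de:
            entries.append((pathway, pv))
    de_universe = de & frozenset().union(
        *(p.genes for p, _ in entries)
    ) if entries else frozenset()
    return EnrichedPathwaySet(entries=entries, de_universe=de_universe)


def write_enrichment_table(
    rows: Iterable[tuple[str, float]], dest: TextSource
) -> None:
    """Write (pathway_id, p_adjusted) rows as the canonical TSV."""
    stream, close = _open_text(dest, "w")
    try:
        stream.write("pathway_id\tp_adjusted\n")
        for pid, pv in rows:
            stream.write(f"{pid}\t{pv:.6g}\n")
    finally:
        if close:
            stream.close()
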