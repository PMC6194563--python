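"""Synthetic pathway collections and enrichment studies.

Real aggregated pathway resources (ConsensusPathDB-style) have three
structural features the cover algorithms exploit: heterogeneous, roughly
log-normal pathway sizes; a long-tailed gene-frequency distribution (hub
genes sit in dozens of pathways); and outright subset redundancy, where one
database's pathway is a fragment of another's.  The generator reproduces
all three with a latent-module model:

1. A pool of disjoint *functional modules* (blocks of genes) is created.
2. With probability ``overlap_intensity`` a pathway is built from shared
   modules: it samples modules and takes a random 30–100% portion of each
   (pathway boundaries are arbitrary, so a pathway captures part of a
   functional module, rarely exactly all of it) until a log-normal size
   target is reached.  Otherwise the pathway is built from fresh,
   pathway-private genes — mimicking databases whose content (e.g.
   small-molecule pathways) barely intersects the rest of the aggregate.
   Module reuse creates the frequency tail and the messy partial overlaps
   between pathway pairs.
3. With probability ``subset_rate`` a pathway is instead a strict random
   subset of an earlier pathway — the textbook redundancy the enrichment
   cover removes.

Gene symbols are synthetic tokens (``G000001`` ...), making no claim of
biological identity.  Generation is a pure function of the recipe: the same
recipe yields byte-identical GMT output.

An enrichment study is layered on top by declaring some modules
differentially expressed: DE genes are drawn from those modules plus a
uniform noise fraction, and each pathway receives a one-sided
hypergeometric over-representation p-value for its DE overlap.  That is the
canonical over-representation model and provides a realistic joint
structure of (p-value, gene set) without emulating any particular
enrichment tool.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.stats import hypergeom

from .io import GeneSetCollection, Pathway

__all__ = [
    "CollectionRecipe",
    "EnrichmentRecipe",
    "generate_collection",
    "generate_enrichment_study",
    "CPDB_LIKE",
]

#: Source-label sampling weights shaped like a CPDB-style aggregate, where
#: Reactome and SMPDB dominate counts and several small databases trail.
_DEFAULT_SOURCES: tuple[tuple[str, float], ...] = (
    ("Reactome", 0.396),
    ("SMPDB", 0.167),
    ("Wikipathways", 0.088),
    ("HumanCyc", 0.082),
    ("KEGG", 0.072),
    ("BioCarta", 0.063),
    ("PID", 0.052),
    ("PharmGKB", 0.028),
    ("INOH", 0.023),
    ("EHMN", 0.016),
    ("NetPath", 0.009),
    ("Signalink", 0.004),
)


@dataclass(frozen=True)
class CollectionRecipe:
    """Parameters of a synthetic pathway collection.

    Defaults describe the ``cpdb_like`` benchmark: 600 pathways over ~120
    modules with high module reuse, giving an overlap score well above the
    disjoint floor so the cover algorithms have meaningful work.
    """

    n_modules: int = 120
    module_size_range: tuple[int, int] = (4, 30)
    n_pathways: int = 600
    #: log-normal (mu, sigma) of intended pathway sizes; median ≈ 20 genes
    #: with a heavy right tail (a few pathways of hundreds of genes),
    #: echoing real aggregated resources.
    pathway_size_distribution: tuple[float, float] = (3.0, 1.1)
    overlap_intensity: float = 0.95
    subset_rate: float = 0.15
    source_labels: tuple[tuple[str, float], ...] = _DEFAULT_SOURCES
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_modules < 1 or self.n_pathways < 1:
            raise ValueError("counts must be >= 1")
        lo, hi = self.module_size_range
        if not (1 <= lo <= hi):
            raise ValueError("invalid module size range")
        if not (0.0 <= self.overlap_intensity <= 1.0):
            raise ValueError("overlap_intensity must lie in [0, 1]")
        if not (0.0 <= self.subset_rate <= 1.0):
            raise ValueError("subset_rate must lie in [0, 1]")
        if not self.source_labels:
            raise ValueError("at least one source label is required")


@dataclass(frozen=True)
class EnrichmentRecipe:
    """Parameters of a synthetic differential-expression study.

    ``enriched_module_ids`` designates the latent modules whose genes are
    preferentially differentially expressed; ``de_noise_rate`` is the
    fraction of DE genes drawn uniformly from the whole universe instead.
    """

    n_de_genes: int = 150
    enriched_module_ids: tuple[int, ...] = (0, 1, 2, 3, 4)
    de_noise_rate: float = 0.15
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_de_genes < 1:
            raise ValueError("n_de_genes must be >= 1")
        if not (0.0 <= self.de_noise_rate <= 1.0):
            raise ValueError("de_noise_rate must lie in [0, 1]")


#: The fixed-seed benchmark recipe used throughout the documentation.
CPDB_LIKE = CollectionRecipe()


def _gene_token(i: int) -> str:
    return f"G{i:06d}"


def generate_collection(recipe: CollectionRecipe) -> GeneSetCollection:
    """Generate a collection from a recipe; deterministic under its seed.

    The latent module gene lists and each pathway's module draws are stored
    in ``collection.metadata`` (keys ``"modules"`` and ``"pathway_modules"``)
    so an enrichment study can later plant DE genes inside chosen modules.

    Raises
    ------
    ValueError
        If the recipe is infeasible (e.g. a requested subset of a
        single-gene pathway).
    """
    rng = np.random.default_rng(recipe.seed)
    lo, hi = recipe.module_size_range
    next_gene = 0
    modules: list[list[str]] = []
    for _ in range(recipe.n_modules):
        size = int(rng.integers(lo, hi + 1))
        modules.append([_gene_token(next_gene + i) for i in range(size)])
        next_gene += size

    labels = [s for s, _ in recipe.source_labels]
    weights = np.array([w for _, w in recipe.source_labels], dtype=float)
    weights = weights / weights.sum()

    mu, sigma = recipe.pathway_size_distribution
    pathways: list[Pathway] = []
    pathway_modules: list[list[int]] = []
    for i in range(recipe.n_pathways):
        source = labels[int(rng.choice(len(labels), p=weights))]
        make_subset = (
            len(pathways) > 0
            and rng.random() < recipe.subset_rate
            and any(p.size >= 2 for p in pathways)
        )
        if make_subset:
            candidates = [j for j, p in enumerate(pathways) if p.size >= 2]
            parent_idx = int(rng.choice(candidates))
            parent = pathways[parent_idx]
            sub_size = int(rng.integers(1, parent.size))  # strict subset
            genes = set(
                rng.choice(sorted(parent.genes), size=sub_size, replace=False)
            )
            used_modules = list(pathway_modules[parent_idx])
        elif rng.random() < recipe.overlap_intensity:
            # module-built pathway: partial draws from sampled modules
            total_pool = sum(len(m) for m in modules)
            # size targets are approximate; a heavy-tail draw is clamped to
            # the module pool rather than failing the recipe
            target = min(max(2, int(round(rng.lognormal(mu, sigma)))), total_pool)
            genes = set()
            used_modules = []
            while len(genes) < target and len(used_modules) < recipe.n_modules:
                m = int(rng.integers(0, recipe.n_modules))
                if m in used_modules:
                    continue
                pool = modules[m]
                portion = max(1, int(round(len(pool) * rng.uniform(0.3, 1.0))))
                take = min(portion, len(pool), target - len(genes))
                genes.update(rng.choice(pool, size=take, replace=False))
                used_modules.append(m)
        else:
            # pathway-private genes, disjoint from everything generated so far
            target = max(2, int(round(rng.lognormal(mu, sigma))))
            genes = {_gene_token(next_gene + j) for j in range(target)}
            next_gene += target
            used_modules = []
        pathways.append(
            Pathway(id=f"P{i:04d}", source=source, genes=frozenset(genes))
        )
        pathway_modules.append(used_modules)

    collection = GeneSetCollection(pathways)
    collection.metadata["modules"] = modules
    collection.metadata["pathway_modules"] = pathway_modules
    collection.metadata["recipe_seed"] = recipe.seed
    return collection


def generate_enrichment_study(
    collection: GeneSetCollection, recipe: EnrichmentRecipe
) -> tuple[frozenset[str], list[tuple[str, float]]]:
    """Plant a DE gene set in chosen modules and score every pathway.

    Returns ``(de_genes, table)`` where ``table`` rows are
    ``(pathway_id, p_adjusted)`` sorted ascending by p-value (ties by id).
    The p-value of a pathway is the one-sided hypergeometric tail of its DE
    overlap given universe size, DE count and pathway size; a pathway
    disjoint from the DE genes scores p = 1.

    Requires a collection produced by :func:`generate_collection` (the
    latent modules travel in ``collection.metadata``).
    """
    modules = collection.metadata.get("modules")
    if modules is None:
        raise ValueError(
            "collection carries no latent modules; generate it with "
            "generate_collection first"
        )
    for m in recipe.enriched_module_ids:
        if not (0 <= m < len(modules)):
            raise ValueError(f"module index {m} out of range (0..{len(modules) - 1})")
    universe = sorted(collection.universe)
    if recipe.n_de_genes > len(universe):
        raise ValueError(
            f"n_de_genes={recipe.n_de_genes} exceeds the universe size "
            f"{len(universe)}"
        )

    rng = np.random.default_rng(recipe.seed)
    enriched_pool = sorted(
        {g for m in recipe.enriched_module_ids for g in modules[m]}
        & collection.universe
    )
    n_noise = int(round(recipe.de_noise_rate * recipe.n_de_genes))
    n_signal = min(recipe.n_de_genes - n_noise, len(enriched_pool))
    de: set[str] = set(
        rng.choice(enriched_pool, size=n_signal, replace=False)
    ) if n_signal else set()
    # top up with uniform noise until the requested DE count is reached
    remaining = [g for g in universe if g not in de]
    n_fill = recipe.n_de_genes - len(de)
    if n_fill > 0:
        de.update(rng.choice(remaining, size=n_fill, replace=False))

    M, n_de = len(universe), len(de)
    table: list[tuple[str, float]] = []
    for p in collection:
        k = len(p.genes & de)
        pv = float(hypergeom.sf(k - 1, M, n_de, p.size)) if k > 0 else 1.0
        table.append((p.id, min(1.0, max(0.0, pv))))
    table.sort(key=lambda row: (row[1], row[0]))
    return frozenset(de), table
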