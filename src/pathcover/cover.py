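"""Greedy set-cover engine for pathway collections.

Three scoring rules drive the same greedy loop; each targets a different
compromise between redundancy, pathway size and gene coverage:

* **standard** — a pathway's value is the number of uncovered genes it
  contains, ``v_i = |s_i ∩ R|``.  This is the textbook greedy set cover;
  it minimises the number of selected pathways but favours very large ones.
* **proportional** — the *proportion* of a pathway's genes still uncovered,
  ``v_i = |s_i ∩ R| / |s_i| + 1 / (|  |s_i| − mean | · k)``, where ``mean``
  is the mean pathway size of the input collection and ``k`` (default
  10,000) is a large constant keeping the second term a mere tie-breaker.
  The tie-break pulls selections toward mean-sized pathways, controlling
  size variability.
* **hitting** — the dual (set-hitting) view: each gene j is worth the
  reciprocal of its pathway frequency, ``1/f_j``, and a pathway scores the
  mean rarity of its uncovered genes, ``v_i = (Σ_{j∈s_i∩R} 1/f_j) / |s_i|``.
  Pathways holding genes found nowhere else must eventually be picked, so
  rewarding rarity removes the most redundancy.

The loop adds the best-scoring candidate (a pathway with at least one
uncovered gene), marks its genes covered, and stops once the gene-coverage
target ``ceil(GC · |U|)`` is reached.  Setting the gene coverage fraction GC
below 1 stops the loop before the last, most redundant selections.

``mean`` and the gene frequencies ``f_j`` are computed once over the full
input collection and frozen for the run; they do not shrink with the
candidate pool.
"""

from __future__ import annotations

import math
import random
from dataclasses import dataclass, field, replace
from typing import Iterable, Literal, Mapping, NamedTuple, Optional

from .io import GeneSetCollection, Pathway

__all__ = [
    "Algorithm",
    "CoverContext",
    "CoverState",
    "CoverResult",
    "Selection",
    "gene_frequencies",
    "score_standard",
    "score_proportional",
    "score_hitting",
    "greedy_cover",
]

Algorithm = Literal["standard", "proportional", "hitting"]
ALGORITHMS: tuple[str, ...] = ("standard", "proportional", "hitting")

#: Relative tolerance under which two scores are considered tied.  Keeps the
#: argmax stable across summation orders and platforms.
SCORE_RTOL = 1e-12

#: Guard for the proportional tie-break when |s_i| equals the mean exactly:
#: sizes are integers, so 0.5 is the smallest nonzero distance to a
#: non-integral mean and preserves the closest-to-mean ordering.
MEAN_GAP_FLOOR = 0.5


def gene_frequencies(collection: GeneSetCollection) -> dict[str, int]:
    """Count, for every gene j, the number of pathways containing it (f_j)."""
    freq: dict[str, int] = {}
    for p in collection:
        for g in p.genes:
            freq[g] = freq.get(g, 0) + 1
    return freq


@dataclass(frozen=True)
class CoverContext:
    """Frozen per-run constants of a greedy cover.

    Parameters
    ----------
    mean_size
        Mean pathway size of the input collection (proportional tie-break).
    gene_freq
        Pathway frequency f_j of every gene in the collection (hitting).
    k
        Large constant damping the proportional second term; default 10,000.
    gc_fraction
        Gene coverage target GC in (0, 1]: the loop may stop once
        ``ceil(gc_fraction · |U|)`` genes are covered.
    tie_policy
        ``"deterministic"`` (max score, then max newly-covered count, then
        smallest id — fully reproducible) or ``"random"`` (uniform among
        score-tied candidates; requires ``seed``).
    """

    mean_size: float
    gene_freq: Mapping[str, int]
    k: float = 10_000.0
    gc_fraction: float = 1.0
    tie_policy: Literal["deterministic", "random"] = "deterministic"
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if self.mean_size <= 0:
            raise ValueError("mean_size must be positive")
        if self.k <= 0:
            raise ValueError("k must be positive")
        if not (0.0 < self.gc_fraction <= 1.0):
            raise ValueError("gc_fraction must lie in (0, 1]")
        if self.tie_policy not in ("deterministic", "random"):
            raise ValueError(f"unknown tie policy {self.tie_policy!r}")
        if self.tie_policy == "random" and self.seed is None:
            raise ValueError("tie_policy='random' requires an explicit seed")
        if any(f < 1 for f in self.gene_freq.values()):
            raise ValueError("every gene frequency must be >= 1")

    @classmethod
    def from_collection(cls, collection: GeneSetCollection, **kwargs) -> "CoverContext":
        """Build a context with mean size and f_j frozen from ``collection``."""
        return cls(
            mean_size=collection.mean_size,
            gene_freq=gene_frequencies(collection),
            **kwargs,
        )


class Selection(NamedTuple):
    """One greedy step: which pathway, at what score, covering what."""

    pathway_id: str
    score: float
    new_genes: int


@dataclass
class CoverState:
    """Mutable bookkeeping of a cover in progress.

    ``covered`` (C) and ``uncovered`` (R) partition the target universe;
    ``selections`` logs every step.  Exposed so the scoring functions can be
    used and tested outside the loop.
    """

    covered: set[str]
    uncovered: set[str]
    selections: list[Selection] = field(default_factory=list)

    @classmethod
    def fresh(cls, universe: Iterable[str]) -> "CoverState":
        return cls(covered=set(), uncovered=set(universe))


def score_standard(pathway: Pathway, state: CoverState) -> float:
    """Number of still-uncovered genes in the pathway, |s_i ∩ R|."""
    return float(len(pathway.genes & state.uncovered))


def score_proportional(
    pathway: Pathway, state: CoverState, ctx: CoverContext
) -> float:
    """Proportion of uncovered genes plus the mean-size tie-break term."""
    uncovered = len(pathway.genes & state.uncovered)
    gap = max(abs(pathway.size - ctx.mean_size), MEAN_GAP_FLOOR)
    return uncovered / pathway.size + 1.0 / (gap * ctx.k)


def score_hitting(pathway: Pathway, state: CoverState, ctx: CoverContext) -> float:
    """Mean rarity of the pathway's uncovered genes, (Σ 1/f_j) / |s_i|."""
    try:
        total = math.fsum(
            1.0 / ctx.gene_freq[g] for g in pathway.genes & state.uncovered
        )
    except KeyError as exc:
        raise ValueError(
            f"no frequency recorded for gene {exc.args[0]!r} in pathway "
            f"{pathway.id!r}"
        ) from None
    return total / pathway.size


@dataclass(frozen=True)
class CoverResult:
    """Outcome of a greedy cover run.

    ``selected`` preserves selection order; ``covered_genes`` is the union of
    the selected pathways' genes restricted to the target universe.
    ``complete`` is False only when the loop ran out of candidates before
    reaching the coverage target (possible only with a user-restricted
    universe), in which case ``warning`` explains the shortfall.
    """

    algorithm: str
    selected: tuple[str, ...]
    covered_genes: frozenset[str]
    selections: tuple[Selection, ...]
    context: CoverContext
    universe_size: int
    target: int
    complete: bool = True
    warning: Optional[str] = None

    @property
    def coverage_fraction(self) -> float:
        return len(self.covered_genes) / self.universe_size

    def step_log_rows(self) -> list[dict]:
        """Rows for the step-log TSV: running score/coverage per selection."""
        rows, cum = [], 0
        for step, sel in enumerate(self.selections, start=1):
            cum += sel.new_genes
            rows.append(
                {
                    "step": step,
                    "pathway_id": sel.pathway_id,
                    "score": sel.score,
                    "new_genes": sel.new_genes,
                    "cumulative_coverage_fraction": cum / self.universe_size,
                }
            )
        return rows


def _ties_equal(a: float, b: float) -> bool:
    return abs(a - b) <= SCORE_RTOL * max(1.0, abs(a), abs(b))


def greedy_cover(
    collection: GeneSetCollection,
    algorithm: Algorithm = "hitting",
    ctx: Optional[CoverContext] = None,
    *,
    universe: Optional[Iterable[str]] = None,
    **ctx_kwargs,
) -> CoverResult:
    """Run the greedy set cover over ``collection``.

    Parameters
    ----------
    collection
        Input pathways; mean size and gene frequencies are frozen from it.
    algorithm
        ``"standard"``, ``"proportional"`` or ``"hitting"``.
    ctx
        A fully built :class:`CoverContext`.  If omitted, one is derived
        from ``collection`` and ``ctx_kwargs`` (``gc_fraction``, ``k``,
        ``tie_policy``, ``seed``).
    universe
        Optional restriction of the gene universe.  By default the target is
        the collection's own universe, which the collection can always cover;
        a restricted universe may be uncoverable, in which case the loop
        terminates with ``complete=False`` rather than raising.

    Notes
    -----
    Only *candidates* — pathways contributing at least one uncovered gene —
    are ever scored, for all three algorithms.  This guarantees each logged
    selection makes progress and keeps the proportional tie-break term from
    selecting an exhausted pathway.

    The engine maintains, per pathway, the set of its genes still uncovered,
    updated through an inverted gene→pathway index; scores are recomputed
    from those residual sets, so the selection sequence is identical to a
    naive full-rescan evaluation.
    """
    if algorithm not in ALGORITHMS:
        raise ValueError(
            f"unknown algorithm {algorithm!r}; choose one of {ALGORITHMS}"
        )
    if ctx is None:
        ctx = CoverContext.from_collection(collection, **ctx_kwargs)
    elif ctx_kwargs:
        ctx = replace(ctx, **ctx_kwargs)

    target_universe = (
        frozenset(universe) & collection.universe
        if universe is not None
        else collection.universe
    )
    n_universe = len(target_universe)
    target = max(0, math.ceil(ctx.gc_fraction * n_universe - 1e-9))

    rng = random.Random(ctx.seed) if ctx.tie_policy == "random" else None

    # Residual uncovered genes per pathway plus an inverted index for updates.
    residual: dict[str, set[str]] = {
        p.id: set(p.genes & target_universe) for p in collection
    }
    containing: dict[str, list[str]] = {}
    for p in collection:
        for g in p.genes & target_universe:
            containing.setdefault(g, []).append(p.id)
    sizes = {p.id: p.size for p in collection}
    gaps = {
        p.id: max(abs(p.size - ctx.mean_size), MEAN_GAP_FLOOR) for p in collection
    }

    state = CoverState.fresh(target_universe)
    selected: list[str] = []
    covered: set[str] = state.covered
    candidates = {pid for pid, res in residual.items() if res}

    def current_score(pid: str) -> float:
        res = residual[pid]
        if algorithm == "standard":
            return float(len(res))
        if algorithm == "proportional":
            return len(res) / sizes[pid] + 1.0 / (gaps[pid] * ctx.k)
        return math.fsum(1.0 / ctx.gene_freq[g] for g in res) / sizes[pid]

    complete = True
    warning = None
    while len(covered) < target:
        if not candidates:
            complete = False
            warning = (
                f"no remaining pathway covers new genes; stopped at "
                f"{len(covered)}/{target} target genes"
            )
            break
        best_score = max(current_score(pid) for pid in candidates)
        tied = [
            pid for pid in candidates if _ties_equal(current_score(pid), best_score)
        ]
        if rng is not None and len(tied) > 1:
            choice = rng.choice(sorted(tied))
        else:
            # max newly covered, then lexicographically smallest id
            choice = min(tied, key=lambda pid: (-len(residual[pid]), pid))
        newly = residual[choice].copy()
        state.selections.append(
            Selection(choice, current_score(choice), len(newly))
        )
        selected.append(choice)
        covered |= newly
        state.uncovered -= newly
        for g in newly:
            for pid in containing[g]:
                residual[pid].discard(g)
                if pid in candidates and not residual[pid]:
                    candidates.discard(pid)
        candidates.discard(choice)

    return CoverResult(
        algorithm=algorithm,
        selected=tuple(selected),
        covered_genes=frozenset(covered),
        selections=tuple(state.selections),
        context=ctx,
        universe_size=n_universe,
        target=target,
        complete=complete,
        warning=warning,
    )
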