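"""Independent reference implementations used as test oracles.

Everything here is written deliberately naively and separately from the
package: scores are recomputed from scratch with their own formula code at
every iteration, optimal covers come from exhaustive subset enumeration,
and the enrichment argmax is a literal value-maximisation loop.  The tests
compare the package's optimised engines against these references.
"""

from __future__ import annotations

import itertools
import math
import random

from pathcover.io import GeneSetCollection, Pathway

K = 10_000.0
TOL = 1e-12


def _ties(a: float, b: float) -> bool:
    return abs(a - b) <= TOL * max(1.0, abs(a), abs(b))


def naive_greedy(
    collection: GeneSetCollection, algorithm: str, gc_fraction: float = 1.0
) -> list[str]:
    """Full-rescan greedy: rescore every pathway from scratch each round."""
    sets = {p.id: set(p.genes) for p in collection}
    universe = set().union(*sets.values())
    mean = sum(len(s) for s in sets.values()) / len(sets)
    freq: dict[str, int] = {}
    for s in sets.values():
        for g in s:
            freq[g] = freq.get(g, 0) + 1

    covered: set[str] = set()
    chosen: list[str] = []
    target = math.ceil(gc_fraction * len(universe) - 1e-9)
    while len(covered) < target:
        best = None  # (score, n_new, id)
        for pid, s in sets.items():
            if pid in chosen:
                continue
            new = s - covered
            if not new:
                continue
            if algorithm == "standard":
                score = float(len(new))
            elif algorithm == "proportional":
                score = len(new) / len(s) + 1.0 / (
                    max(abs(len(s) - mean), 0.5) * K
                )
            elif algorithm == "hitting":
                score = math.fsum(1.0 / freq[g] for g in new) / len(s)
            else:
                raise ValueError(algorithm)
            cand = (score, len(new), pid)
            if best is None:
                best = cand
            elif _ties(cand[0], best[0]):
                if (-cand[1], cand[2]) < (-best[1], best[2]):
                    best = cand
            elif cand[0] > best[0]:
                best = cand
        if best is None:
            break
        chosen.append(best[2])
        covered |= sets[best[2]]
    return chosen


def optimal_cover_size(collection: GeneSetCollection) -> int:
    """Minimum number of pathways covering the universe, by enumeration."""
    sets = [set(p.genes) for p in collection]
    universe = set().union(*sets)
    for k in range(1, len(sets) + 1):
        for combo in itertools.combinations(sets, k):
            if set().union(*combo) >= universe:
                return k
    raise AssertionError("unreachable: the full collection covers its universe")


def harmonic(n: int) -> float:
    return sum(1.0 / i for i in range(1, n + 1))


def argmax_enrichment_cover(
    entries: list[tuple[Pathway, float]], de_universe: frozenset[str]
) -> list[str]:
    """Literal argmax of v_i = (1 − p_i) · b, b = [s_i ∩ R ≠ ∅]."""
    uncovered = set(de_universe)
    remaining = {p.id: (set(p.genes) & de_universe, pv) for p, pv in entries}
    chosen: list[str] = []
    while True:
        best = None
        for pid, (genes, pv) in remaining.items():
            b = 1 if genes & uncovered else 0
            v = (1.0 - pv) * b
            if v <= 0.0:
                continue
            # ties in (1 - p) resolved toward the smaller id
            if best is None or v > best[0] or (v == best[0] and pid < best[1]):
                best = (v, pid)
        if best is None:
            break
        pid = best[1]
        uncovered -= remaining[pid][0]
        del remaining[pid]
        chosen.append(pid)
    return chosen


def random_instance(
    rng: random.Random, max_pathways: int = 50, max_genes: int = 200
) -> GeneSetCollection:
    """Random small collection with mixed structure (blocks, subsets, noise)."""
    n_genes = rng.randint(10, max_genes)
    genes = [f"g{i}" for i in range(n_genes)]
    n_pathways = rng.randint(3, max_pathways)
    pathways: list[Pathway] = []
    for i in range(n_pathways):
        style = rng.random()
        if style < 0.25 and pathways:
            parent = rng.choice(pathways)
            if len(parent.genes) > 1:
                size = rng.randint(1, len(parent.genes) - 1)
                members = rng.sample(sorted(parent.genes), size)
            else:
                members = sorted(parent.genes)
        else:
            size = rng.randint(1, max(2, n_genes // 3))
            members = rng.sample(genes, min(size, n_genes))
        pathways.append(
            Pathway(id=f"p{i:03d}", source="unknown", genes=frozenset(members))
        )
    return GeneSetCollection(pathways)
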