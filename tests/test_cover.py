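"""Scoring functions and the greedy cover loop."""

import math
import random

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pathcover.cover import (
    CoverContext,
    CoverState,
    gene_frequencies,
    greedy_cover,
    score_hitting,
    score_proportional,
    score_standard,
)
from pathcover.io import Pathway

from conftest import make_collection
from oracles import naive_greedy, random_instance


def pw(pid, genes):
    return Pathway(pid, "unknown", frozenset(genes))


def ctx_for(collection, **kw):
    return CoverContext.from_collection(collection, **kw)


class TestScoreStandard:
    def test_counts_uncovered_intersection(self):
        state = CoverState(covered=set(), uncovered={"a", "b", "c"})
        assert score_standard(pw("p", {"a", "b"}), state) == 2.0

    def test_zero_when_disjoint_from_uncovered(self):
        state = CoverState(covered=set(), uncovered={"a"})
        assert score_standard(pw("p", {"b", "c"}), state) == 0.0

    def test_zero_at_terminal_state(self):
        state = CoverState(covered={"a", "b"}, uncovered=set())
        assert score_standard(pw("p", {"a", "b"}), state) == 0.0


class TestScoreProportional:
    def test_direct_arithmetic(self):
        # |s|=4, 2 uncovered, mean 8/3: 0.5 + 1/((4-8/3)*1e4) = 0.500075
        c = make_collection(("A", list("wxyz")), ("B", ["x"]), ("C", list("xyz")))
        assert math.isclose(c.mean_size, 8 / 3)
        state = CoverState(covered={"w", "x"}, uncovered={"y", "z"})
        got = score_proportional(c["A"], state, ctx_for(c))
        assert got == pytest.approx(0.500075, abs=1e-9)

    def test_exact_mean_guard_uses_half_gap(self):
        # |s|=3 equals mean 3.0 exactly: 1 + 1/(0.5*1e4) = 1.0002
        c = make_collection(("A", list("abc")), ("B", list("def")))
        state = CoverState(covered=set(), uncovered=set("abcdef"))
        assert score_proportional(c["A"], state, ctx_for(c)) == pytest.approx(
            1.0002, abs=1e-12
        )

    def test_only_tiebreak_term_when_fully_covered(self):
        c = make_collection(("A", list("abcde")), ("B", list("xyz")))
        assert c.mean_size == 4.0
        state = CoverState(covered=set("abcde"), uncovered={"x"})
        assert score_proportional(c["A"], state, ctx_for(c)) == pytest.approx(
            0.0001, abs=1e-12
        )


class TestScoreHitting:
    def test_mean_rarity(self):
        c = make_collection(("A", ["g1", "g2"]), ("B", ["g2"]))
        state = CoverState(covered=set(), uncovered={"g1", "g2"})
        # f(g1)=1, f(g2)=2 → (1 + 0.5)/2 = 0.75
        assert score_hitting(c["A"], state, ctx_for(c)) == 0.75

    def test_single_shared_gene(self):
        c = make_collection(("A", ["g3"]), ("B", ["g3"]))
        state = CoverState(covered=set(), uncovered={"g3"})
        assert score_hitting(c["A"], state, ctx_for(c)) == 0.5

    def test_zero_when_covered(self):
        c = make_collection(("A", ["g1"]), ("B", ["g1"]))
        state = CoverState(covered={"g1"}, uncovered=set())
        assert score_hitting(c["A"], state, ctx_for(c)) == 0.0

    def test_missing_frequency_is_hard_error(self):
        c = make_collection(("A", ["g1"]))
        ctx = CoverContext(mean_size=1.0, gene_freq={})
        state = CoverState(covered=set(), uncovered={"g1"})
        with pytest.raises(ValueError, match="g1"):
            score_hitting(c["A"], state, ctx)


class TestGeneFrequencies:
    def test_counts(self):
        c = make_collection(("A", ["a", "b"]), ("B", ["b", "c"]))
        assert gene_frequencies(c) == {"a": 1, "b": 2, "c": 1}

    def test_singleton(self):
        assert gene_frequencies(make_collection(("A", ["x"]))) == {"x": 1}


class TestGreedyCover:
    def test_hand_traced_selection(self, tiny_collection):
        """Step 2 ties S3/S4 at score 2; lexicographic id breaks the tie."""
        r = greedy_cover(tiny_collection, "standard")
        assert list(r.selected) == ["S1", "S3", "S4"]
        assert r.covered_genes == tiny_collection.universe
        assert r.complete

    def test_dominant_set_selected_alone(self):
        c = make_collection(
            ("ALL", list("abcdef")), ("X", list("ab")), ("Y", list("cd"))
        )
        r = greedy_cover(c, "standard")
        assert list(r.selected) == ["ALL"]
        assert r.covered_genes == c.universe

    def test_gc_stops_after_target_met(self):
        c = make_collection(
            ("S1", list("abcd")), ("S2", list("efg")), ("S3", list("h"))
        )
        r = greedy_cover(c, "standard", gc_fraction=0.5)
        # ceil(0.5*8) = 4 genes; S1 alone reaches the target
        assert list(r.selected) == ["S1"]
        assert r.target == 4

    def test_every_selection_covers_new_genes(self, tiny_collection):
        for alg in ("standard", "proportional", "hitting"):
            r = greedy_cover(tiny_collection, alg)
            assert all(s.new_genes >= 1 for s in r.selections)
            assert sum(s.new_genes for s in r.selections) == len(r.covered_genes)

    def test_restricted_universe_shortfall_flags_not_raises(self, tiny_collection):
        r = greedy_cover(tiny_collection, "standard", universe={"1", "nonexistent"})
        assert r.complete  # "nonexistent" is outside the collection: U = {"1"}
        r2 = greedy_cover(
            make_collection(("A", ["a"]), ("B", ["a", "b"])),
            "standard",
            universe={"a"},
            gc_fraction=1.0,
        )
        assert r2.complete and r2.covered_genes == {"a"}

    def test_unknown_algorithm_rejected(self, tiny_collection):
        with pytest.raises(ValueError, match="unknown algorithm"):
            greedy_cover(tiny_collection, "fastest")

    def test_random_tie_policy_requires_seed(self, tiny_collection):
        with pytest.raises(ValueError, match="seed"):
            greedy_cover(tiny_collection, "standard", tie_policy="random")

    def test_random_tie_policy_reproducible(self, tiny_collection):
        a = greedy_cover(tiny_collection, "standard", tie_policy="random", seed=7)
        b = greedy_cover(tiny_collection, "standard", tie_policy="random", seed=7)
        assert a.selected == b.selected

    def test_random_tie_policy_varies_across_seeds(self):
        # many identical-score pathways: some seed pair must disagree
        c = make_collection(*[(f"T{i}", [f"x{i}", "shared"]) for i in range(8)])
        picks = {
            greedy_cover(c, "standard", tie_policy="random", seed=s).selected[0]
            for s in range(25)
        }
        assert len(picks) > 1

    def test_step_log_rows(self, tiny_collection):
        rows = greedy_cover(tiny_collection, "standard").step_log_rows()
        assert [r["step"] for r in rows] == [1, 2, 3]
        assert rows[-1]["cumulative_coverage_fraction"] == 1.0


class TestContextValidation:
    def test_gc_bounds(self, tiny_collection):
        for bad in (0.0, -0.1, 1.5):
            with pytest.raises(ValueError):
                ctx_for(tiny_collection, gc_fraction=bad)

    def test_k_positive(self, tiny_collection):
        with pytest.raises(ValueError):
            ctx_for(tiny_collection, k=0)


@settings(derandomize=True, max_examples=30, deadline=None)
@given(st.integers(0, 10_000), st.sampled_from(["standard", "proportional", "hitting"]))
def test_matches_naive_rescan_oracle(seed, algorithm):
    """The incremental engine reproduces a from-scratch rescoring reference."""
    rng = random.Random(seed)
    c = random_instance(rng, max_pathways=20, max_genes=60)
    assert list(greedy_cover(c, algorithm).selected) == naive_greedy(c, algorithm)


@settings(derandomize=True, max_examples=30, deadline=None)
@given(st.integers(0, 10_000))
def test_proportional_score_range(seed):
    """First term of the proportional score lies in [0,1]; the tie-break
    term is bounded by 1/(0.5k) and cannot override a 3e-4 first-term gap."""
    rng = random.Random(seed)
    c = random_instance(rng, max_pathways=15, max_genes=50)
    ctx = ctx_for(c)
    state = CoverState(
        covered=set(rng.sample(sorted(c.universe), rng.randint(0, len(c.universe)))),
        uncovered=set(),
    )
    state.uncovered = set(c.universe) - state.covered
    for p in c:
        total = score_proportional(p, state, ctx)
        first = len(p.genes & state.uncovered) / p.size
        assert 0.0 <= first <= 1.0
        assert 0.0 < total - first <= 1.0 / (0.5 * ctx.k)


@settings(derandomize=True, max_examples=30, deadline=None)
@given(st.integers(0, 10_000))
def test_hitting_score_range(seed):
    """Hitting scores lie in [0,1]; 1 requires all genes uncovered and unique."""
    rng = random.Random(seed)
    c = random_instance(rng, max_pathways=15, max_genes=50)
    ctx = ctx_for(c)
    state = CoverState(covered=set(), uncovered=set(c.universe))
    for p in c:
        s = score_hitting(p, state, ctx)
        assert 0.0 <= s <= 1.0 + 1e-15
        if s >= 1.0 - 1e-15:
            assert all(ctx.gene_freq[g] == 1 for g in p.genes)
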