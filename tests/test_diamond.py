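import itertools
import math

import networkx as nx
import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from netmod.diamond import (
    DiamondStep,
    connectivity_pvalue,
    grow_module,
    rank_candidates,
)
from netmod.interactome import Interactome
from netmod.seeds import SeedSet


def enumerate_tail(N: int, s0: int, k: int, ks: int) -> float:
    """Oracle: P(X >= ks) by enumerating every k-subset of an N-population."""
    hits = total = 0
    for draw in itertools.combinations(range(N), k):
        total += 1
        if sum(1 for x in draw if x < s0) >= ks:
            hits += 1
    return hits / total if total else 1.0


def summation_tail(N: int, s0: int, k: int, ks: int) -> float:
    """Oracle: direct tail summation of the hypergeometric pmf."""
    den = math.comb(N, k)
    return sum(math.comb(s0, i) * math.comb(N - s0, k - i) for i in range(ks, min(k, s0) + 1)) / den


class TestConnectivityPvalue:
    @pytest.mark.parametrize(
        "N,s0,k,ks,expected",
        [
            (10, 3, 4, 0, 1.0),
            (10, 3, 4, 2, 1 / 3),   # 70 of the C(10,4)=210 draws have >= 2 successes
            (8, 2, 2, 2, 1 / 28),   # C(2,2)*C(6,0)/C(8,2)
            (8, 2, 2, 1, 13 / 28),
        ],
    )
    def test_known_values(self, N, s0, k, ks, expected):
        assert connectivity_pvalue(N, s0, k, ks) == pytest.approx(expected, abs=1e-15)
        assert enumerate_tail(N, s0, k, ks) == pytest.approx(expected, abs=1e-12)

    def test_invalid_arguments_rejected(self):
        for args in [(10, 0, 4, 0), (10, 3, 11, 0), (10, 3, 4, 5), (10, 3, 2, 3)]:
            with pytest.raises(ValueError):
                connectivity_pvalue(*args)

    def test_large_population_matches_scaled_summation(self):
        # asymptotic path (N > exact threshold) against exact integer summation
        for N, s0, k, ks in [(20000, 50, 300, 5), (16677, 20, 1000, 10)]:
            assert connectivity_pvalue(N, s0, k, ks) == pytest.approx(
                summation_tail(N, s0, k, ks), rel=1e-9
            )

    def test_never_zero_at_extreme_significance(self):
        p = connectivity_pvalue(20000, 500, 600, 500)
        assert 0.0 < p <= 1.0

    @settings(derandomize=True, max_examples=200)
    @given(st.data())
    def test_monotone_in_ks_and_k(self, data):
        N = data.draw(st.integers(5, 60))
        s0 = data.draw(st.integers(1, N - 1))
        k = data.draw(st.integers(2, N - 1))
        ks = data.draw(st.integers(1, min(k, s0)))
        p = connectivity_pvalue(N, s0, k, ks)
        # more module links -> strictly more surprising (except where the
        # pigeonhole bound forces successes and the tail is already 1)
        if ks - 1 >= 1:
            prev = connectivity_pvalue(N, s0, k, ks - 1)
            assert prev >= p
            if prev < 1.0:
                assert prev > p
        # higher degree with same module links -> less surprising
        if k + 1 <= N and ks <= min(k + 1, s0):
            assert connectivity_pvalue(N, s0, k + 1, ks) >= p


class TestRankCandidates:
    def test_toy_ranking(self, toy_graph):
        ranked = rank_candidates(toy_graph, {"A", "B"})
        assert [s.protein_id for s in ranked] == ["C", "F", "D"]
        by_id = {s.protein_id: s for s in ranked}
        assert (by_id["C"].k, by_id["C"].ks) == (2, 2)
        assert by_id["C"].p_value == pytest.approx(1 / 28)
        assert by_id["F"].p_value == pytest.approx(2 / 8)
        assert by_id["D"].p_value == pytest.approx(13 / 28)

    def test_full_module_has_no_candidates(self, toy_graph):
        assert rank_candidates(toy_graph, toy_graph.nodes) == []

    def test_matches_summation_oracle_on_random_graphs(self):
        rng = np.random.default_rng(5)
        for trial in range(10):
            n = int(rng.integers(20, 80))
            g = Interactome(nx.gnp_random_graph(n, 3.0 / n, seed=int(rng.integers(2**31))))
            nodes = sorted(g.nodes)
            module = set(rng.choice(nodes, size=5, replace=False))
            got = [(s.protein_id, s.k, s.ks) for s in rank_candidates(g, module)]
            want = []
            for v in nodes:
                if v in module:
                    continue
                ks = len(g.neighbors(v) & module)
                if ks >= 1:
                    want.append((summation_tail(g.N, len(module), g.degree(v), ks),
                                 -ks, g.degree(v), v))
            want.sort()
            assert got == [(v, k, -ks) for _, ks, k, v in want]


class TestGrowModule:
    def test_toy_first_addition(self, toy_graph):
        trace = grow_module(toy_graph, SeedSet("up", frozenset({"A", "B"})), max_added=1)
        (step,) = trace.steps
        assert (step.iteration, step.protein_id, step.k, step.ks) == (1, "C", 2, 2)
        assert step.p_value == pytest.approx(1 / 28)

    def test_exhaustion_flagged(self, toy_graph):
        trace = grow_module(toy_graph, {"A", "B"}, max_added=50)
        assert trace.exhausted
        # everything reachable from the seeds gets added, the G-H pair never does
        assert set(trace.added) == {"C", "D", "E", "F"}

    def test_empty_seeds_rejected(self, toy_graph):
        with pytest.raises(ValueError):
            grow_module(toy_graph, frozenset(), max_added=1)

    def test_one_per_iteration_and_deterministic(self, small_synthetic):
        _, g, truth = small_synthetic
        seeds = SeedSet("up", frozenset(truth.seeds_up))
        t1 = grow_module(g, seeds, max_added=15)
        t2 = grow_module(g, seeds, max_added=15)
        assert [s.protein_id for s in t1.steps] == [s.protein_id for s in t2.steps]
        assert [s.iteration for s in t1.steps] == list(range(1, 16))
        assert len(set(t1.added)) == len(t1.added)
        assert not set(t1.added) & seeds.proteins

    def test_always_include_pins_protein(self, toy_graph):
        trace = grow_module(toy_graph, {"A"}, max_added=1, always_include=["B"])
        assert trace.steps[0].protein_id == "C"  # C touches both A and B

    def test_step_validation(self):
        with pytest.raises(ValueError):
            DiamondStep(1, "X", k=2, ks=3, p_value=0.5)
        with pytest.raises(ValueError):
            DiamondStep(1, "X", k=2, ks=1, p_value=0.0)
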