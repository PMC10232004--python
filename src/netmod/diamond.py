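"""Connectivity-significance ranking and iterative module growth (DIAMOnD).

The algorithm scores every protein outside the current module by the
upper-tail hypergeometric probability that a protein with ``k`` interactome
links has at least ``ks`` links into the module by chance, given the
population of ``N`` proteins of which ``s0`` are module members:

    P(X >= ks),  X ~ Hypergeom(N, s0, k)

The candidate with the lowest P value joins the module and a new iteration
starts, so ``s0`` and the ``ks`` counts are recomputed against the growing
module (seeds plus everything added so far).

P values are computed with exact integer combinatorics for populations up
to ``EXACT_N`` nodes and with scipy's log-space survival function above
that; ranking always compares log P, so underflow at interactome scale can
never produce spurious ties or zeros.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from .interactome import Interactome
from .seeds import SeedSet

__all__ = [
    "DiamondStep",
    "DiamondTrace",
    "connectivity_pvalue",
    "rank_candidates",
    "grow_module",
    "EXACT_N",
]

#: population size up to which the tail is summed with exact integer arithmetic
EXACT_N = 600

#: smallest positive double; P values are clamped here so they are never 0
_TINY = 5e-324


@dataclass(frozen=True)
class DiamondStep:
    """One scored candidate: degree ``k``, module links ``ks``, tail P value."""

    iteration: int
    protein_id: str
    k: int
    ks: int
    p_value: float

    def __post_init__(self) -> None:
        if not (0 <= self.ks <= self.k):
            raise ValueError(f"invalid counts k={self.k}, ks={self.ks}")
        if not (0.0 < self.p_value <= 1.0):
            raise ValueError(f"p_value out of (0,1]: {self.p_value}")


@dataclass
class DiamondTrace:
    """Ordered record of module growth from a seed set."""

    seeds: frozenset[str]
    steps: list[DiamondStep]
    N: int
    exhausted: bool = False

    @property
    def added(self) -> list[str]:
        return [s.protein_id for s in self.steps]

    def members_at(self, n_added: int) -> set[str]:
        """Seed set plus the first ``n_added`` additions."""
        return set(self.seeds) | {s.protein_id for s in self.steps[:n_added]}

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "iteration": [s.iteration for s in self.steps],
                "protein_id": [s.protein_id for s in self.steps],
                "k": [s.k for s in self.steps],
                "ks": [s.ks for s in self.steps],
                "p_value": [s.p_value for s in self.steps],
            }
        )

    def write_tsv(self, path) -> None:
        df = self.to_frame()
        df["p_value"] = df["p_value"].map(lambda p: f"{p:.6e}")
        df.to_csv(path, sep="\t", index=False)


def _check_args(N: int, s0: int, k: int, ks: int) -> None:
    if s0 < 1:
        raise ValueError(f"s0 must be >= 1, got {s0}")
    if not (0 <= ks <= k <= N):
        raise ValueError(f"need 0 <= ks <= k <= N, got ks={ks}, k={k}, N={N}")
    if ks > s0 or s0 > N:
        raise ValueError(f"need ks <= s0 <= N, got ks={ks}, s0={s0}, N={N}")


def _exact_tail(N: int, s0: int, k: int, ks: int) -> tuple[int, int]:
    """Exact upper tail as (numerator, denominator) integers."""
    den = math.comb(N, k)
    num = sum(
        math.comb(s0, i) * math.comb(N - s0, k - i)
        for i in range(ks, min(k, s0) + 1)
    )
    return num, den


def connectivity_pvalue(N: int, s0: int, k: int, ks: int) -> float:
    """Upper-tail hypergeometric probability ``P(X >= ks)``.

    Population ``N``, success states ``s0`` (current module size), draws
    ``k`` (candidate degree). Exact for ``N <= EXACT_N``; log-space scipy
    otherwise, clamped away from zero.
    """
    _check_args(N, s0, k, ks)
    if ks == 0:
        return 1.0
    if N <= EXACT_N:
        num, den = _exact_tail(N, s0, k, ks)
        return num / den
    p = float(np.exp(hypergeom.logsf(ks - 1, N, s0, k)))
    return min(max(p, _TINY), 1.0)


def _pvalues(N: int, s0: int, k: np.ndarray, ks: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised (p, log p) tail probabilities for a batch of candidates.

    Ranking compares log p; the reported p is the exact ratio on the exact
    path so it matches :func:`connectivity_pvalue` bit for bit.
    """
    if N <= EXACT_N:
        p = np.empty(len(k))
        for i, (ki, ksi) in enumerate(zip(k.tolist(), ks.tolist())):
            num, den = _exact_tail(N, s0, ki, ksi)
            p[i] = num / den
        with np.errstate(divide="ignore"):
            return p, np.log(p)
    with np.errstate(divide="ignore"):
        logp = np.asarray(hypergeom.logsf(ks - 1, N, s0, k), dtype=float)
    return np.clip(np.exp(logp), _TINY, 1.0), logp


def _module_link_counts(g: Interactome, module_nodes: set[str]) -> dict[str, int]:
    """ks for every non-module node adjacent to the module."""
    adj = g.adjacency()
    ks: dict[str, int] = {}
    for m in module_nodes:
        for v in adj[m]:
            if v not in module_nodes:
                ks[v] = ks.get(v, 0) + 1
    return ks


def _rank(
    g: Interactome,
    s0: int,
    ks_counts: dict[str, int],
    start_iteration: int = 1,
) -> list[DiamondStep]:
    if not ks_counts:
        return []
    names = sorted(ks_counts)
    ks = np.array([ks_counts[v] for v in names], dtype=np.int64)
    k = np.array([g.degree(v) for v in names], dtype=np.int64)
    pvals, logp = _pvalues(g.N, s0, k, ks)
    order = sorted(
        range(len(names)),
        key=lambda i: (logp[i], -int(ks[i]), int(k[i]), names[i]),
    )
    steps = []
    for rank, i in enumerate(order):
        p = float(pvals[i])
        steps.append(
            DiamondStep(
                iteration=start_iteration + rank,
                protein_id=names[i],
                k=int(k[i]),
                ks=int(ks[i]),
                p_value=p,
            )
        )
    return steps


def rank_candidates(g: Interactome, module_nodes: Iterable[str]) -> list[DiamondStep]:
    """Score and rank every protein adjacent to the current module.

    Candidates are all non-module proteins with at least one link into the
    module. Sorting is ascending in P value with ties broken by larger
    ``ks``, then smaller ``k``, then lexicographic identifier, so the
    ranking is fully deterministic. An empty list means growth is
    exhausted.
    """
    module = set(module_nodes)
    if not module:
        raise ValueError("module_nodes must be non-empty")
    unknown = module - g.nodes
    if unknown:
        raise KeyError("module nodes not in interactome: " + ", ".join(sorted(unknown)[:10]))
    return _rank(g, len(module), _module_link_counts(g, module))


def grow_module(
    g: Interactome,
    seeds: SeedSet | Iterable[str],
    max_added: int,
    *,
    always_include: Sequence[str] = (),
) -> DiamondTrace:
    """Grow a module by repeatedly adding the most significant candidate.

    Each iteration rescores all candidates against the current module
    (seeds plus previous additions, so ``s0`` grows by one per step) and
    appends the top-ranked protein. Stops after ``max_added`` additions or
    when no candidate touches the module (``exhausted`` is then set).

    ``always_include`` pins proteins into the module before growth starts
    without counting them as seeds for selection purposes (e.g. the gene
    knocked out in the experiment).
    """
    seed_set = frozenset(seeds.proteins if isinstance(seeds, SeedSet) else seeds)
    if not seed_set:
        raise ValueError("seed set is empty")
    if max_added < 1:
        raise ValueError("max_added must be >= 1")
    unknown = (seed_set | set(always_include)) - g.nodes
    if unknown:
        raise KeyError("seeds not in interactome: " + ", ".join(sorted(unknown)[:10]))

    module = set(seed_set) | set(always_include)
    ks_counts = _module_link_counts(g, module)
    adj = g.adjacency()
    steps: list[DiamondStep] = []
    exhausted = False
    for it in range(1, max_added + 1):
        ranked = _rank(g, len(module), ks_counts, start_iteration=it)
        if not ranked:
            exhausted = True
            break
        best = ranked[0]
        steps.append(best)
        v = best.protein_id
        module.add(v)
        ks_counts.pop(v)
        for u in adj[v]:
            if u not in module:
                ks_counts[u] = ks_counts.get(u, 0) + 1
    return DiamondTrace(
        seeds=frozenset(module - {s.protein_id for s in steps}),
        steps=steps,
        N=g.N,
        exhausted=exhausted,
    )
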