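"""Final module size via the largest-connected-component z-score break-off.

After each growth iteration the candidate module (seeds plus the added
prefix) is reduced to its largest connected component (LCC) and compared
against random expectation: node sets of the same cardinality are drawn at
random from the interactome (1,000 samples by default) and

    z = (module - random_module) / sigma_random

where ``module`` is the observed LCC size and ``random_module`` /
``sigma_random`` are the mean and standard deviation of the sampled LCC
sizes. The final module is the smallest prefix at which every seed lies in
one connected component of the candidate module and z exceeds the
significance threshold (1.96 by default).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .diamond import DiamondTrace
from .interactome import Interactome
from .seeds import SeedSet

__all__ = [
    "NullDistribution",
    "TrajectoryPoint",
    "ModuleResult",
    "sample_null_lcc",
    "z_score",
    "determine_final_module",
]

log = logging.getLogger(__name__)


def _child_seed(rng_seed: int, key: int) -> int:
    """Deterministic per-size stream split, kept in the int32 range."""
    state = np.random.SeedSequence(entropy=rng_seed, spawn_key=(key,))
    return int(state.generate_state(1)[0]) & 0x7FFFFFFF


@dataclass(frozen=True)
class NullDistribution:
    """LCC sizes of random node sets of fixed cardinality."""

    set_size: int
    n_samples: int
    lcc_sizes: tuple[int, ...]
    rng_seed: int
    scheme: str = "uniform"

    @property
    def mean(self) -> float:
        return float(np.mean(self.lcc_sizes))

    @property
    def sd(self) -> float:
        return float(np.std(self.lcc_sizes))  # population sd over the samples


def _degree_bins(g: Interactome) -> dict[int, list[str]]:
    """Nodes grouped into log2 degree bins (degree 0 is its own bin)."""
    bins: dict[int, list[str]] = {}
    for v in sorted(g.nodes):
        d = g.degree(v)
        b = -1 if d == 0 else int(math.log2(d))
        bins.setdefault(b, []).append(v)
    return bins


def sample_null_lcc(
    g: Interactome,
    set_size: int,
    n_samples: int = 1000,
    scheme: str = "uniform",
    rng_seed: int = 0,
    *,
    degree_reference: Sequence[int] | None = None,
) -> NullDistribution:
    """Draw random node sets and record each induced-subgraph LCC size.

    ``uniform`` draws ``set_size`` nodes without replacement;
    ``degree_matched`` draws, for each degree in ``degree_reference`` (the
    observed module's degree profile), a node from the matching log2 degree
    bin, without replacement within a sample. Reproducible from
    ``rng_seed``.
    """
    if not (1 <= set_size <= g.N):
        raise ValueError(f"set_size must be in [1, N={g.N}], got {set_size}")
    if n_samples < 2:
        raise ValueError("n_samples must be >= 2")
    rng = np.random.default_rng(rng_seed)
    nodes = sorted(g.nodes)
    sizes: list[int] = []
    if scheme == "uniform":
        idx = np.arange(len(nodes))
        for _ in range(n_samples):
            pick = rng.choice(idx, size=set_size, replace=False)
            sizes.append(g.induced_lcc_size((nodes[i] for i in pick), validate=False))
    elif scheme == "degree_matched":
        if degree_reference is None:
            raise ValueError("degree_matched sampling needs a reference degree profile")
        if len(degree_reference) != set_size:
            raise ValueError("degree_reference length must equal set_size")
        bins = _degree_bins(g)
        bin_keys = sorted(bins)
        ref_bins = [
            -1 if d == 0 else int(math.log2(d)) for d in degree_reference
        ]
        for _ in range(n_samples):
            chosen: set[str] = set()
            for b in ref_bins:
                # widen to neighbouring bins when the target bin is used up
                for width in range(0, len(bin_keys) + 1):
                    pool = [
                        v
                        for key in bin_keys
                        if abs(key - b) <= width
                        for v in bins[key]
                        if v not in chosen
                    ]
                    if pool:
                        chosen.add(pool[int(rng.integers(len(pool)))])
                        break
                else:  # pragma: no cover - only if set_size > N
                    raise RuntimeError("exhausted all degree bins")
            sizes.append(g.induced_lcc_size(chosen, validate=False))
    else:
        raise ValueError(f"unknown sampling scheme: {scheme!r}")
    return NullDistribution(
        set_size=set_size,
        n_samples=n_samples,
        lcc_sizes=tuple(sizes),
        rng_seed=rng_seed,
        scheme=scheme,
    )


def z_score(observed: float, null: NullDistribution) -> float:
    """``(observed - mean) / sd``; sd = 0 maps to +inf / 0 / -inf by sign."""
    mean, sd = null.mean, null.sd
    if sd == 0.0:
        if observed > mean:
            return math.inf
        if observed < mean:
            return -math.inf
        return 0.0
    return (observed - mean) / sd


@dataclass(frozen=True)
class TrajectoryPoint:
    """One module size with its observed LCC and null comparison."""

    size: int
    observed_lcc: int
    null_mean: float
    null_sd: float
    z: float
    all_seeds_integrated: bool


@dataclass
class ModuleResult:
    """Final module membership plus the full z-score trajectory."""

    seeds: frozenset[str]
    added: tuple[str, ...]  # prefix retained in the final module
    trace: DiamondTrace
    final_size: int | None
    z_trajectory: list[TrajectoryPoint]
    all_seeds_integrated_at: int | None
    termination_reason: str  # criterion_met | max_iterations | exhausted
    excluded_seeds: tuple[str, ...]
    scheme: str
    statistic: str
    z_threshold: float
    n_samples: int
    rng_seed: int
    interactome_checksum: str

    @property
    def members(self) -> set[str]:
        return set(self.seeds) | set(self.added)

    @property
    def final_z(self) -> float | None:
        if self.final_size is None:
            return None
        for pt in self.z_trajectory:
            if pt.size == self.final_size:
                return pt.z
        return None

    def role_of(self, protein: str) -> str:
        if protein in self.seeds:
            return "seed"
        if protein in set(self.added):
            return "added"
        raise KeyError(f"{protein!r} not a module member")

    def members_frame(self) -> pd.DataFrame:
        """Members as a table: seeds (iteration 0) then additions in order."""
        iter_of = {s.protein_id: s.iteration for s in self.trace.steps}
        rows = [(p, "seed", 0) for p in sorted(self.seeds)] + [
            (p, "added", iter_of[p]) for p in self.added
        ]
        return pd.DataFrame(rows, columns=["protein_id", "role", "iteration"])

    def trajectory_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "size": [p.size for p in self.z_trajectory],
                "lcc": [p.observed_lcc for p in self.z_trajectory],
                "null_mean": [p.null_mean for p in self.z_trajectory],
                "null_sd": [p.null_sd for p in self.z_trajectory],
                "z": [p.z for p in self.z_trajectory],
                "all_seeds_integrated": [
                    p.all_seeds_integrated for p in self.z_trajectory
                ],
            }
        )


def _reachable_seeds(g: Interactome, seeds: frozenset[str]) -> tuple[frozenset[str], tuple[str, ...]]:
    """Drop stray seeds that can never join the bulk of the seed set.

    Seeds outside the interactome component holding a strict majority of
    the seeds are unreachable from the rest and are excluded from the
    integration criterion (logged). Without a strict majority nothing is
    excluded — integration is then simply impossible and the trajectory
    records that.
    """
    import networkx as nx

    comp_of: dict[str, int] = {}
    for i, comp in enumerate(nx.connected_components(g.graph)):
        for v in comp:
            comp_of[v] = i
    counts: dict[int, int] = {}
    for s in seeds:
        counts[comp_of[s]] = counts.get(comp_of[s], 0) + 1
    majority = max(sorted(counts), key=lambda c: counts[c])
    if 2 * counts[majority] <= len(seeds) and len(counts) > 1:
        return seeds, ()
    kept = frozenset(s for s in seeds if comp_of[s] == majority)
    excluded = tuple(sorted(seeds - kept))
    if excluded:
        log.warning(
            "%d seed(s) lie outside the interactome component holding the "
            "majority of seeds and are excluded from the integration "
            "criterion: %s", len(excluded), ", ".join(excluded[:10]),
        )
    return kept, excluded


def _observed_statistic(
    g: Interactome, members: set[str], eligible_seeds: frozenset[str], statistic: str
) -> tuple[int, bool]:
    """Observed module-size statistic and the all-seeds-integrated flag."""
    lcc_members = g.induced_lcc_members(members)
    integrated = bool(eligible_seeds) and eligible_seeds <= lcc_members
    if statistic == "full_module":
        return len(lcc_members), integrated
    if statistic == "seeds_only":
        # seeds reachable from one another through the candidate module
        adj = g.adjacency()
        best = 0
        unvisited = set(members)
        while unvisited:
            root = unvisited.pop()
            comp = {root}
            frontier = [root]
            while frontier:
                nxt = set()
                for v in frontier:
                    nxt |= adj[v] & unvisited
                unvisited -= nxt
                comp |= nxt
                frontier = list(nxt)
            best = max(best, len(comp & eligible_seeds))
        return best, integrated
    raise ValueError(f"unknown statistic: {statistic!r}")


def determine_final_module(
    g: Interactome,
    seeds: SeedSet | Iterable[str],
    trace: DiamondTrace,
    z_threshold: float = 1.96,
    n_samples: int = 1000,
    scheme: str = "uniform",
    rng_seed: int = 0,
    *,
    statistic: str = "full_module",
) -> ModuleResult:
    """Walk the growth trace and apply the break-off criterion.

    For every prefix of the trace, the observed LCC of seeds + prefix is
    compared to the null distribution of random same-size node sets; the
    smallest size at which all (reachable) seeds sit in one connected
    component of the module *and* z exceeds ``z_threshold`` is the final
    size. The full trajectory is always returned so both readings of the
    criterion can be inspected.
    """
    seed_set = frozenset(seeds.proteins if isinstance(seeds, SeedSet) else seeds)
    if not seed_set:
        raise ValueError("seed set is empty")
    if statistic not in ("full_module", "seeds_only"):
        raise ValueError(f"unknown statistic: {statistic!r}")
    eligible, excluded = _reachable_seeds(g, seed_set)

    trajectory: list[TrajectoryPoint] = []
    final_size: int | None = None
    final_prefix = 0
    integrated_at: int | None = None
    degree_profile_cache: list[int] | None = None
    for n_added in range(0, len(trace.steps) + 1):
        members = trace.members_at(n_added)
        size = len(members)
        observed, integrated = _observed_statistic(g, members, eligible, statistic)
        if scheme == "degree_matched":
            degree_profile_cache = sorted(g.degree(v) for v in members)
        null = sample_null_lcc(
            g,
            size,
            n_samples=n_samples,
            scheme=scheme,
            rng_seed=_child_seed(rng_seed, size),
            degree_reference=degree_profile_cache,
        )
        z = z_score(observed, null)
        trajectory.append(
            TrajectoryPoint(size, observed, null.mean, null.sd, z, integrated)
        )
        if integrated and integrated_at is None:
            integrated_at = size
        if final_size is None and integrated and z > z_threshold:
            final_size = size
            final_prefix = n_added

    if final_size is not None:
        reason = "criterion_met"
        added = tuple(trace.added[:final_prefix])
    else:
        reason = "exhausted" if trace.exhausted else "max_iterations"
        added = tuple(trace.added)
    return ModuleResult(
        seeds=seed_set,
        added=added,
        trace=trace,
        final_size=final_size,
        z_trajectory=trajectory,
        all_seeds_integrated_at=integrated_at,
        termination_reason=reason,
        excluded_seeds=excluded,
        scheme=scheme,
        statistic=statistic,
        z_threshold=z_threshold,
        n_samples=n_samples,
        rng_seed=rng_seed,
        interactome_checksum=g.checksum(),
    )
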