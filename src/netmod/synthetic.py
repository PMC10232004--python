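"""Synthetic interactomes, planted modules, seeds, and differential tables.

Everything downstream of raw data acquisition can be exercised on
generated fixtures with known ground truth: a scale-free-like (preferential
attachment) or homogeneous (Erdős–Rényi) base graph, one or two planted
densely connected modules, seed lists drawn from the planted members with
optional contamination, and a differential protein table whose strongly
regulated annotated rows are exactly those seeds.

Noise model of the table: seed proteins carry log2 ratios drawn from a
shifted normal (mean +2 or −2, sd 0.5, magnitude clipped to at least 1.2);
all other proteins are background, normal(0, 0.3) clipped to |r| < 0.9.
With the default selection threshold of 1.0 this separates seeds from
background with certainty, which is what makes the construction oracle
exact. Planted members (and a small fraction of background) carry the
"lysosome" annotation flag.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .interactome import Interactome

__all__ = [
    "SyntheticConfig",
    "GroundTruth",
    "generate_interactome",
    "generate_differential_table",
    "write_differential_table",
]

#: annotation flag attached to planted members (emulating lysosome enrichment)
ANNOTATION = "lysosome"


@dataclass(frozen=True)
class SyntheticConfig:
    """Parameters of one synthetic study.

    ``base`` picks the graph family: ``preferential_attachment`` (scale-free
    degree heterogeneity, ``attachment_m`` edges per new node) or
    ``erdos_renyi`` (homogeneous, edge probability ``er_p``).
    ``n_modules`` plants one module (up-regulated) or two (up and down)
    sharing ``overlap`` proteins; intra-module edges are added with
    probability ``planted_p``. ``contamination`` is the fraction of seeds
    replaced by random non-planted nodes.
    """

    n_nodes: int = 2000
    base: str = "preferential_attachment"
    attachment_m: int = 4
    er_p: float = 0.01
    planted_size: int = 50
    planted_p: float = 0.3
    n_seeds: int = 10
    contamination: float = 0.0
    n_modules: int = 1
    overlap: int = 0
    background_flag_rate: float = 0.05
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_nodes < 1:
            raise ValueError("n_nodes must be >= 1")
        if self.base not in ("preferential_attachment", "erdos_renyi"):
            raise ValueError(f"unknown base graph family: {self.base!r}")
        if not (0 <= self.planted_size <= self.n_nodes):
            raise ValueError("planted_size must be in [0, n_nodes]")
        if not (0 <= self.n_seeds <= self.planted_size or self.planted_size == 0 and self.n_seeds == 0):
            raise ValueError("n_seeds must be <= planted_size")
        for name in ("er_p", "planted_p", "contamination", "background_flag_rate"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.n_modules not in (1, 2):
            raise ValueError("n_modules must be 1 or 2")
        if self.n_modules == 2:
            if self.overlap > self.planted_size:
                raise ValueError("overlap must be <= planted_size")
            if 2 * self.planted_size - self.overlap > self.n_nodes:
                raise ValueError("two planted modules do not fit in n_nodes")
        elif self.overlap:
            raise ValueError("overlap requires n_modules=2")


@dataclass(frozen=True)
class GroundTruth:
    """What was planted: module memberships, seed lists, overlap."""

    planted_up: frozenset[str]
    planted_down: frozenset[str]
    seeds_up: tuple[str, ...]
    seeds_down: tuple[str, ...]
    overlap: frozenset[str]

    def to_json(self, path) -> None:
        payload = {
            "planted_up": sorted(self.planted_up),
            "planted_down": sorted(self.planted_down),
            "seeds_up": list(self.seeds_up),
            "seeds_down": list(self.seeds_down),
            "overlap": sorted(self.overlap),
        }
        Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")

    @classmethod
    def from_json(cls, path) -> "GroundTruth":
        d = json.loads(Path(path).read_text())
        return cls(
            planted_up=frozenset(d["planted_up"]),
            planted_down=frozenset(d["planted_down"]),
            seeds_up=tuple(d["seeds_up"]),
            seeds_down=tuple(d["seeds_down"]),
            overlap=frozenset(d["overlap"]),
        )


def _node_name(i: int) -> str:
    return f"P{i:05d}"


def _rng(cfg: SyntheticConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence(entropy=cfg.rng_seed, spawn_key=(stream,))
    )


def _base_graph(cfg: SyntheticConfig) -> nx.Graph:
    seed = int(_rng(cfg, 0).integers(2**31))
    n = cfg.n_nodes
    if n == 1:
        g = nx.Graph()
        g.add_node(0)
        return g
    if cfg.base == "preferential_attachment":
        m = min(cfg.attachment_m, n - 1)
        return nx.barabasi_albert_graph(n, m, seed=seed)
    return nx.gnp_random_graph(n, cfg.er_p, seed=seed)


def _densify(g: nx.Graph, members: list[str], p: float, rng: np.random.Generator) -> None:
    for a, b in itertools.combinations(sorted(members), 2):
        if rng.random() < p:
            g.add_edge(a, b)


def _draw_seeds(
    planted: list[str],
    all_nodes: list[str],
    planted_any: set[str],
    cfg: SyntheticConfig,
    rng: np.random.Generator,
) -> tuple[str, ...]:
    seeds = list(rng.choice(planted, size=cfg.n_seeds, replace=False))
    n_contam = int(round(cfg.contamination * cfg.n_seeds))
    if n_contam:
        outside = sorted(set(all_nodes) - planted_any)
        replacements = rng.choice(outside, size=n_contam, replace=False)
        seeds[:n_contam] = list(replacements)
    return tuple(sorted(seeds))


def generate_interactome(cfg: SyntheticConfig) -> tuple[Interactome, GroundTruth]:
    """Build the synthetic interactome with planted module(s) and seeds.

    Fully reproducible from ``cfg.rng_seed``; the planted modules are
    densified with intra-member edge probability ``planted_p`` on top of
    the base graph.
    """
    base = _base_graph(cfg)
    g = nx.relabel_nodes(base, {i: _node_name(i) for i in base.nodes}, copy=True)
    nodes = sorted(g.nodes)

    rng = _rng(cfg, 1)
    planted_up: list[str] = []
    planted_down: list[str] = []
    overlap: set[str] = set()
    if cfg.planted_size:
        planted_up = sorted(rng.choice(nodes, size=cfg.planted_size, replace=False))
        if cfg.n_modules == 2:
            overlap = set(rng.choice(planted_up, size=cfg.overlap, replace=False)) if cfg.overlap else set()
            rest_pool = sorted(set(nodes) - set(planted_up))
            fresh = rng.choice(rest_pool, size=cfg.planted_size - len(overlap), replace=False)
            planted_down = sorted(set(fresh) | overlap)
        _densify(g, planted_up, cfg.planted_p, rng)
        if planted_down:
            _densify(g, planted_down, cfg.planted_p, rng)

    seed_rng = _rng(cfg, 2)
    planted_any = set(planted_up) | set(planted_down)
    seeds_up: tuple[str, ...] = ()
    seeds_down: tuple[str, ...] = ()
    if cfg.n_seeds and planted_up:
        # seeds for the down module are drawn outside the overlap so the two
        # directions stay disjoint in the differential table
        seeds_up = _draw_seeds(planted_up, nodes, planted_any, cfg, seed_rng)
        if cfg.n_modules == 2:
            down_pool = sorted(set(planted_down) - overlap - set(seeds_up))
            seeds_down = _draw_seeds(down_pool, nodes, planted_any | set(seeds_up), cfg, seed_rng)

    truth = GroundTruth(
        planted_up=frozenset(planted_up),
        planted_down=frozenset(planted_down),
        seeds_up=seeds_up,
        seeds_down=seeds_down,
        overlap=frozenset(overlap),
    )
    return Interactome(g), truth


def generate_differential_table(cfg: SyntheticConfig, truth: GroundTruth) -> pd.DataFrame:
    """Emit the differential protein table matching the planted ground truth.

    Seed proteins get strong shifted-normal ratios with the sign of their
    direction; everything else is clipped background noise. Planted
    members and all seeds carry the annotation flag, plus a
    ``background_flag_rate`` fraction of background rows.
    """
    rng = _rng(cfg, 3)
    nodes = [_node_name(i) for i in range(cfg.n_nodes)]
    ratios = np.clip(rng.normal(0.0, 0.3, size=len(nodes)), -0.9, 0.9)
    df = pd.DataFrame({"protein_id": nodes, "log_ratio": ratios})
    idx = {v: i for i, v in enumerate(nodes)}

    for seed_list, sign in ((truth.seeds_up, +1.0), (truth.seeds_down, -1.0)):
        if seed_list:
            mags = np.maximum(rng.normal(2.0, 0.5, size=len(seed_list)), 1.2)
            for p, m in zip(seed_list, mags):
                df.loc[idx[p], "log_ratio"] = sign * m

    flagged = set(truth.planted_up) | set(truth.planted_down)
    flagged |= set(truth.seeds_up) | set(truth.seeds_down)
    n_bg_flags = int(round(cfg.background_flag_rate * (len(nodes) - len(flagged))))
    if n_bg_flags:
        background = sorted(set(nodes) - flagged)
        flagged |= set(rng.choice(background, size=n_bg_flags, replace=False))
    df[ANNOTATION] = df["protein_id"].isin(flagged).astype(int)
    return df


def write_differential_table(df: pd.DataFrame, path) -> None:
    out = df.copy()
    out["log_ratio"] = out["log_ratio"].map(lambda r: f"{r:.6f}")
    out.to_csv(path, sep="\t", index=False)
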