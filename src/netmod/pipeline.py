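"""End-to-end orchestration: seeds → growth → break-off → connectors.

`run_pipeline` executes the two directional module growths (up- and
down-regulated seeds), intersects the final modules, and writes a report
bundle with fixed filenames into the output directory:

    members_up.tsv / members_down.tsv      module membership with roles
    trajectory_up.tsv / trajectory_down.tsv  z-score trajectories
    connectors.tsv                         ranked shared-protein summary
    union_subgraph.tsv                     edges among the module union
    run.json                               machine-readable run metadata
    summary.txt                            human-readable run summary

All randomness flows from one configured ``rng_seed``; per-stage streams
are split deterministically, so two runs with the same config are
byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import yaml

from . import connectors as conn
from .interactome import Interactome, load_edge_list
from .model import DiamondModule, DiamondModuleResults
from .seeds import read_differential_table

__all__ = ["RunConfig", "RunBundle", "run_pipeline"]

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Everything a pipeline run needs; loadable from YAML."""

    interactome: str
    table: str
    outdir: str
    dialect: str = "tsv"
    header: bool = False
    annotation: str = "lysosome"
    threshold: float = 0.0
    top_k: int | None = None
    max_added: int | None = None  # default: 2*s + 100 per direction
    z_threshold: float = 1.96
    n_samples: int = 1000
    scheme: str = "uniform"
    population: str = "all_nodes"
    statistic: str = "full_module"
    always_include: list[str] = field(default_factory=list)
    rng_seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(data) - {f for f in cls.__dataclass_fields__}
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class RunBundle:
    """In-memory handle on a finished run."""

    config: RunConfig
    up: DiamondModuleResults
    down: DiamondModuleResults
    report: conn.ConnectorReport
    outdir: Path


def _stage_seed(base: int, stage: int) -> int:
    ss = np.random.SeedSequence(entropy=base, spawn_key=(1000 + stage,))
    return int(ss.generate_state(1)[0]) & 0x7FFFFFFF


def _fit_direction(
    g: Interactome, table, cfg: RunConfig, direction: str, stage: int
) -> DiamondModuleResults:
    model = DiamondModule.from_differential_table(
        g,
        table,
        annotation=cfg.annotation,
        direction=direction,
        top_k=cfg.top_k,
        threshold=cfg.threshold,
        population=cfg.population,
        always_include=cfg.always_include,
    )
    log.info("%s: %d seeds (%d dropped)", direction, model.seeds.s, len(model.seeds.dropped))
    return model.fit(
        max_added=cfg.max_added,
        z_threshold=cfg.z_threshold,
        n_samples=cfg.n_samples,
        scheme=cfg.scheme,
        statistic=cfg.statistic,
        rng_seed=_stage_seed(cfg.rng_seed, stage),
    )


def _write_tsv(df, path: Path, float_cols: dict[str, str] = {}) -> None:
    out = df.copy()
    for col, fmt in float_cols.items():
        out[col] = out[col].map(lambda v: fmt % v)
    out.to_csv(path, sep="\t", index=False)


def run_pipeline(cfg: RunConfig) -> RunBundle:
    """Execute the full two-module analysis and write the report bundle."""
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    try:
        g, load_report = load_edge_list(cfg.interactome, cfg.dialect, header=cfg.header)
    except Exception as e:
        raise RuntimeError(
            f"stage interactome_io failed: {e} "
            "(check the edge-list path, dialect and header flag)"
        ) from e
    try:
        table = read_differential_table(cfg.table)
    except Exception as e:
        raise RuntimeError(
            f"stage seed_selection failed while reading the table: {e} "
            "(the table needs protein_id and log_ratio columns)"
        ) from e

    results: dict[str, DiamondModuleResults] = {}
    for stage, direction in enumerate(("up", "down"), start=1):
        try:
            results[direction] = _fit_direction(g, table, cfg, direction, stage)
        except Exception as e:
            raise RuntimeError(
                f"stage module_growth[{direction}] failed: {e} "
                "(check annotation/threshold produce non-empty seed sets)"
            ) from e

    # the connector step must see the same population the fits used
    g_used = results["up"].model.interactome
    report = conn.build_connector_report(g_used, results["up"].result, results["down"].result)

    traj_fmt = {"null_mean": "%.4f", "null_sd": "%.4f", "z": "%.4f"}
    for direction in ("up", "down"):
        r = results[direction]
        _write_tsv(r.members_frame(), outdir / f"members_{direction}.tsv")
        _write_tsv(r.trajectory, outdir / f"trajectory_{direction}.tsv", traj_fmt)
    _write_tsv(report.to_frame(), outdir / "connectors.tsv")
    conn.write_union_subgraph(g_used, results["up"].result, results["down"].result,
                              outdir / "union_subgraph.tsv")

    meta = {
        "config": asdict(cfg),
        "config_hash": cfg.config_hash(),
        "interactome_checksum": g_used.checksum(),
        "load_report": asdict(load_report),
        "rng_seed": cfg.rng_seed,
        "modules": {
            d: {
                "n_seeds": results[d].model.seeds.s,
                "seeds_dropped": list(results[d].model.seeds.dropped),
                "final_size": results[d].final_size,
                "final_z": results[d].final_z,
                "termination_reason": results[d].termination_reason,
                "all_seeds_integrated_at": results[d].result.all_seeds_integrated_at,
            }
            for d in ("up", "down")
        },
        "n_shared_proteins": len(report.shared_proteins),
    }
    (outdir / "run.json").write_text(json.dumps(meta, indent=2, sort_keys=True) + "\n")

    summary = "\n\n".join(
        [
            "PIPELINE RUN SUMMARY",
            f"config hash: {cfg.config_hash()}\n"
            f"interactome checksum: {g_used.checksum()}\n"
            f"rng seed: {cfg.rng_seed}\n"
            f"conventions: population={cfg.population} scheme={cfg.scheme} "
            f"statistic={cfg.statistic} z_threshold={cfg.z_threshold} "
            f"n_samples={cfg.n_samples}",
            "=== UP module ===\n" + results["up"].summary(),
            "=== DOWN module ===\n" + results["down"].summary(),
            f"=== Connectors ===\nshared proteins: {len(report.shared_proteins)}\n"
            + report.to_frame().to_string(index=False),
            "",
        ]
    )
    (outdir / "summary.txt").write_text(summary)

    return RunBundle(config=cfg, up=results["up"], down=results["down"],
                     report=report, outdir=outdir)
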