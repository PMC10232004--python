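"""Model/Results interface for disease-module detection.

:class:`DiamondModule` bundles the data (interactome + seed set) with the
modelling conventions; :meth:`DiamondModule.fit` runs the growth and the
z-score break-off and returns a :class:`DiamondModuleResults` carrying the
module membership, the z trajectory, and a ``summary()`` table.

Example
-------
>>> from netmod import synthetic, model
>>> g, truth = synthetic.generate_interactome(synthetic.SyntheticConfig(rng_seed=3))
>>> mod = model.DiamondModule(g, truth.seeds_up)
>>> res = mod.fit(max_added=40, n_samples=200, rng_seed=3)
>>> res.final_size is not None
True
"""

from __future__ import annotations

from typing import Iterable, Sequence

import pandas as pd

from . import diamond, termination
from .interactome import Interactome
from .seeds import SeedSet, restrict_to_interactome, select_seed_proteins
from .termination import ModuleResult


class DiamondModule:
    """Disease-module growth model for one directional seed set.

    Parameters
    ----------
    interactome : Interactome
        The protein–protein interaction graph (the statistical population).
    seeds : SeedSet or iterable of str
        Seed proteins; identifiers missing from the interactome are
        dropped with a warning.
    population : {"all_nodes", "interactome_lcc"}
        Whether the hypergeometric population counts every node or only
        the interactome's own largest connected component.
    always_include : sequence of str
        Proteins pinned into the module before growth (not seeds).
    """

    def __init__(
        self,
        interactome: Interactome,
        seeds: SeedSet | Iterable[str],
        *,
        population: str = "all_nodes",
        always_include: Sequence[str] = (),
    ) -> None:
        if population not in ("all_nodes", "interactome_lcc"):
            raise ValueError(f"unknown population convention: {population!r}")
        if population == "interactome_lcc":
            keep = interactome.lcc_nodes()
            interactome = Interactome(interactome.graph.subgraph(keep).copy())
        self.interactome = interactome
        if not isinstance(seeds, SeedSet):
            seeds = SeedSet(direction="up", proteins=frozenset(seeds))
        self.seeds = restrict_to_interactome(seeds, interactome)
        self.population = population
        self.always_include = tuple(always_include)

    @classmethod
    def from_differential_table(
        cls,
        interactome: Interactome,
        table: pd.DataFrame,
        *,
        annotation: str,
        direction: str,
        top_k: int | None = None,
        threshold: float = 0.0,
        **kwargs,
    ) -> "DiamondModule":
        """Build the model straight from a differential protein table."""
        seeds = select_seed_proteins(
            table, annotation=annotation, direction=direction,
            top_k=top_k, threshold=threshold,
        )
        return cls(interactome, seeds, **kwargs)

    @property
    def default_max_added(self) -> int:
        """Growth budget: 2·s + 100 additions."""
        return 2 * self.seeds.s + 100

    def fit(
        self,
        max_added: int | None = None,
        z_threshold: float = 1.96,
        n_samples: int = 1000,
        scheme: str = "uniform",
        statistic: str = "full_module",
        rng_seed: int = 0,
    ) -> "DiamondModuleResults":
        """Grow the module and apply the z-score break-off criterion."""
        trace = diamond.grow_module(
            self.interactome,
            self.seeds,
            max_added if max_added is not None else self.default_max_added,
            always_include=self.always_include,
        )
        result = termination.determine_final_module(
            self.interactome,
            self.seeds,
            trace,
            z_threshold=z_threshold,
            n_samples=n_samples,
            scheme=scheme,
            rng_seed=rng_seed,
            statistic=statistic,
        )
        return DiamondModuleResults(self, result)


class DiamondModuleResults:
    """Fitted module: membership, trajectory, and diagnostics."""

    def __init__(self, model: DiamondModule, result: ModuleResult) -> None:
        self.model = model
        self.result = result

    # convenience pass-throughs ---------------------------------------
    @property
    def members(self) -> set[str]:
        return self.result.members

    @property
    def final_size(self) -> int | None:
        return self.result.final_size

    @property
    def final_z(self) -> float | None:
        return self.result.final_z

    @property
    def termination_reason(self) -> str:
        return self.result.termination_reason

    @property
    def trajectory(self) -> pd.DataFrame:
        return self.result.trajectory_frame()

    def members_frame(self) -> pd.DataFrame:
        return self.result.members_frame()

    def summary(self) -> str:
        """Human-readable report of the fit and every convention in force."""
        r = self.result
        g = self.model.interactome
        lines = [
            "      Disease Module Growth (DIAMOnD)",
            "=" * 54,
            f"Interactome nodes (N)    {g.N:>10d}",
            f"Interactome edges        {g.n_edges:>10d}",
            f"Interactome checksum     {r.interactome_checksum:>16s}",
            f"Seeds (s)                {self.model.seeds.s:>10d}  [{self.model.seeds.direction}]",
            f"Seeds dropped            {len(self.model.seeds.dropped):>10d}",
            f"Seeds excluded           {len(r.excluded_seeds):>10d}",
            f"Population convention    {self.model.population:>16s}",
            f"Sampling scheme          {r.scheme:>16s}",
            f"Statistic                {r.statistic:>16s}",
            f"Null samples             {r.n_samples:>10d}",
            f"z threshold              {r.z_threshold:>10.2f}",
            f"rng seed                 {r.rng_seed:>10d}",
            "-" * 54,
            f"Termination              {r.termination_reason:>16s}",
            f"Final module size        "
            + (f"{r.final_size:>10d}" if r.final_size is not None else "      none"),
            f"z at final size          "
            + (f"{r.final_z:>10.2f}" if r.final_z is not None else "      none"),
            f"All seeds integrated at  "
            + (
                f"{r.all_seeds_integrated_at:>10d}"
                if r.all_seeds_integrated_at is not None
                else "     never"
            ),
            f"Proteins added           {len(r.added):>10d}",
            "=" * 54,
        ]
        head = self.members_frame().head(15)
        lines.append("First members (seeds, then additions in order):")
        lines.append(head.to_string(index=False))
        return "\n".join(lines)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"<DiamondModuleResults final_size={self.final_size} "
            f"reason={self.termination_reason}>"
        )
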