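"""Seed-protein selection from a differential protein-abundance table.

Seeds are the differentially abundant proteins (e.g. lysosome-annotated
SILAC hits, as log2 KO/WT ratios) from which module growth starts. Up- and
down-regulated proteins form separate seed sets and grow separate modules.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .interactome import Interactome

__all__ = [
    "SeedSet",
    "read_differential_table",
    "validate_differential_table",
    "select_seed_proteins",
    "restrict_to_interactome",
]

log = logging.getLogger(__name__)

#: mandatory columns of a differential protein table
REQUIRED_COLUMNS = ("protein_id", "log_ratio")


@dataclass(frozen=True)
class SeedSet:
    """A directional set of seed proteins.

    ``dropped`` lists identifiers removed because they are absent from the
    interactome (populated by :func:`restrict_to_interactome`).
    """

    direction: str  # "up" or "down"
    proteins: frozenset[str]
    dropped: tuple[str, ...] = ()

    @property
    def s(self) -> int:
        return len(self.proteins)

    def __post_init__(self) -> None:
        if self.direction not in ("up", "down"):
            raise ValueError(f"direction must be 'up' or 'down', got {self.direction!r}")


def validate_differential_table(table: pd.DataFrame) -> None:
    """Check required columns, unique protein ids and finite log ratios."""
    missing = [c for c in REQUIRED_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"differential table lacks columns: {missing}")
    dup = table["protein_id"][table["protein_id"].duplicated()]
    if not dup.empty:
        raise ValueError(
            "duplicate protein_id in table: " + ", ".join(map(str, dup.unique()[:5]))
        )
    ratios = pd.to_numeric(table["log_ratio"], errors="coerce")
    if not np.isfinite(ratios.to_numpy(dtype=float)).all():
        raise ValueError("log_ratio contains non-finite or non-numeric values")


def read_differential_table(path, *, sep: str | None = None) -> pd.DataFrame:
    """Read a TSV/CSV differential table and validate it.

    The table needs ``protein_id`` and ``log_ratio`` columns; any further
    boolean (0/1, true/false) columns are treated as annotation flags whose
    flag name is the column name.
    """
    df = pd.read_csv(path, sep=sep, engine="python")
    validate_differential_table(df)
    return df


def select_seed_proteins(
    table: pd.DataFrame,
    annotation: str,
    direction: str,
    top_k: int | None = None,
    threshold: float = 0.0,
) -> SeedSet:
    """Select seed proteins by annotation, direction, and ratio magnitude.

    Keeps rows carrying ``annotation`` (a truthy column of that name),
    filters ``log_ratio > +threshold`` (up) or ``< -threshold`` (down),
    ranks by ``|log_ratio|`` descending with ties broken by lexicographic
    ``protein_id``, and retains the first ``top_k`` rows (``None`` keeps
    all). Selection is fully deterministic.
    """
    if direction not in ("up", "down"):
        raise ValueError(f"direction must be 'up' or 'down', got {direction!r}")
    if top_k is not None and top_k < 1:
        raise ValueError("top_k must be >= 1 or None")
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    validate_differential_table(table)
    if annotation not in table.columns:
        raise ValueError(f"annotation column {annotation!r} not in table")
    flagged = table[table[annotation].astype(bool)]
    if flagged.empty:
        raise ValueError(f"no rows carry annotation {annotation!r}")
    if direction == "up":
        kept = flagged[flagged["log_ratio"] > threshold]
    else:
        kept = flagged[flagged["log_ratio"] < -threshold]
    ranked = kept.assign(_mag=kept["log_ratio"].abs()).sort_values(
        ["_mag", "protein_id"], ascending=[False, True], kind="mergesort"
    )
    if top_k is not None:
        ranked = ranked.head(top_k)
    return SeedSet(direction=direction, proteins=frozenset(ranked["protein_id"]))


def restrict_to_interactome(seed: SeedSet, g: Interactome) -> SeedSet:
    """Intersect a seed set with the interactome's node universe.

    Identifiers absent from the interactome are recorded in ``dropped``
    and a warning is logged; an empty intersection is an error because
    module growth would be impossible.
    """
    present = frozenset(p for p in seed.proteins if p in g)
    dropped = tuple(sorted(seed.proteins - present))
    if dropped:
        log.warning(
            "%d/%d %s-seeds not in interactome, dropped: %s",
            len(dropped), len(seed.proteins), seed.direction,
            ", ".join(dropped[:10]),
        )
    if not present:
        raise ValueError(
            f"no {seed.direction}-seeds remain after interactome restriction"
        )
    return SeedSet(direction=seed.direction, proteins=present, dropped=dropped)
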