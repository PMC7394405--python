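"""Diet composition tables and Schoener dietary overlap.

A diet is summarized as the proportional contribution of each plant
species to the bites of one group (herbivore x camp x season).  Two
contribution scales are supported:

``pooled``
    bites of a species divided by all bites of the group;
``station``
    contributions computed within each feeding station, then averaged with
    equal station weight (robust to stations with very different bite
    counts).

Overlap between two diets j and k uses Schoener's index

    O_jk = 1 - 0.5 * sum_i |P_ij - P_ik|

over the union of species (a species absent from one diet contributes its
full proportion in the other to the divergence).  O is symmetric and lies
in [0, 1]: 0 for disjoint diets, 1 for identical ones.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core_io import SchemaError

SCALES = ("pooled", "station")


@dataclass
class DietTable:
    """Proportional species contributions of one group's diet."""

    group: str
    contributions: pd.Series  # index: species label; values: proportions
    n_bites: int
    scale: str = "pooled"

    def __post_init__(self) -> None:
        if self.scale not in SCALES:
            raise SchemaError(f"scale must be one of {SCALES}")
        self.contributions = self.contributions.astype(float).sort_index()
        if (self.contributions < -1e-12).any():
            raise SchemaError("diet contributions must be non-negative")
        total = float(self.contributions.sum())
        if abs(total - 1.0) > 1e-9:
            raise SchemaError(
                f"diet contributions for {self.group!r} sum to {total}, not 1"
            )

    @property
    def species(self) -> list[str]:
        return [s for s, p in self.contributions.items() if p > 0]


@dataclass(frozen=True)
class OverlapResult:
    group_j: str
    group_k: str
    schoener: float
    species_union: tuple[str, ...]


def from_proportions(
    group: str, proportions: dict[str, float], n_bites: int = 0,
    scale: str = "pooled", normalize: bool = False,
) -> DietTable:
    """Build a :class:`DietTable` from a species -> proportion mapping.

    With ``normalize=True`` the values are rescaled to sum to 1 first
    (useful for published tables whose percentages carry rounding error).
    """
    s = pd.Series(proportions, dtype=float)
    if normalize:
        total = s.sum()
        if total <= 0:
            raise SchemaError("cannot normalize an all-zero diet")
        s = s / total
    return DietTable(group=group, contributions=s, n_bites=n_bites, scale=scale)


def diet_contributions(
    bites: pd.DataFrame, group: str, scale: str = "pooled"
) -> DietTable:
    """Species contributions of one group of bites.

    Parameters
    ----------
    bites
        Bite rows of a single group; needs ``species`` and, for the
        station scale, ``observation_id`` and ``station_index``.
    group
        Label attached to the resulting table.
    scale
        ``"pooled"`` or ``"station"`` (see module docstring).
    """
    if scale not in SCALES:
        raise SchemaError(f"scale must be one of {SCALES}")
    if bites.empty:
        raise SchemaError(f"group {group!r}: no bites")
    n = int(len(bites))
    if scale == "pooled":
        props = bites["species"].value_counts(normalize=True)
    else:
        per_station = (
            bites.groupby(["observation_id", "station_index"])["species"]
            .value_counts(normalize=True)
            .rename("p")
            .reset_index()
        )
        props = (
            per_station.groupby("species")["p"].sum()
            / per_station.groupby(["observation_id", "station_index"]).ngroups
        )
    return DietTable(group=group, contributions=props, n_bites=n, scale=scale)


def top_species(table: DietTable, threshold: float = 0.9) -> list[str]:
    """Smallest set of highest-contribution species exceeding ``threshold``.

    Species are taken in decreasing contribution order, ties broken by
    species label, until the cumulative contribution exceeds the
    threshold.  ``threshold=1.0`` returns every species with a nonzero
    contribution.
    """
    if not 0 < threshold <= 1:
        raise SchemaError("threshold must lie in (0, 1]")
    ordered = table.contributions[table.contributions > 0].sort_index()
    ordered = ordered.sort_values(ascending=False, kind="stable")
    chosen: list[str] = []
    cum = 0.0
    for species, p in ordered.items():
        chosen.append(str(species))
        cum += float(p)
        if cum > threshold or np.isclose(cum, threshold) and threshold == 1.0:
            break
    return chosen


def schoener_overlap(
    table_j: DietTable, table_k: DietTable, renormalize: bool = False
) -> OverlapResult:
    """Schoener's dietary overlap between two diets on the same scale.

    Proportions are aligned over the union of species, absent species
    filled with 0.  With ``renormalize=True`` each table is first rescaled
    to sum to 1 over the union (only relevant for truncated tables).
    """
    if table_j.scale != table_k.scale:
        raise SchemaError(
            f"cannot compare diets on different scales: "
            f"{table_j.scale!r} vs {table_k.scale!r}"
        )
    pj, pk = table_j.contributions.align(table_k.contributions, fill_value=0.0)
    if renormalize:
        pj = pj / pj.sum()
        pk = pk / pk.sum()
    o = 1.0 - 0.5 * float(np.abs(pj.to_numpy() - pk.to_numpy()).sum())
    o = min(max(o, 0.0), 1.0)  # clip floating-point dust at the bounds
    return OverlapResult(
        group_j=table_j.group,
        group_k=table_k.group,
        schoener=o,
        species_union=tuple(pj.index),
    )


@dataclass(frozen=True)
class DietExpansion:
    """Seasonal diet change: overlap plus species turnover."""

    overlap: OverlapResult
    newly_included: tuple[str, ...]  # in the second diet only
    newly_dropped: tuple[str, ...]   # in the first diet only


def diet_expansion(table_wet: DietTable, table_dry: DietTable) -> DietExpansion:
    """Between-season overlap and the species gained/lost from wet to dry."""
    overlap = schoener_overlap(table_wet, table_dry)
    wet, dry = set(table_wet.species), set(table_dry.species)
    return DietExpansion(
        overlap=overlap,
        newly_included=tuple(sorted(dry - wet)),
        newly_dropped=tuple(sorted(wet - dry)),
    )


def overlap_matrix(tables: list[DietTable], renormalize: bool = False) -> pd.DataFrame:
    """Symmetric Schoener overlap matrix for a list of diet tables."""
    labels = [t.group for t in tables]
    mat = pd.DataFrame(np.eye(len(tables)), index=labels, columns=labels)
    for i, tj in enumerate(tables):
        for j in range(i + 1, len(tables)):
            o = schoener_overlap(tj, tables[j], renormalize=renormalize).schoener
            mat.iloc[i, j] = mat.iloc[j, i] = o
    return mat
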