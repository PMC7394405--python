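"""Shared domain types, delimited-text schemas, and configuration loading.

Every stage of the pipeline communicates through plain CSV files (UTF-8,
header row) whose columns carry their units in the name
(``sward_height_cm``, ``bite_mass_g``, ``elapsed_min``).  Range labels such
as the Walker greenness classes use the ASCII hyphen (``"1-10"``) in files
so the files are bit-stable across locales.

The record types mirror the atoms of a cattle/antelope foraging field
study:

* :class:`CampConfig` — a fenced grazing area with its cattle numbers;
  :func:`stocking_rate` turns this into hectares per animal unit.
* :class:`QuadratRecord` — one transect quadrat (sward height + greenness).
* :class:`BiteRecord` / :class:`ForagingObservation` — individual bites
  grouped into five-feeding-station observations.
* :class:`SwardSeries` — one marked grass sward measured every few days,
  with its defoliation (grazing or clipping) events.
* :class:`NutrientProfile` — crude protein / digestibility of a species in
  a greenness class.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger("grazekit")

# Walker's eight-point percentage-green scale, in increasing order.
WALKER_CLASSES: tuple[str, ...] = (
    "0", "1-10", "11-25", "26-50", "51-75", "76-90", "91-99", "100",
)

# Four-bin greenness categories, from brownest to greenest.
GREENNESS4: tuple[str, ...] = (
    "very brown", "mainly brown", "mainly green", "very green",
)

SEASONS: tuple[str, ...] = ("wet", "dry")
HERBIVORES: tuple[str, ...] = ("oribi", "cattle")

#: Animal-unit equivalents: one adult beef cow (~650 kg) is one AU,
#: a heifer counts as 0.7 AU.
COW_AU = 1.0
HEIFER_AU = 0.7


class SchemaError(ValueError):
    """A table or record violates its schema (bad label, sign, or column)."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CampConfig:
    """One fenced grazing camp in one season."""

    camp_id: str
    area_ha: float
    n_cows: int
    n_heifers: int
    season: str

    def __post_init__(self) -> None:
        if self.area_ha <= 0:
            raise SchemaError(f"camp {self.camp_id!r}: area_ha must be > 0")
        if self.n_cows < 0 or self.n_heifers < 0:
            raise SchemaError(f"camp {self.camp_id!r}: animal counts must be >= 0")
        if int(self.n_cows) != self.n_cows or int(self.n_heifers) != self.n_heifers:
            raise SchemaError(f"camp {self.camp_id!r}: animal counts must be integers")
        if self.season not in SEASONS:
            raise SchemaError(f"camp {self.camp_id!r}: season must be one of {SEASONS}")


def animal_units(config: CampConfig) -> float:
    """Total animal units in a camp (cows at 1.0 AU, heifers at 0.7 AU)."""
    return config.n_cows * COW_AU + config.n_heifers * HEIFER_AU


def stocking_rate(config: CampConfig) -> float:
    """Stocking rate as land area per animal unit (ha/AU).

    Lower values mean denser stocking.  Raises :class:`SchemaError` for a
    camp with no animals (the rate is undefined, not infinite-by-fiat).
    """
    au = animal_units(config)
    if au <= 0:
        raise SchemaError(
            f"camp {config.camp_id!r} has zero animal units: stocking rate undefined"
        )
    return config.area_ha / au


@dataclass(frozen=True)
class QuadratRecord:
    """One 0.4 m^2 transect quadrat: sward height plus Walker greenness."""

    camp_id: str
    season: str
    month: str
    transect_id: str
    position_m: float
    sward_height_cm: float
    greenness_pct_class: str

    def __post_init__(self) -> None:
        if self.position_m < 0:
            raise SchemaError("position_m must be >= 0")
        if self.sward_height_cm <= 0:
            raise SchemaError("sward_height_cm must be > 0")
        if self.greenness_pct_class not in WALKER_CLASSES:
            raise SchemaError(
                f"unknown Walker greenness class {self.greenness_pct_class!r}"
            )


@dataclass(frozen=True)
class BiteRecord:
    """One recorded bite within a feeding station."""

    observation_id: str
    station_index: int
    species: str
    greenness4: str
    sward_height_cm: float
    bite_mass_g: float

    def __post_init__(self) -> None:
        if not 1 <= self.station_index <= 5:
            raise SchemaError("station_index must be in 1..5")
        if self.greenness4 not in GREENNESS4:
            raise SchemaError(f"unknown greenness bin {self.greenness4!r}")
        if self.sward_height_cm <= 0:
            raise SchemaError("sward_height_cm must be > 0")
        if self.bite_mass_g < 0:
            raise SchemaError("bite_mass_g must be >= 0")


@dataclass
class ForagingObservation:
    """Five consecutive feeding stations of one animal: the intake-rate unit."""

    observation_id: str
    camp_id: str
    herbivore: str
    season: str
    total_bites: int
    elapsed_min: float
    bites: list[BiteRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.herbivore not in HERBIVORES:
            raise SchemaError(f"unknown herbivore {self.herbivore!r}")
        if self.season not in SEASONS:
            raise SchemaError(f"season must be one of {SEASONS}")
        if self.total_bites <= 0:
            raise SchemaError("total_bites must be > 0")
        if self.elapsed_min <= 0:
            raise SchemaError("elapsed_min must be > 0")
        if self.total_bites < len(self.bites):
            raise SchemaError("total_bites must be >= number of attached bites")


@dataclass
class SwardSeries:
    """Height time series of one marked sward plus its defoliation events.

    ``group`` is the camp id for grazed swards or the treatment label
    (e.g. ``"clip-5"``) for clipping-experiment swards.  Defoliation times
    are known exactly for clipped swards and are event times for simulated
    grazed swards; for real grazed swards the list may be empty.
    """

    sward_id: str
    group: str
    days: list[float]
    heights_cm: list[float]
    defoliation_days: list[float] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.days) != len(self.heights_cm):
            raise SchemaError("days and heights_cm must have equal length")
        if len(self.days) < 2:
            raise SchemaError("a sward series needs at least two time points")
        if any(b <= a for a, b in zip(self.days, self.days[1:])):
            raise SchemaError("days must be strictly increasing")
        if any(h <= 0 for h in self.heights_cm):
            raise SchemaError("heights must be positive")
        self.defoliation_days = sorted(self.defoliation_days)

    @property
    def initial_height_cm(self) -> float:
        return self.heights_cm[0]

    @property
    def final_height_cm(self) -> float:
        return self.heights_cm[-1]

    @property
    def n_defoliations(self) -> int:
        return len(self.defoliation_days)


@dataclass(frozen=True)
class NutrientProfile:
    """Crude protein and digestibility of one species x greenness bin."""

    species: str
    greenness4: str
    cp_pct: float
    omd_pct: float

    def __post_init__(self) -> None:
        if self.greenness4 not in GREENNESS4:
            raise SchemaError(f"unknown greenness bin {self.greenness4!r}")
        if not 0 <= self.cp_pct <= 100:
            raise SchemaError("cp_pct must lie in [0, 100]")
        if not 0 <= self.omd_pct <= 100:
            raise SchemaError("omd_pct must lie in [0, 100]")


# ---------------------------------------------------------------------------
# Table schemas
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Column:
    """Validation rules for one CSV column."""

    name: str
    kind: str  # "str" | "int" | "float"
    minimum: float | None = None
    exclusive_min: bool = False
    maximum: float | None = None
    domain: tuple[str, ...] | None = None


@dataclass(frozen=True)
class TableSchema:
    name: str
    columns: tuple[Column, ...]

    @property
    def column_names(self) -> list[str]:
        return [c.name for c in self.columns]

    def validate(self, df: pd.DataFrame) -> pd.DataFrame:
        """Return a copy with coerced dtypes; raise SchemaError on violations.

        Error messages name the offending field and the (1-based, header
        included) file row numbers of up to five offending rows.
        """
        missing = [c.name for c in self.columns if c.name not in df.columns]
        if missing:
            raise SchemaError(f"table {self.name!r}: missing column(s) {missing}")
        out = df.loc[:, self.column_names].copy()
        problems: list[str] = []
        for col in self.columns:
            s = out[col.name]
            if col.kind in ("int", "float"):
                coerced = pd.to_numeric(s, errors="coerce")
                bad = coerced.isna() & s.notna()
                self._report(problems, col.name, bad, "not numeric")
                if col.kind == "int":
                    nonint = coerced.notna() & (coerced != coerced.round())
                    self._report(problems, col.name, nonint, "not an integer")
                    coerced = coerced.round().astype("Int64")
                out[col.name] = coerced
                s = coerced
                if col.minimum is not None:
                    if col.exclusive_min:
                        bad = s.notna() & (s <= col.minimum)
                        self._report(problems, col.name, bad, f"must be > {col.minimum}")
                    else:
                        bad = s.notna() & (s < col.minimum)
                        self._report(problems, col.name, bad, f"must be >= {col.minimum}")
                if col.maximum is not None:
                    bad = s.notna() & (s > col.maximum)
                    self._report(problems, col.name, bad, f"must be <= {col.maximum}")
                nan = s.isna()
                self._report(problems, col.name, nan, "missing value")
            else:
                out[col.name] = s.astype(str)
                if col.domain is not None:
                    bad = ~out[col.name].isin(col.domain)
                    self._report(
                        problems, col.name, bad,
                        f"not in allowed labels {list(col.domain)}",
                    )
        if problems:
            raise SchemaError(
                f"table {self.name!r} failed validation:\n  " + "\n  ".join(problems)
            )
        return out

    @staticmethod
    def _report(problems: list[str], col: str, bad: pd.Series, why: str) -> None:
        if bad.any():
            rows = [int(i) + 2 for i in bad[bad].index[:5]]  # +2: header + 1-basing
            more = "" if int(bad.sum()) <= 5 else f" (+{int(bad.sum()) - 5} more)"
            problems.append(f"column {col!r}: {why} at file row(s) {rows}{more}")


SCHEMAS: dict[str, TableSchema] = {
    "camps": TableSchema("camps", (
        Column("camp_id", "str"),
        Column("season", "str", domain=SEASONS),
        Column("area_ha", "float", minimum=0, exclusive_min=True),
        Column("n_cows", "int", minimum=0),
        Column("n_heifers", "int", minimum=0),
    )),
    "quadrats": TableSchema("quadrats", (
        Column("camp_id", "str"),
        Column("season", "str", domain=SEASONS),
        Column("month", "str"),
        Column("transect_id", "str"),
        Column("position_m", "float", minimum=0),
        Column("sward_height_cm", "float", minimum=0, exclusive_min=True),
        Column("greenness_pct_class", "str", domain=WALKER_CLASSES),
    )),
    "observations": TableSchema("observations", (
        Column("observation_id", "str"),
        Column("camp_id", "str"),
        Column("herbivore", "str", domain=HERBIVORES),
        Column("season", "str", domain=SEASONS),
        Column("total_bites", "int", minimum=0, exclusive_min=True),
        Column("elapsed_min", "float", minimum=0, exclusive_min=True),
    )),
    "bites": TableSchema("bites", (
        Column("observation_id", "str"),
        Column("station_index", "int", minimum=1, maximum=5),
        Column("species", "str"),
        Column("greenness4", "str", domain=GREENNESS4),
        Column("sward_height_cm", "float", minimum=0, exclusive_min=True),
        Column("bite_mass_g", "float", minimum=0),
    )),
    "sward_series": TableSchema("sward_series", (
        Column("sward_id", "str"),
        Column("group", "str"),
        Column("day", "float", minimum=0),
        Column("height_cm", "float", minimum=0, exclusive_min=True),
    )),
    "defoliation_events": TableSchema("defoliation_events", (
        Column("sward_id", "str"),
        Column("group", "str"),
        Column("event_day", "float", minimum=0),
    )),
    "nutrients": TableSchema("nutrients", (
        Column("species", "str"),
        Column("greenness4", "str", domain=GREENNESS4),
        Column("cp_pct", "float", minimum=0, maximum=100),
        Column("omd_pct", "float", minimum=0, maximum=100),
    )),
}


def read_table(path: str | Path, schema: str | TableSchema) -> pd.DataFrame:
    """Read a CSV and validate it against a named schema."""
    sch = SCHEMAS[schema] if isinstance(schema, str) else schema
    df = pd.read_csv(path, dtype=str, keep_default_na=False, na_values=[""])
    return sch.validate(df)


def write_table(df: pd.DataFrame, path: str | Path, schema: str | TableSchema) -> Path:
    """Validate a frame against a schema and write it as CSV (lossless floats)."""
    sch = SCHEMAS[schema] if isinstance(schema, str) else schema
    validated = sch.validate(df)
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    # default float formatting is shortest round-trip repr: read-back lossless
    validated.to_csv(path, index=False)
    return path


# ---------------------------------------------------------------------------
# Frame <-> record conversion
# ---------------------------------------------------------------------------

def observations_from_frames(
    obs_df: pd.DataFrame, bites_df: pd.DataFrame
) -> list[ForagingObservation]:
    """Assemble :class:`ForagingObservation` objects from validated frames."""
    by_obs: dict[str, list[BiteRecord]] = {}
    for row in bites_df.itertuples(index=False):
        by_obs.setdefault(row.observation_id, []).append(BiteRecord(
            observation_id=row.observation_id,
            station_index=int(row.station_index),
            species=row.species,
            greenness4=row.greenness4,
            sward_height_cm=float(row.sward_height_cm),
            bite_mass_g=float(row.bite_mass_g),
        ))
    out = []
    for row in obs_df.itertuples(index=False):
        out.append(ForagingObservation(
            observation_id=row.observation_id,
            camp_id=row.camp_id,
            herbivore=row.herbivore,
            season=row.season,
            total_bites=int(row.total_bites),
            elapsed_min=float(row.elapsed_min),
            bites=by_obs.get(row.observation_id, []),
        ))
    return out


def sward_series_from_frames(
    series_df: pd.DataFrame, events_df: pd.DataFrame | None = None
) -> list[SwardSeries]:
    """Assemble :class:`SwardSeries` objects from validated frames."""
    events: dict[str, list[float]] = {}
    if events_df is not None:
        for row in events_df.itertuples(index=False):
            events.setdefault(row.sward_id, []).append(float(row.event_day))
    out = []
    for (sward_id, group), g in series_df.groupby(["sward_id", "group"], sort=True):
        g = g.sort_values("day")
        out.append(SwardSeries(
            sward_id=sward_id,
            group=group,
            days=[float(d) for d in g["day"]],
            heights_cm=[float(h) for h in g["height_cm"]],
            defoliation_days=events.get(sward_id, []),
        ))
    return out


def camps_from_frame(camps_df: pd.DataFrame) -> list[CampConfig]:
    return [
        CampConfig(
            camp_id=row.camp_id,
            area_ha=float(row.area_ha),
            n_cows=int(row.n_cows),
            n_heifers=int(row.n_heifers),
            season=row.season,
        )
        for row in camps_df.itertuples(index=False)
    ]


# ---------------------------------------------------------------------------
# Structured config
# ---------------------------------------------------------------------------

def load_config(path: str | Path) -> dict:
    """Load a YAML run configuration into a nested dict."""
    with open(path, "r", encoding="utf-8") as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise SchemaError(f"config {path}: expected a mapping at top level")
    return cfg


def dump_config(cfg: dict, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=True)
    return path
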