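"""Synthetic field-study generator.

Generates camps, transect quadrats, marked-sward regrowth series, foraging
observations with bite records, and a nutrient table with the statistical
structure the downstream analysis assumes:

* sward heights per camp x season: Gamma, parameterized by mean and CV;
* greenness: camp- and season-specific multinomials over the four bins,
  refined to Walker classes by a within-bin split;
* diet composition: camp-specific species multinomials (stored as
  percentage contributions in the config);
* bite masses: lognormal per species; bite rates: Gamma; elapsed times:
  lognormal;
* sward dynamics over a 38-day trial, sampled every 3 days, punctuated by
  defoliation events — Poisson-timed for grazed swards (rate scaling with
  stocking density) or on fixed schedules for the clipping experiment.

Two growth models are available.  The default, ``proportional``, grows
log-height linearly in time and applies a constant log-height drop per
defoliation event, which makes expected net relative regrowth exactly
linear in the number of events — the linearity the clipping-calibration
analysis relies on.  ``linear_reset`` grows height by a constant cm/day
and resets it to the defoliation height at each event.

All randomness flows from one integer seed through
:class:`numpy.random.SeedSequence` substreams, so output is reproducible
at the record level.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import core_io
from .core_io import GREENNESS4, SEASONS, SchemaError, SwardSeries, write_table


class ConfigError(ValueError):
    """The simulation configuration is inconsistent or degenerate."""


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

def _require(cond: bool, msg: str) -> None:
    if not cond:
        raise ConfigError(msg)


def _normalized_multinomial(d: dict, what: str) -> pd.Series:
    _require(bool(d), f"{what}: empty multinomial")
    s = pd.Series(d, dtype=float).sort_index()
    _require((s >= 0).all(), f"{what}: negative probability")
    total = float(s.sum())
    _require(total > 0, f"{what}: all-zero multinomial")
    s = s / total
    assert abs(s.sum() - 1.0) <= 1e-9
    return s


@dataclass
class SimulationConfig:
    """Validated wrapper around the nested simulation-config mapping."""

    raw: dict

    def __post_init__(self) -> None:
        cfg = self.raw
        for key in ("seed", "trial", "transects", "camps", "foraging", "nutrients"):
            _require(key in cfg, f"config: missing section {key!r}")
        trial = cfg["trial"]
        _require(trial["days"] > 0, "trial.days must be positive")
        _require(trial["growth_model"] in ("proportional", "linear_reset"),
                 "trial.growth_model must be proportional or linear_reset")
        _require(trial["initial_height"]["mean_cm"] > 0,
                 "initial height mean must be positive")
        _require(trial["initial_height"]["cv_pct"] > 0,
                 "initial height CV must be positive (degenerate otherwise)")
        for label, days in trial["clipping"]["schedules"].items():
            for d in days:
                _require(0 <= d <= trial["days"],
                         f"clipping schedule {label!r}: day {d} outside "
                         f"[0, {trial['days']}]")
        for camp_id, camp in cfg["camps"].items():
            _require(camp["area_ha"] > 0, f"camp {camp_id!r}: area must be > 0")
            _require(camp["grazing_events_per_day"] >= 0,
                     f"camp {camp_id!r}: event rate must be >= 0")
            for season, hp in camp["sward_height"].items():
                _require(hp["mean_cm"] > 0,
                         f"camp {camp_id!r} {season}: height mean must be > 0")
                _require(hp["cv_pct"] > 0,
                         f"camp {camp_id!r} {season}: height CV must be > 0 "
                         "(a zero-CV Gamma is degenerate)")
            for season, avail in camp.get("greenness_availability", {}).items():
                _normalized_multinomial(
                    avail, f"camp {camp_id!r} {season} greenness availability")
        for herb, fcfg in cfg["foraging"].items():
            if herb == "stations_per_observation":
                continue
            for season, by_camp in fcfg["diet_species"].items():
                for camp_id, mult in by_camp.items():
                    _normalized_multinomial(
                        mult, f"{herb} {season} {camp_id} diet species")
            for season, by_camp in fcfg["diet_greenness"].items():
                for camp_id, mult in by_camp.items():
                    m = _normalized_multinomial(
                        mult, f"{herb} {season} {camp_id} diet greenness")
                    _require(set(m.index) <= set(GREENNESS4),
                             f"{herb} {season} {camp_id}: unknown greenness bin")

    # -- accessors ---------------------------------------------------------

    @property
    def seed(self) -> int:
        return int(self.raw["seed"])

    @property
    def trial(self) -> dict:
        return self.raw["trial"]

    @property
    def sample_days(self) -> list[int]:
        days = int(self.trial["days"])
        step = int(self.trial["sample_every_days"])
        out = list(range(0, days, step))
        if out[-1] != days:
            out.append(days)
        return out

    def camp_ids(self, with_transects: bool = False) -> list[str]:
        ids = list(self.raw["camps"])
        if with_transects:
            ids = [c for c in ids
                   if self.raw["camps"][c].get("greenness_availability")
                   and len(self.raw["camps"][c]["sward_height"]) == len(SEASONS)]
        return ids

    def camp(self, camp_id: str) -> dict:
        return self.raw["camps"][camp_id]

    def height_params(self, camp_id: str, season: str) -> tuple[float, float]:
        hp = self.camp(camp_id)["sward_height"][season]
        return float(hp["mean_cm"]), float(hp["cv_pct"])

    def availability(self, camp_id: str, season: str) -> pd.Series:
        return _normalized_multinomial(
            self.camp(camp_id)["greenness_availability"][season],
            f"{camp_id} {season} availability")

    def diet_percentages(self, herbivore: str, season: str, camp_id: str) -> pd.Series:
        """Configured diet contributions as raw percentages (not normalized)."""
        return pd.Series(
            self.raw["foraging"][herbivore]["diet_species"][season][camp_id],
            dtype=float,
        )

    def diet_species(self, herbivore: str, season: str, camp_id: str) -> pd.Series:
        return _normalized_multinomial(
            self.raw["foraging"][herbivore]["diet_species"][season][camp_id],
            f"{herbivore} {season} {camp_id} diet")

    def diet_columns(self) -> dict[tuple[str, str, str], pd.Series]:
        """All configured (herbivore, season, camp) -> percentage columns."""
        out = {}
        for herb, fcfg in self.raw["foraging"].items():
            if herb == "stations_per_observation":
                continue
            for season, by_camp in fcfg["diet_species"].items():
                for camp_id in by_camp:
                    out[(herb, season, camp_id)] = self.diet_percentages(
                        herb, season, camp_id)
        return out


def default_config_path() -> Path:
    return Path(resources.files("grazekit").joinpath("data/default_config.yaml"))


def default_config() -> SimulationConfig:
    with open(default_config_path(), "r", encoding="utf-8") as fh:
        return SimulationConfig(yaml.safe_load(fh))


def load_simulation_config(path: str | Path) -> SimulationConfig:
    return SimulationConfig(core_io.load_config(path))


# ---------------------------------------------------------------------------
# Distribution helpers (mean/CV parameterizations)
# ---------------------------------------------------------------------------

def gamma_from_mean_cv(rng: np.random.Generator, mean: float, cv_pct: float,
                       size: int) -> np.ndarray:
    if mean <= 0 or cv_pct <= 0:
        raise ConfigError("Gamma mean and CV must be positive")
    cv = cv_pct / 100.0
    shape = 1.0 / cv ** 2
    return rng.gamma(shape, mean * cv ** 2, size=size)


def lognormal_from_mean_cv(rng: np.random.Generator, mean: float, cv_pct: float,
                           size: int) -> np.ndarray:
    if mean <= 0 or cv_pct <= 0:
        raise ConfigError("lognormal mean and CV must be positive")
    cv = cv_pct / 100.0
    sigma2 = math.log1p(cv ** 2)
    mu = math.log(mean) - sigma2 / 2.0
    return rng.lognormal(mu, math.sqrt(sigma2), size=size)


# ---------------------------------------------------------------------------
# Transects
# ---------------------------------------------------------------------------

def simulate_transects(config: SimulationConfig,
                       rng: np.random.Generator) -> pd.DataFrame:
    """Quadrat records for every transect-sampled camp x season x month."""
    t = config.raw["transects"]
    per_transect = int(t["points_per_transect"]) * int(t["quadrats_per_point"])
    rows = []
    for camp_id in config.camp_ids(with_transects=True):
        for season in SEASONS:
            mean, cv = config.height_params(camp_id, season)
            avail = config.availability(camp_id, season)
            within = config.raw["walker_within_bin"]
            for month in t["months"][season]:
                for transect in range(1, int(t["transects_per_month"]) + 1):
                    heights = gamma_from_mean_cv(rng, mean, cv, per_transect)
                    bins = rng.choice(avail.index.to_numpy(), size=per_transect,
                                      p=avail.to_numpy())
                    for i in range(per_transect):
                        split = _normalized_multinomial(
                            within[bins[i]], f"walker split {bins[i]!r}")
                        walker = rng.choice(split.index.to_numpy(),
                                            p=split.to_numpy())
                        point = i // int(t["quadrats_per_point"])
                        rows.append({
                            "camp_id": camp_id,
                            "season": season,
                            "month": month,
                            "transect_id": f"{camp_id}-{season}-{month}-T{transect}",
                            "position_m": point * float(t["point_spacing_m"]),
                            "sward_height_cm": float(heights[i]),
                            "greenness_pct_class": str(walker),
                        })
    return core_io.SCHEMAS["quadrats"].validate(pd.DataFrame(rows))


# ---------------------------------------------------------------------------
# Sward regrowth series
# ---------------------------------------------------------------------------

def _series_heights(config: SimulationConfig, h0: float, noise: float,
                    event_days: np.ndarray) -> list[float]:
    trial = config.trial
    days = config.sample_days
    total = float(trial["days"])
    model = trial["growth_model"]
    heights = []
    if model == "proportional":
        r = float(trial["proportional"]["log_growth_per_day"])
        drop = float(trial["proportional"]["defoliation_log_drop"])
        for t in days:
            n_before = int((event_days <= t).sum())
            heights.append(h0 * math.exp(r * t + drop * n_before + noise * t / total))
    else:
        g = float(trial["linear_reset"]["growth_cm_per_day"])
        reset = float(trial["linear_reset"]["defoliation_height_cm"])
        for t in days:
            before = event_days[event_days <= t]
            if before.size == 0:
                h = h0 + g * t
            else:
                h = reset + g * (t - float(before.max()))
            heights.append(h * math.exp(noise * t / total))
    return heights


def simulate_sward_series(config: SimulationConfig, mode: str,
                          rng: np.random.Generator) -> list[SwardSeries]:
    """Marked-sward height series for the grazed trial or clipping experiment.

    ``mode="grazed"``: per camp, ``n_grazed_swards_per_camp`` swards with
    Poisson-timed defoliation events at the camp's configured daily rate.
    ``mode="clipped"``: per clipping schedule, the configured number of
    replicate swards defoliated on the schedule's fixed days; the group
    label is ``clip-<n>``.
    """
    if mode not in ("grazed", "clipped"):
        raise ConfigError(f"unknown sward-series mode {mode!r}")
    trial = config.trial
    total_days = float(trial["days"])
    h_mean = float(trial["initial_height"]["mean_cm"])
    h_cv = float(trial["initial_height"]["cv_pct"])
    noise_sd = float(trial["regrowth_noise_sd"])
    out: list[SwardSeries] = []

    def make(sward_id: str, group: str, event_days: np.ndarray) -> SwardSeries:
        h0 = float(lognormal_from_mean_cv(rng, h_mean, h_cv, 1)[0])
        noise = float(rng.normal(0.0, noise_sd)) if noise_sd > 0 else 0.0
        heights = _series_heights(config, h0, noise, event_days)
        return SwardSeries(
            sward_id=sward_id,
            group=group,
            days=[float(d) for d in config.sample_days],
            heights_cm=heights,
            defoliation_days=[float(d) for d in event_days],
        )

    if mode == "grazed":
        n = int(trial["n_grazed_swards_per_camp"])
        for camp_id in config.camp_ids():
            rate = float(config.camp(camp_id)["grazing_events_per_day"])
            if rate <= 0:
                continue
            for i in range(n):
                count = int(rng.poisson(rate * total_days))
                events = np.sort(rng.uniform(0.0, total_days, size=count))
                out.append(make(f"{camp_id}-S{i + 1:02d}", camp_id, events))
    else:
        n = int(trial["clipping"]["n_replicates_per_schedule"])
        for label, sched in trial["clipping"]["schedules"].items():
            events = np.asarray(sorted(float(d) for d in sched))
            for i in range(n):
                out.append(make(f"clip{label}-S{i + 1:02d}", f"clip-{label}",
                                events.copy()))
    return out


def sward_series_to_frames(series: list[SwardSeries]) -> tuple[pd.DataFrame, pd.DataFrame]:
    """(heights frame, defoliation-events frame) in the CSV schemas."""
    h_rows, e_rows = [], []
    for s in series:
        for d, h in zip(s.days, s.heights_cm):
            h_rows.append({"sward_id": s.sward_id, "group": s.group,
                           "day": d, "height_cm": h})
        for d in s.defoliation_days:
            e_rows.append({"sward_id": s.sward_id, "group": s.group,
                           "event_day": d})
    heights = core_io.SCHEMAS["sward_series"].validate(pd.DataFrame(h_rows))
    events = pd.DataFrame(e_rows, columns=["sward_id", "group", "event_day"])
    if not events.empty:
        events = core_io.SCHEMAS["defoliation_events"].validate(events)
    return heights, events


# ---------------------------------------------------------------------------
# Foraging observations
# ---------------------------------------------------------------------------

def simulate_foraging(config: SimulationConfig,
                      rng: np.random.Generator) -> list[core_io.ForagingObservation]:
    """Five-station foraging observations with attached bite records."""
    fcfg = config.raw["foraging"]
    n_stations = int(fcfg["stations_per_observation"])
    out: list[core_io.ForagingObservation] = []
    for herb in sorted(k for k in fcfg if k != "stations_per_observation"):
        hcfg = fcfg[herb]
        mass_cfg = hcfg["bite_mass_g"]
        for season in SEASONS:
            by_camp = hcfg["n_observations"].get(season, {})
            for camp_id in sorted(by_camp):
                n_obs = int(by_camp[camp_id])
                species = config.diet_species(herb, season, camp_id)
                greenness = _normalized_multinomial(
                    hcfg["diet_greenness"][season][camp_id],
                    f"{herb} {season} {camp_id} greenness")
                gh = hcfg["grazed_height"][season][camp_id]
                for i in range(n_obs):
                    obs_id = f"{herb}-{camp_id}-{season}-{i + 1:03d}"
                    elapsed = float(lognormal_from_mean_cv(
                        rng, float(hcfg["elapsed_min"]["mean"]),
                        float(hcfg["elapsed_min"]["cv_pct"]), 1)[0])
                    rate = float(gamma_from_mean_cv(
                        rng, float(hcfg["bite_rate"]["mean_per_min"]),
                        float(hcfg["bite_rate"]["cv_pct"]), 1)[0])
                    total_bites = max(1, int(round(rate * elapsed)))
                    stations = rng.multinomial(
                        total_bites, [1.0 / n_stations] * n_stations)
                    bites = []
                    for st, count in enumerate(stations, start=1):
                        if count == 0:
                            continue
                        sp = rng.choice(species.index.to_numpy(), size=count,
                                        p=species.to_numpy())
                        gr = rng.choice(greenness.index.to_numpy(), size=count,
                                        p=greenness.to_numpy())
                        hts = gamma_from_mean_cv(
                            rng, float(gh["mean_cm"]), float(gh["cv_pct"]), count)
                        for b in range(count):
                            mp = mass_cfg.get("overrides", {}).get(
                                str(sp[b]), mass_cfg["default"])
                            mass = float(lognormal_from_mean_cv(
                                rng, float(mp["mean_g"]), float(mp["cv_pct"]), 1)[0])
                            bites.append(core_io.BiteRecord(
                                observation_id=obs_id,
                                station_index=st,
                                species=str(sp[b]),
                                greenness4=str(gr[b]),
                                sward_height_cm=float(hts[b]),
                                bite_mass_g=mass,
                            ))
                    out.append(core_io.ForagingObservation(
                        observation_id=obs_id,
                        camp_id=camp_id,
                        herbivore=herb,
                        season=season,
                        total_bites=total_bites,
                        elapsed_min=elapsed,
                        bites=bites,
                    ))
    return out


def foraging_to_frames(
    observations: list[core_io.ForagingObservation],
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """(observations frame, bites frame) in the CSV schemas."""
    o_rows, b_rows = [], []
    for o in observations:
        o_rows.append({
            "observation_id": o.observation_id, "camp_id": o.camp_id,
            "herbivore": o.herbivore, "season": o.season,
            "total_bites": o.total_bites, "elapsed_min": o.elapsed_min,
        })
        for b in o.bites:
            b_rows.append({
                "observation_id": b.observation_id,
                "station_index": b.station_index,
                "species": b.species, "greenness4": b.greenness4,
                "sward_height_cm": b.sward_height_cm,
                "bite_mass_g": b.bite_mass_g,
            })
    obs = core_io.SCHEMAS["observations"].validate(pd.DataFrame(o_rows))
    bites = core_io.SCHEMAS["bites"].validate(pd.DataFrame(b_rows))
    return obs, bites


# ---------------------------------------------------------------------------
# Nutrient table and camps
# ---------------------------------------------------------------------------

def simulate_nutrients(config: SimulationConfig) -> pd.DataFrame:
    """Deterministic nutrient table for the profiled (top-six) species.

    Each diet column contributes its six largest-contribution species;
    the union is profiled across all four greenness bins with the
    configured baseline-plus-offset concentrations.
    """
    ncfg = config.raw["nutrients"]
    profiled: set[str] = set()
    for column in config.diet_columns().values():
        top6 = column.sort_index().sort_values(ascending=False, kind="stable")
        profiled.update(str(s) for s in top6.index[:6])
    rows = []
    for species in sorted(profiled):
        for bin4 in GREENNESS4:
            cp = float(ncfg["cp_base_pct"][bin4]) + float(
                ncfg["cp_species_offset"].get(species, 0.0))
            omd = float(ncfg["omd_base_pct"][bin4]) + float(
                ncfg["omd_species_offset"].get(species, 0.0))
            rows.append({
                "species": species, "greenness4": bin4,
                "cp_pct": float(np.clip(cp, 0.5, 30.0)),
                "omd_pct": float(np.clip(omd, 20.0, 85.0)),
            })
    return core_io.SCHEMAS["nutrients"].validate(pd.DataFrame(rows))


def simulate_camps(config: SimulationConfig) -> pd.DataFrame:
    """Camp configuration table (one row per camp x season present)."""
    rows = []
    for camp_id in config.camp_ids():
        camp = config.camp(camp_id)
        for season in camp["sward_height"]:
            rows.append({
                "camp_id": camp_id, "season": season,
                "area_ha": float(camp["area_ha"]),
                "n_cows": int(camp["n_cows"]),
                "n_heifers": int(camp["n_heifers"]),
            })
    return core_io.SCHEMAS["camps"].validate(pd.DataFrame(rows))


# ---------------------------------------------------------------------------
# Full simulation
# ---------------------------------------------------------------------------

#: CSV file names written by :func:`simulate_all`.
OUTPUT_FILES = {
    "camps": "camps.csv",
    "quadrats": "quadrats.csv",
    "observations": "observations.csv",
    "bites": "bites.csv",
    "sward_series_grazed": "sward_series_grazed.csv",
    "events_grazed": "defoliation_events_grazed.csv",
    "sward_series_clipped": "sward_series_clipped.csv",
    "events_clipped": "defoliation_events_clipped.csv",
    "nutrients": "nutrients.csv",
}


def substreams(seed: int, n: int = 4) -> list[np.random.Generator]:
    """Deterministic per-stage random generators derived from one seed."""
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


def simulate_all(config: SimulationConfig, out_dir: str | Path,
                 seed: int | None = None) -> dict[str, Path]:
    """Run every generator and write the CSV suite to ``out_dir``."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    seed = config.seed if seed is None else int(seed)
    rng_t, rng_g, rng_c, rng_f = substreams(seed, 4)

    quadrats = simulate_transects(config, rng_t)
    grazed = simulate_sward_series(config, "grazed", rng_g)
    clipped = simulate_sward_series(config, "clipped", rng_c)
    observations = simulate_foraging(config, rng_f)

    g_heights, g_events = sward_series_to_frames(grazed)
    c_heights, c_events = sward_series_to_frames(clipped)
    obs_df, bites_df = foraging_to_frames(observations)

    paths = {}
    frames = {
        "camps": (simulate_camps(config), "camps"),
        "quadrats": (quadrats, "quadrats"),
        "observations": (obs_df, "observations"),
        "bites": (bites_df, "bites"),
        "sward_series_grazed": (g_heights, "sward_series"),
        "events_grazed": (g_events, "defoliation_events"),
        "sward_series_clipped": (c_heights, "sward_series"),
        "events_clipped": (c_events, "defoliation_events"),
        "nutrients": (simulate_nutrients(config), "nutrients"),
    }
    for key, (df, schema) in frames.items():
        paths[key] = write_table(df, out_dir / OUTPUT_FILES[key], schema)
    return paths
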