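import copy
import math

import numpy as np
import pandas as pd
import pytest

from grazekit import synthetic_data as sd
from grazekit.diet import diet_contributions, schoener_overlap
from grazekit.regrowth import relative_regrowth
from grazekit.synthetic_data import ConfigError, SimulationConfig


def rng_pair(seed=123):
    return (np.random.default_rng(seed), np.random.default_rng(seed))


class TestConfig:
    def test_default_config_validates(self, default_cfg):
        assert default_cfg.seed > 0
        assert default_cfg.sample_days[0] == 0
        assert default_cfg.sample_days[-1] == default_cfg.trial["days"]

    def test_multinomials_normalized(self, default_cfg):
        for key, col in default_cfg.diet_columns().items():
            s = default_cfg.diet_species(*key)
            assert s.sum() == pytest.approx(1.0, abs=1e-9)
            assert (s >= 0).all()

    def test_zero_cv_rejected(self, default_cfg):
        raw = copy.deepcopy(default_cfg.raw)
        raw["camps"]["low"]["sward_height"]["wet"]["cv_pct"] = 0.0
        with pytest.raises(ConfigError, match="CV must be > 0"):
            SimulationConfig(raw)

    def test_empty_species_multinomial_rejected(self, default_cfg):
        raw = copy.deepcopy(default_cfg.raw)
        raw["foraging"]["oribi"]["diet_species"]["wet"]["low"] = {}
        with pytest.raises(ConfigError, match="empty multinomial"):
            SimulationConfig(raw)

    def test_schedule_day_outside_trial_rejected(self, default_cfg):
        raw = copy.deepcopy(default_cfg.raw)
        raw["trial"]["clipping"]["schedules"]["3"] = [3, 17, 50]
        with pytest.raises(ConfigError, match="outside"):
            SimulationConfig(raw)


class TestTransects:
    def test_same_seed_identical_records(self, small_cfg):
        r1, r2 = rng_pair()
        pd.testing.assert_frame_equal(
            sd.simulate_transects(small_cfg, r1),
            sd.simulate_transects(small_cfg, r2))

    def test_gamma_mean_and_cv_recovered(self, default_cfg):
        """A camp configured at mean 23 cm / 58% CV yields samples matching
        those moments at n = 10,000."""
        raw = copy.deepcopy(default_cfg.raw)
        raw["camps"] = {"solo": {
            "area_ha": 100.0, "n_cows": 10, "n_heifers": 0,
            "grazing_events_per_day": 0.1,
            "sward_height": {
                "wet": {"mean_cm": 23.0, "cv_pct": 58.0},
                "dry": {"mean_cm": 23.0, "cv_pct": 58.0},
            },
            "greenness_availability": {
                "wet": {"very green": 1.0}, "dry": {"very green": 1.0},
            },
        }}
        raw["transects"] = {
            "transects_per_month": 1, "points_per_transect": 2500,
            "quadrats_per_point": 2, "point_spacing_m": 50,
            "months": {"wet": ["Jan"], "dry": ["Jun"]},
        }
        cfg = SimulationConfig(raw)
        q = sd.simulate_transects(cfg, np.random.default_rng(7))
        h = q["sward_height_cm"].to_numpy()
        assert h.size == 10_000
        assert abs(h.mean() / 23.0 - 1) < 0.02
        cv = 100.0 * h.std(ddof=1) / h.mean()
        assert abs(cv / 58.0 - 1) < 0.05

    def test_degenerate_gamma_rejected(self, rng):
        with pytest.raises(ConfigError):
            sd.gamma_from_mean_cv(rng, 23.0, 0.0, 10)


class TestSwardSeries:
    def test_linear_reset_growth_without_events(self, default_cfg):
        """0.5 cm/day for 38 days from 8 cm reaches 27 cm: regrowth ln(27/8)."""
        raw = copy.deepcopy(default_cfg.raw)
        raw["trial"]["growth_model"] = "linear_reset"
        cfg = SimulationConfig(raw)
        heights = sd._series_heights(cfg, h0=8.0, noise=0.0,
                                     event_days=np.array([]))
        assert heights[-1] == pytest.approx(27.0)
        from grazekit.core_io import SwardSeries
        s = SwardSeries("s", "g", [float(d) for d in cfg.sample_days], heights)
        assert relative_regrowth(s) == pytest.approx(math.log(27.0 / 8.0))

    def test_weekly_clipping_shows_five_defoliations(self, small_cfg):
        series = sd.simulate_sward_series(small_cfg, "clipped",
                                          np.random.default_rng(5))
        weekly = [s for s in series if s.group == "clip-5"]
        assert weekly
        for s in weekly:
            assert s.n_defoliations == 5
            # each event produces a net height drop over its 3-day interval
            diffs = np.diff(np.log(s.heights_cm))
            assert int((diffs < 0).sum()) == 5

    def test_poisson_event_count_mean(self, default_cfg):
        """Rate 14/38 per day over 38 days: mean count over 1,000 swards
        within 5% of 14."""
        raw = copy.deepcopy(default_cfg.raw)
        raw["trial"]["n_grazed_swards_per_camp"] = 1000
        raw["camps"] = {"high": raw["camps"]["high"]}
        cfg = SimulationConfig(raw)
        series = sd.simulate_sward_series(cfg, "grazed", np.random.default_rng(3))
        counts = [s.n_defoliations for s in series]
        assert len(counts) == 1000
        assert abs(np.mean(counts) / 14.0 - 1) < 0.05

    def test_same_seed_identical_series(self, small_cfg):
        r1, r2 = rng_pair(9)
        s1 = sd.simulate_sward_series(small_cfg, "grazed", r1)
        s2 = sd.simulate_sward_series(small_cfg, "grazed", r2)
        assert [(s.sward_id, s.heights_cm, s.defoliation_days) for s in s1] == \
               [(s.sward_id, s.heights_cm, s.defoliation_days) for s in s2]

    def test_unknown_mode_rejected(self, small_cfg, rng):
        with pytest.raises(ConfigError, match="mode"):
            sd.simulate_sward_series(small_cfg, "burned", rng)


class TestForaging:
    def test_single_species_diet_is_pure(self, small_cfg):
        raw = copy.deepcopy(small_cfg.raw)
        raw["foraging"]["oribi"]["diet_species"]["wet"]["low"] = {"Only grass": 1.0}
        cfg = SimulationConfig(raw)
        observations = sd.simulate_foraging(cfg, np.random.default_rng(2))
        target = [o for o in observations
                  if o.herbivore == "oribi" and o.camp_id == "low"
                  and o.season == "wet"]
        bites = [b for o in target for b in o.bites]
        assert bites and all(b.species == "Only grass" for b in bites)

    def test_same_seed_identical_observations(self, small_cfg):
        r1, r2 = rng_pair(11)
        o1 = sd.simulate_foraging(small_cfg, r1)
        o2 = sd.simulate_foraging(small_cfg, r2)
        f1 = sd.foraging_to_frames(o1)
        f2 = sd.foraging_to_frames(o2)
        pd.testing.assert_frame_equal(f1[0], f2[0])
        pd.testing.assert_frame_equal(f1[1], f2[1])

    def test_identical_multinomials_converge_to_full_overlap(self, small_cfg):
        """Two camps sampling the same species multinomial approach
        Schoener overlap 1 as bite counts grow."""
        raw = copy.deepcopy(small_cfg.raw)
        mult = raw["foraging"]["oribi"]["diet_species"]["wet"]["low"]
        raw["foraging"]["oribi"]["diet_species"]["wet"]["intermediate"] = dict(mult)
        raw["foraging"]["oribi"]["n_observations"]["wet"] = {
            "low": 40, "intermediate": 40}
        raw["foraging"]["oribi"]["n_observations"]["dry"] = {}
        raw["foraging"]["cattle"]["n_observations"]["wet"] = {}
        cfg = SimulationConfig(raw)
        obs, bites = sd.foraging_to_frames(
            sd.simulate_foraging(cfg, np.random.default_rng(21)))
        merged = bites.merge(obs[["observation_id", "camp_id"]], on="observation_id")
        tables = [diet_contributions(g, camp)
                  for camp, g in merged.groupby("camp_id")]
        assert len(tables) == 2
        assert schoener_overlap(*tables).schoener > 0.93

    def test_total_bites_cover_attached_records(self, small_cfg, rng):
        for o in sd.simulate_foraging(small_cfg, rng):
            assert o.total_bites >= len(o.bites)
            assert {b.station_index for b in o.bites} <= {1, 2, 3, 4, 5}


class TestNutrientsAndOutputs:
    def test_profiled_species_cover_top6_of_every_diet(self, default_cfg):
        nut = sd.simulate_nutrients(default_cfg)
        profiled = set(nut["species"])
        for col in default_cfg.diet_columns().values():
            top6 = set(col.sort_values(ascending=False).index[:6])
            assert top6 <= profiled

    def test_simulate_all_outputs_validate(self, small_cfg, tmp_path):
        from grazekit.core_io import read_table
        paths = sd.simulate_all(small_cfg, tmp_path, seed=4)
        schema_of = {
            "camps": "camps", "quadrats": "quadrats",
            "observations": "observations", "bites": "bites",
            "sward_series_grazed": "sward_series",
            "sward_series_clipped": "sward_series",
            "events_grazed": "defoliation_events",
            "events_clipped": "defoliation_events",
            "nutrients": "nutrients",
        }
        for key, schema in schema_of.items():
            df = read_table(paths[key], schema)  # raises on violation
            assert not df.empty
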