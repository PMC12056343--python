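"""Synthetic telemetry generator: determinism, truth structure, signal model."""

from dataclasses import replace
from datetime import date

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from dielscope import SimulationConfig, simulate_bird_day, simulate_study, simulate_timing_dataset
from dielscope.synthetic import ConfigError, default_sites, schedule_to_signal
from dielscope.solar import solar_times


def tiny_config(**kw):
    base = dict(
        n_birds_per_species_per_habitat=1,
        n_days=1,
        seasons=("pre_breeding",),
        years=(2020,),
        seed=3,
    )
    base.update(kw)
    return SimulationConfig(**base)


ZERO_VARIANCE = dict(
    between_sd_onset_h={"urban": 0.0, "forest": 0.0},
    within_sd_onset_h={"urban": 0.0, "forest": 0.0},
    between_sd_end_h={"urban": 0.0, "forest": 0.0},
    within_sd_end_h={"urban": 0.0, "forest": 0.0},
    site_sd_h=0.0,
    date_sd_h=0.0,
)


class TestConfigValidation:
    @pytest.mark.parametrize(
        "field,value,match",
        [
            ("detection_prob", 0.0, "detection_prob"),
            ("scan_interval_s", 170, "scan_interval_s"),
            ("n_receivers_per_site", 7, "n_receivers_per_site"),
            ("signal_step_active_dB", -1.0, "signal_step_active_dB"),
            ("nocturnal_active_prob", {"urban": 1.2, "forest": 0.0}, "nocturnal_active_prob"),
        ],
    )
    def test_invalid_field_named_in_error(self, field, value, match):
        cfg = tiny_config(**{field: value})
        with pytest.raises(ConfigError, match=match):
            cfg.validate()

    def test_species_effect_maps_must_cover_species(self):
        cfg = tiny_config(species_list=("blackbird", "robin", "kingfisher"))
        with pytest.raises(ConfigError, match="kingfisher"):
            cfg.validate()

    def test_yaml_round_trip(self, tmp_path):
        cfg = tiny_config(n_days=4, detection_prob=0.77)
        cfg.to_yaml(tmp_path / "sim.yaml")
        back = SimulationConfig.from_yaml(tmp_path / "sim.yaml")
        assert back == cfg


class TestStudyStructure:
    def test_full_slot_count_per_receiver_per_day(self):
        """With no dropout, each receiver logs 86400/180 = 480 slots per day."""
        cfg = tiny_config(
            species_list=("blackbird",),
            detection_prob=1.0,
            out_of_range_prob_per_day=0.0,
        )
        study = simulate_study(cfg)
        det = study.detections
        day = det[det.timestamp.dt.tz_convert("Europe/London").dt.date == date(2020, 3, 1)]
        counts = day.groupby(["tag_id", "receiver_id"]).size()
        assert (counts == 480).all()

    def test_same_seed_identical_output(self):
        cfg = tiny_config(species_list=("robin", "dunnock"))
        a = simulate_study(cfg)
        b = simulate_study(cfg)
        pd.testing.assert_frame_equal(a.detections, b.detections)
        pd.testing.assert_frame_equal(a.truth, b.truth)
        pd.testing.assert_frame_equal(a.climate, b.climate)

    def test_adding_birds_leaves_existing_draws_unchanged(self):
        """Substreams are keyed per bird, so growing the roster never
        perturbs the truth of birds already present."""
        small = simulate_study(tiny_config(n_birds_per_species_per_habitat=1))
        big = simulate_study(tiny_config(n_birds_per_species_per_habitat=2))
        shared = small.truth.merge(
            big.truth, on=["bird_id", "date"], suffixes=("_s", "_b")
        )
        assert len(shared) == len(small.truth)
        assert np.allclose(shared.true_rel_onset_h_s, shared.true_rel_onset_h_b)

    def test_zero_variance_synchronises_cohort(self):
        """With all variance parameters at zero, every bird of a species and
        habitat shares the same true onset each day."""
        cfg = tiny_config(
            n_birds_per_species_per_habitat=3,
            species_list=("blackbird", "robin"),
            **ZERO_VARIANCE,
        )
        study = simulate_study(cfg)
        spread = study.truth.groupby(["species", "habitat", "date"]).true_rel_onset_h.nunique()
        assert (spread == 1).all()

    def test_urban_blackbird_advance_is_33_minutes(self):
        """Zero-variance urban blackbirds start 0.55 h (33 min) before their
        forest counterparts."""
        cfg = tiny_config(species_list=("blackbird",), **ZERO_VARIANCE)
        study = simulate_study(cfg)
        m = study.truth.groupby("habitat").true_rel_onset_h.mean()
        assert (m["urban"] - m["forest"]) * 60 == pytest.approx(-33.0, abs=1e-6)

    def test_nocturnal_bouts_outside_daytime_activity(self):
        cfg = tiny_config(nocturnal_active_prob={"urban": 0.3, "forest": 0.3})
        sites = default_sites(cfg)
        sd = solar_times(sites.latitude[0], sites.longitude[0], date(2020, 3, 1),
                         "Europe/London", sites.site_id[0])
        bird = simulate_study(cfg).birds.iloc[0]
        bird = bird.copy()
        rng = np.random.default_rng(0)
        sched = simulate_bird_day(bird, date(2020, 3, 1), sd, cfg, rng)
        for b0, b1 in sched.nocturnal_bouts:
            assert b1 <= sched.true_onset or b0 >= sched.true_end


class TestMomentRecovery:
    def test_within_and_between_sds_recovered(self):
        """Empirical between/within-bird SDs of true onsets match the
        configured values within three standard errors (>=50 birds x 20 d)."""
        within = {"urban": 0.30, "forest": 0.30}
        between = {"urban": 0.40, "forest": 0.20}
        df = simulate_timing_dataset(
            SimulationConfig(within_sd_onset_h=within, between_sd_onset_h=between,
                             site_sd_h=0.0, date_sd_h=0.0),
            n_birds_per_cell=5, n_days=20, seed=200,
        )
        for hab in ("urban", "forest"):
            sub = df[df.habitat == hab]
            n_birds = sub.bird_id.nunique()
            n_obs = len(sub)
            dev = sub.relative_onset_h - sub.groupby("bird_id").relative_onset_h.transform("mean")
            sd_w = dev.std(ddof=0) * np.sqrt(n_obs / (n_obs - n_birds))
            se_w = within[hab] / np.sqrt(2 * (n_obs - n_birds))
            assert sd_w == pytest.approx(within[hab], abs=3 * se_w)
            bird_means = sub.groupby(["bird_id", "species"]).relative_onset_h.mean()
            sd_b = bird_means.groupby("species").transform(lambda v: v - v.mean()).std(ddof=1)
            se_b = between[hab] / np.sqrt(2 * n_birds) + within[hab] / np.sqrt(20 * n_birds)
            assert sd_b == pytest.approx(between[hab], abs=3 * se_b + 0.02)


class TestSignalModel:
    def _mask(self, n, active_idx):
        grid = pd.date_range("2020-03-01", periods=n, freq="180s", tz="Europe/London")
        mask = np.zeros(n, dtype=bool)
        mask[active_idx] = True
        return pd.Series(mask, index=grid)

    def test_inactive_day_zero_noise_constant_signal(self):
        cfg = tiny_config(signal_noise_inactive_dB=0.0, detection_prob=1.0)
        sig = schedule_to_signal(self._mask(100, []), ["r1"], cfg, np.random.default_rng(1))
        d = np.abs(np.diff(sig.signal_dB.to_numpy()))
        assert np.allclose(d, 0.0)

    def test_active_slots_force_threshold_crossing(self):
        """With a 20 dB step and no noise, every active-slot differential is
        at least 10 dB and classifies as active downstream."""
        cfg = tiny_config(signal_noise_inactive_dB=0.0, detection_prob=1.0)
        active = list(range(40, 70))
        sig = schedule_to_signal(self._mask(100, active), ["r1"], cfg, np.random.default_rng(2))
        s = sig.sort_values("timestamp").signal_dB.to_numpy()
        d = np.abs(np.diff(s))
        assert (d[39:69] >= 10.0).all()
        assert (d[:39] == 0.0).all()

    def test_separability_at_ten_db(self):
        """Noise 2 dB vs step 20 dB: active and inactive differentials are
        separable at the 10 dB threshold with error below 1%."""
        cfg = tiny_config(detection_prob=1.0)
        rng = np.random.default_rng(3)
        active_idx = np.nonzero(rng.random(5000) < 0.5)[0]
        mask = self._mask(5000, active_idx)
        sig = schedule_to_signal(mask, ["r1"], cfg, rng)
        s = sig.sort_values("timestamp")
        vals = s.signal_dB.to_numpy()
        d = np.abs(np.diff(vals))
        is_active = mask.to_numpy()[1:]
        err_active = (d[is_active] <= 10).mean()
        err_inactive = (d[~is_active] > 10).mean()
        assert err_active < 0.01
        assert err_inactive < 0.01

    def test_dropout_count_within_binomial_bounds(self):
        """detection_prob=0.8 over 480 slots: the per-receiver detection count
        lies inside the exact binomial 99% interval around 384."""
        cfg = tiny_config(detection_prob=0.8)
        sig = schedule_to_signal(self._mask(480, []), ["r1"], cfg, np.random.default_rng(4))
        lo, hi = stats.binom.ppf([0.005, 0.995], 480, 0.8)
        assert lo <= len(sig) <= hi
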