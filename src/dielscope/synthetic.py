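"""Synthetic automated-radio-telemetry study generator with known ground truth.

Emulates a multi-site, multi-season deployment on six passerine species in
urban and forest habitats: per-bird diel activity square waves anchored to
sunrise/sunset, habitat- and species-specific mean timing shifts,
habitat-specific between- and within-individual variance, sparse nocturnal
activity bouts, daytime rest gaps, per-receiver signal noise, independent
detection dropout plus occasional out-of-range episodes.

The generator's latent truth (per-bird deviations, per-day deviations, true
onset/end instants, per-slot activity masks) is returned alongside the raw
detection streams so every downstream stage can be validated against it.

Signal model: each receiver assigns a bird a fixed baseline strength drawn
once per bird-receiver pair.  While a bird is inactive its latent signal
holds its last position, so consecutive-scan differentials are pure receiver
noise; each active 3-min slot moves the latent signal to the opposite side
of the baseline at a distance of at least ``signal_step_active_dB / 2``, so
every active-slot differential is at least ``signal_step_active_dB`` and the
active/inactive differential distributions are separable at the downstream
10 dB threshold.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, asdict, replace
from datetime import date as _date, timedelta
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml
from scipy import optimize, special

from .solar import SolarDay, solar_times

__all__ = [
    "SimulationConfig",
    "ConfigError",
    "DaySchedule",
    "SyntheticStudy",
    "default_sites",
    "simulate_study",
    "simulate_bird_day",
    "schedule_to_signal",
    "simulate_timing_dataset",
    "simulate_activity_dataset",
]

SPECIES = ("blackbird", "blue_tit", "chaffinch", "dunnock", "great_tit", "robin")
SEXABLE_SPECIES = frozenset({"blackbird", "great_tit", "chaffinch"})
HABITATS = ("urban", "forest")


class ConfigError(ValueError):
    """Invalid simulation configuration; the message names the field."""


def _per_habitat(urban: float, forest: float) -> dict[str, float]:
    return {"urban": urban, "forest": forest}


@dataclass
class SimulationConfig:
    """Study-design and ground-truth parameters of the synthetic deployment.

    Defaults encode the study conditions the package targets: two urban and
    two forest sites near Glasgow / Loch Lomond, six species, pre-breeding
    (from 1 March) and post-breeding (from 5 October) deployments in 2020
    and 2021, 3-min scans, and habitat contrasts in both means and variance
    components.  Timing values are hours relative to sunrise (onset) or
    sunset (end); activity-level values are per-slot probabilities with
    between/within-bird heterogeneity on the logit scale.
    """

    n_birds_per_species_per_habitat: int = 6  # per season-year block
    species_list: Sequence[str] = SPECIES
    habitats: Sequence[str] = HABITATS
    sites_per_habitat: int = 2
    n_days: int = 14
    seasons: Sequence[str] = ("pre_breeding", "post_breeding")
    years: Sequence[int] = (2020, 2021)
    season_start: Mapping[str, tuple[int, int]] = field(
        default_factory=lambda: {"pre_breeding": (3, 1), "post_breeding": (10, 5)}
    )

    # --- timing traits (hours, relative to the solar anchor) ---
    species_base_onset_h: Mapping[str, float] = field(
        default_factory=lambda: {
            "blackbird": -0.50, "robin": -0.60, "great_tit": 0.00,
            "blue_tit": 0.00, "dunnock": 0.10, "chaffinch": 0.20,
        }
    )
    mean_onset_shift_urban_h: Mapping[str, float] = field(
        default_factory=lambda: {
            "blackbird": -0.55, "robin": -0.50, "blue_tit": -0.35,
            "dunnock": -0.30, "great_tit": -0.15, "chaffinch": -0.05,
        }
    )
    species_base_end_h: Mapping[str, float] = field(
        default_factory=lambda: {
            "blackbird": -0.30, "robin": -0.40, "great_tit": -0.70,
            "blue_tit": -0.70, "dunnock": -0.60, "chaffinch": -0.66,
        }
    )
    mean_end_shift_urban_h: Mapping[str, float] = field(
        default_factory=lambda: {
            "blackbird": 0.40, "robin": 0.20, "great_tit": 0.10,
            "blue_tit": 0.10, "dunnock": 0.15, "chaffinch": 0.60,
        }
    )
    season_effect_onset_h: Mapping[str, float] = field(
        default_factory=lambda: {"pre_breeding": -0.10, "post_breeding": 0.0}
    )
    season_effect_end_h: Mapping[str, float] = field(
        default_factory=lambda: {"pre_breeding": 0.0, "post_breeding": 0.0}
    )
    year_effect_end_h: Mapping[int, float] = field(
        default_factory=lambda: {2020: 0.0, 2021: -0.15}
    )
    tmin_effect_end_h_per_c: float = -0.02
    sex_onset_shift_h: float = 0.0  # male minus female
    sex_end_shift_h: float = 0.0

    between_sd_onset_h: Mapping[str, float] = field(
        default_factory=lambda: _per_habitat(0.35, 0.25)
    )
    within_sd_onset_h: Mapping[str, float] = field(
        default_factory=lambda: _per_habitat(0.81, 0.55)
    )
    between_sd_end_h: Mapping[str, float] = field(
        default_factory=lambda: _per_habitat(0.31, 0.21)
    )
    within_sd_end_h: Mapping[str, float] = field(
        default_factory=lambda: _per_habitat(0.88, 0.83)
    )
    site_sd_h: float = 0.10
    date_sd_h: float = 0.25

    # --- activity levels (per-slot probabilities; heterogeneity on logit) ---
    diurnal_active_prob: Mapping[str, float] = field(
        default_factory=lambda: _per_habitat(0.485, 0.497)
    )
    nocturnal_active_prob: Mapping[str, float] = field(
        default_factory=lambda: _per_habitat(0.041, 0.016)
    )
    between_sd_logit_diurnal: Mapping[str, float] = field(
        default_factory=lambda: _per_habitat(0.42, 0.60)
    )
    within_sd_logit_diurnal: Mapping[str, float] = field(
        default_factory=lambda: _per_habitat(0.46, 0.70)
    )
    between_sd_logit_nocturnal: Mapping[str, float] = field(
        default_factory=lambda: _per_habitat(1.00, 1.00)
    )
    within_sd_logit_nocturnal: Mapping[str, float] = field(
        default_factory=lambda: _per_habitat(1.00, 1.30)
    )
    corr_between_diurnal_nocturnal: Mapping[str, float] = field(
        default_factory=lambda: _per_habitat(0.05, -0.20)
    )
    corr_within_diurnal_nocturnal: Mapping[str, float] = field(
        default_factory=lambda: _per_habitat(0.00, -0.30)
    )

    # --- signal and detection model ---
    signal_noise_inactive_dB: float = 2.0
    signal_step_active_dB: float = 20.0
    detection_prob: float = 0.85
    out_of_range_prob_per_day: float = 0.30
    out_of_range_len_h: tuple[float, float] = (2.0, 12.0)
    n_receivers_per_site: int = 3
    scan_interval_s: int = 180

    # --- climate (AR(1) around seasonal means) ---
    tmin_season_mean_c: Mapping[str, float] = field(
        default_factory=lambda: {"pre_breeding": 3.5, "post_breeding": 8.0}
    )
    tmin_sd_c: float = 2.5
    tmin_ar1: float = 0.6
    precip_mean_mm: float = 2.0
    precip_sd_mm: float = 3.0
    precip_ar1: float = 0.3

    seed: int = 42

    # ------------------------------------------------------------------
    def validate(self) -> None:
        def check_prob(name: str, value) -> None:
            vals = value.values() if isinstance(value, Mapping) else [value]
            if any(not (0.0 <= v <= 1.0) for v in vals):
                raise ConfigError(f"{name} must lie in [0, 1]")

        def check_nonneg(name: str, value) -> None:
            vals = value.values() if isinstance(value, Mapping) else [value]
            if any(v < 0 for v in vals):
                raise ConfigError(f"{name} must be >= 0")

        if self.n_birds_per_species_per_habitat < 1:
            raise ConfigError("n_birds_per_species_per_habitat must be >= 1")
        if self.n_days < 1:
            raise ConfigError("n_days must be >= 1")
        if not 2 <= self.n_receivers_per_site <= 4:
            raise ConfigError("n_receivers_per_site must be in 2..4")
        if 86400 % self.scan_interval_s != 0:
            raise ConfigError("scan_interval_s must divide 86400")
        if not (0.0 < self.detection_prob <= 1.0):
            raise ConfigError("detection_prob must be in (0, 1]")
        check_prob("diurnal_active_prob", self.diurnal_active_prob)
        check_prob("nocturnal_active_prob", self.nocturnal_active_prob)
        check_prob("out_of_range_prob_per_day", self.out_of_range_prob_per_day)
        for name in (
            "between_sd_onset_h", "within_sd_onset_h", "between_sd_end_h",
            "within_sd_end_h", "between_sd_logit_diurnal", "within_sd_logit_diurnal",
            "between_sd_logit_nocturnal", "within_sd_logit_nocturnal",
        ):
            check_nonneg(name, getattr(self, name))
        check_nonneg("signal_noise_inactive_dB", self.signal_noise_inactive_dB)
        if self.signal_step_active_dB <= 0:
            raise ConfigError("signal_step_active_dB must be > 0")
        for name in ("corr_between_diurnal_nocturnal", "corr_within_diurnal_nocturnal"):
            if any(not (-1.0 <= v <= 1.0) for v in getattr(self, name).values()):
                raise ConfigError(f"{name} must lie in [-1, 1]")
        for name in (
            "species_base_onset_h", "mean_onset_shift_urban_h",
            "species_base_end_h", "mean_end_shift_urban_h",
        ):
            missing = set(self.species_list) - set(getattr(self, name))
            if missing:
                raise ConfigError(f"{name} missing species {sorted(missing)}")
        for name in ("seasons",):
            missing = set(self.seasons) - set(self.season_start)
            if missing:
                raise ConfigError(f"season_start missing seasons {sorted(missing)}")

    # ------------------------------------------------------------------
    def to_yaml(self, path: str | Path) -> None:
        d = asdict(self)
        d["species_list"] = list(self.species_list)
        d["habitats"] = list(self.habitats)
        d["seasons"] = list(self.seasons)
        d["years"] = list(self.years)
        d["season_start"] = {k: list(v) for k, v in self.season_start.items()}
        d["out_of_range_len_h"] = list(self.out_of_range_len_h)
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimulationConfig":
        d = yaml.safe_load(Path(path).read_text())
        for key in ("species_list", "habitats", "seasons", "years"):
            if key in d:
                d[key] = tuple(d[key])
        if "season_start" in d:
            d["season_start"] = {k: tuple(v) for k, v in d["season_start"].items()}
        if "out_of_range_len_h" in d:
            d["out_of_range_len_h"] = tuple(d["out_of_range_len_h"])
        if "year_effect_end_h" in d:
            d["year_effect_end_h"] = {int(k): v for k, v in d["year_effect_end_h"].items()}
        cfg = cls(**d)
        cfg.validate()
        return cfg


@dataclass
class DaySchedule:
    """Ground-truth activity schedule of one bird on one date.

    ``active_mask`` covers the 3-min grid from local midnight of ``date`` to
    02:00 local on the following day, so the night-of-``date`` nocturnal
    window (22:00-02:00) is owned entirely by this schedule.  Slots in
    00:00-02:00 of ``date`` itself are always inactive here -- they belong to
    the previous night's schedule.
    """

    bird_id: str
    date: _date
    true_onset: pd.Timestamp
    true_end: pd.Timestamp
    nocturnal_bouts: list[tuple[pd.Timestamp, pd.Timestamp]]
    active_mask: pd.Series  # bool, indexed by slot-start timestamps

    def __post_init__(self) -> None:
        if not self.true_onset < self.true_end:
            raise ValueError("true_onset must precede true_end")


@dataclass
class SyntheticStudy:
    """Bundle of raw detections, metadata, climate and truth tables."""

    detections: pd.DataFrame
    birds: pd.DataFrame
    sites: pd.DataFrame
    climate: pd.DataFrame
    truth: pd.DataFrame
    solar: pd.DataFrame
    config: SimulationConfig

    def to_dir(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        det = self.detections.copy()
        det["timestamp"] = det["timestamp"].map(lambda t: t.isoformat())
        det.to_csv(out / "detections.csv", index=False)
        self.birds.to_csv(out / "birds.csv", index=False)
        self.sites.to_csv(out / "sites.csv", index=False)
        self.climate.to_csv(out / "climate.csv", index=False)
        tr = self.truth.copy()
        for col in ("true_onset", "true_end"):
            tr[col] = tr[col].map(lambda t: t.isoformat())
        tr.to_csv(out / "truth.csv", index=False)
        so = self.solar.copy()
        for col in ("sunrise", "sunset"):
            so[col] = so[col].map(lambda t: t.isoformat())
        so.to_csv(out / "solar.csv", index=False)
        self.config.to_yaml(out / "sim_config.yaml")


# ----------------------------------------------------------------------
# helpers

def default_sites(config: SimulationConfig) -> pd.DataFrame:
    """Site metadata: two urban sites in Glasgow, two forest sites at Loch Lomond."""
    catalogue = {
        "urban": [
            ("urban_kelvingrove", 55.8697, -4.2870),
            ("urban_garscube", 55.9037, -4.3200),
            ("urban_botanics", 55.8786, -4.2900),
            ("urban_queens_park", 55.8290, -4.2680),
        ],
        "forest": [
            ("forest_scene", 56.1288, -4.6132),
            ("forest_sallochy", 56.1237, -4.6012),
            ("forest_ross_wood", 56.1100, -4.6300),
            ("forest_inchcailloch", 56.0840, -4.5570),
        ],
    }
    rows = []
    for habitat in config.habitats:
        for site_id, lat, lon in catalogue[habitat][: config.sites_per_habitat]:
            rows.append(
                {
                    "site_id": site_id,
                    "habitat": habitat,
                    "latitude": lat,
                    "longitude": lon,
                    "timezone": "Europe/London",
                }
            )
    return pd.DataFrame(rows)


def _crc(text: str) -> int:
    return zlib.crc32(text.encode())


def _rng(seed: int, *keys: int) -> np.random.Generator:
    """Deterministic substream keyed by stable integers (bird/site/date ids)."""
    return np.random.default_rng(np.random.SeedSequence([seed & 0x7FFFFFFF, *keys]))


import functools


def _logit_normal_mean(mu: float, sigma: float, nodes: int = 41) -> float:
    x, w = np.polynomial.hermite_e.hermegauss(nodes)
    return float(np.sum(w * special.expit(mu + sigma * x)) / np.sum(w))


@functools.lru_cache(maxsize=256)
def _solve_base_logit(target: float, sigma: float) -> float:
    """Logit-scale intercept whose logit-normal mean equals the target proportion."""
    if target >= 1.0:
        return 30.0
    if target <= 0.0:
        return -30.0
    if sigma == 0.0:
        return float(special.logit(target))
    return float(
        optimize.brentq(lambda m: _logit_normal_mean(m, sigma) - target, -15.0, 15.0)
    )


def _block_dates(config: SimulationConfig, year: int, season: str) -> list[_date]:
    m, d = config.season_start[season]
    start = _date(year, m, d)
    return [start + timedelta(days=i) for i in range(config.n_days)]


def _day_grid(date: _date, tz: str, interval_s: int) -> pd.DatetimeIndex:
    """Slot-start grid from local midnight of ``date`` to 02:00 local next day."""
    start = pd.Timestamp(date).tz_localize(tz)
    end = (pd.Timestamp(date) + pd.Timedelta(days=1, hours=2)).tz_localize(
        tz, ambiguous=True, nonexistent="shift_forward"
    )
    return pd.date_range(start, end, freq=f"{interval_s}s", inclusive="left")


# ----------------------------------------------------------------------
# roster and latent truth

def _build_roster(config: SimulationConfig, sites: pd.DataFrame) -> pd.DataFrame:
    rows = []
    for year in config.years:
        for season in config.seasons:
            for habitat in config.habitats:
                hab_sites = sites.loc[sites.habitat == habitat, "site_id"].tolist()
                for species in config.species_list:
                    for i in range(config.n_birds_per_species_per_habitat):
                        site = hab_sites[i % len(hab_sites)]
                        tag = f"{species}.{site}.{year}.{season}.{i:02d}"
                        rows.append(
                            {
                                "bird_id": tag,
                                "species": species,
                                "habitat": habitat,
                                "site_id": site,
                                "year": year,
                                "season": season,
                            }
                        )
    roster = pd.DataFrame(rows)
    # latent sex for every bird; recorded (known) only for the sexable species
    sex = np.array(
        ["male" if _rng(config.seed, 11, _crc(b)).random() < 0.5 else "female"
         for b in roster.bird_id]
    )
    roster["sex"] = sex
    roster["sex_known"] = roster.species.isin(SEXABLE_SPECIES)
    return roster


def _bird_latents(config: SimulationConfig, roster: pd.DataFrame) -> pd.DataFrame:
    """Per-bird between-individual deviations for all four traits."""
    rows = []
    for bird in roster.itertuples(index=False):
        rng = _rng(config.seed, 1, _crc(bird.bird_id))
        h = bird.habitat
        dev_onset = rng.normal(0.0, config.between_sd_onset_h[h])
        dev_end = rng.normal(0.0, config.between_sd_end_h[h])
        # correlated bivariate (diurnal, nocturnal) activity intercepts
        sd_d = config.between_sd_logit_diurnal[h]
        sd_n = config.between_sd_logit_nocturnal[h]
        rho = config.corr_between_diurnal_nocturnal[h]
        z1, z2 = rng.standard_normal(2)
        b_di = sd_d * z1
        b_no = sd_n * (rho * z1 + np.sqrt(max(0.0, 1 - rho**2)) * z2)
        rows.append(
            {
                "bird_id": bird.bird_id,
                "dev_onset_between_h": dev_onset,
                "dev_end_between_h": dev_end,
                "dev_diurnal_between_logit": b_di,
                "dev_nocturnal_between_logit": b_no,
            }
        )
    return pd.DataFrame(rows)


def _simulate_climate(config: SimulationConfig, sites: pd.DataFrame) -> pd.DataFrame:
    rows = []
    for s_idx, site in enumerate(sites.itertuples(index=False)):
        for year in config.years:
            for sn_idx, season in enumerate(config.seasons):
                rng = _rng(config.seed, 4, s_idx, year, sn_idx)
                mu = config.tmin_season_mean_c[season]
                phi, sd = config.tmin_ar1, config.tmin_sd_c
                phi_p, sd_p = config.precip_ar1, config.precip_sd_mm
                t = mu + sd * rng.standard_normal()
                p = config.precip_mean_mm + sd_p * rng.standard_normal()
                for d in _block_dates(config, year, season):
                    t = mu + phi * (t - mu) + sd * np.sqrt(1 - phi**2) * rng.standard_normal()
                    p = (
                        config.precip_mean_mm
                        + phi_p * (p - config.precip_mean_mm)
                        + sd_p * np.sqrt(1 - phi_p**2) * rng.standard_normal()
                    )
                    rows.append(
                        {
                            "site_id": site.site_id,
                            "date": d,
                            "tmin_c": round(t, 2),
                            "precip_mm": round(max(0.0, p), 2),
                        }
                    )
    return pd.DataFrame(rows)


def _site_effect(config: SimulationConfig, site_id: str, trait: int) -> float:
    return float(_rng(config.seed, 5, _crc(site_id), trait).normal(0.0, config.site_sd_h))


def _date_effect(config: SimulationConfig, d: _date, trait: int) -> float:
    return float(_rng(config.seed, 6, d.toordinal(), trait).normal(0.0, config.date_sd_h))


# ----------------------------------------------------------------------
# per-day schedule

def simulate_bird_day(
    bird,
    date: _date,
    solar_day: SolarDay,
    config: SimulationConfig,
    rng: np.random.Generator,
    *,
    tmin_c: float | None = None,
    day_devs: tuple[float, float] | None = None,
    activity_devs: tuple[float, float] | None = None,
) -> DaySchedule:
    """Ground-truth schedule for one bird-day.

    ``bird`` is a roster row (namedtuple/Series) carrying species, habitat,
    sex, season, year and the bird's between-individual deviations.  Day
    deviations and the within-day activity latents are drawn from ``rng``
    unless supplied.
    """
    h = bird.habitat
    tz = str(solar_day.sunrise.tz)

    if day_devs is None:
        day_devs = (
            rng.normal(0.0, config.within_sd_onset_h[h]),
            rng.normal(0.0, config.within_sd_end_h[h]),
        )
    e_onset, e_end = day_devs

    sex_on = config.sex_onset_shift_h if bird.sex == "male" else 0.0
    sex_en = config.sex_end_shift_h if bird.sex == "male" else 0.0
    urban = h == "urban"
    tmin_dev = 0.0
    if tmin_c is not None:
        tmin_dev = tmin_c - config.tmin_season_mean_c[bird.season]

    rel_onset = (
        config.species_base_onset_h[bird.species]
        + (config.mean_onset_shift_urban_h[bird.species] if urban else 0.0)
        + config.season_effect_onset_h.get(bird.season, 0.0)
        + sex_on
        + _site_effect(config, bird.site_id, 0)
        + _date_effect(config, date, 0)
        + bird.dev_onset_between_h
        + e_onset
    )
    rel_end = (
        config.species_base_end_h[bird.species]
        + (config.mean_end_shift_urban_h[bird.species] if urban else 0.0)
        + config.season_effect_end_h.get(bird.season, 0.0)
        + config.year_effect_end_h.get(bird.year, 0.0)
        + config.tmin_effect_end_h_per_c * tmin_dev
        + sex_en
        + _site_effect(config, bird.site_id, 1)
        + _date_effect(config, date, 1)
        + bird.dev_end_between_h
        + e_end
    )

    true_onset = solar_day.sunrise + pd.Timedelta(hours=rel_onset)
    true_end = solar_day.sunset + pd.Timedelta(hours=rel_end)
    if true_end <= true_onset:  # pathological draw; clamp to a 1-h day
        true_end = true_onset + pd.Timedelta(hours=1)

    if activity_devs is None:
        sd_d = config.within_sd_logit_diurnal[h]
        sd_n = config.within_sd_logit_nocturnal[h]
        rho = config.corr_within_diurnal_nocturnal[h]
        z1, z2 = rng.standard_normal(2)
        activity_devs = (
            sd_d * z1,
            sd_n * (rho * z1 + np.sqrt(max(0.0, 1 - rho**2)) * z2),
        )
    e_di, e_no = activity_devs

    sig_d = np.hypot(config.between_sd_logit_diurnal[h], config.within_sd_logit_diurnal[h])
    sig_n = np.hypot(config.between_sd_logit_nocturnal[h], config.within_sd_logit_nocturnal[h])
    p_di = special.expit(
        _solve_base_logit(config.diurnal_active_prob[h], sig_d)
        + bird.dev_diurnal_between_logit + e_di
    )
    p_no = special.expit(
        _solve_base_logit(config.nocturnal_active_prob[h], sig_n)
        + bird.dev_nocturnal_between_logit + e_no
    )

    grid = _day_grid(date, tz, config.scan_interval_s)
    n = len(grid)
    active = np.zeros(n, dtype=bool)

    in_day = (grid >= true_onset) & (grid < true_end)
    active[in_day] = rng.random(int(in_day.sum())) < p_di
    # the bird always moves when leaving the roost and when returning to it
    day_idx = np.nonzero(in_day)[0]
    if day_idx.size:
        active[day_idx[0]] = True
        active[day_idx[-1]] = True

    noct_start = (pd.Timestamp(date) + pd.Timedelta(hours=22)).tz_localize(
        tz, ambiguous=True, nonexistent="shift_forward"
    )
    noct_end = (pd.Timestamp(date) + pd.Timedelta(hours=26)).tz_localize(
        tz, ambiguous=True, nonexistent="shift_forward"
    )
    in_night = (grid >= noct_start) & (grid < noct_end) & ~in_day
    active[in_night] = rng.random(int(in_night.sum())) < p_no

    bouts: list[tuple[pd.Timestamp, pd.Timestamp]] = []
    step = pd.Timedelta(seconds=config.scan_interval_s)
    night_active = np.nonzero(active & in_night)[0]
    if night_active.size:
        splits = np.split(night_active, np.nonzero(np.diff(night_active) > 1)[0] + 1)
        bouts = [(grid[s[0]], grid[s[-1]] + step) for s in splits]

    mask = pd.Series(active, index=grid)
    return DaySchedule(
        bird_id=bird.bird_id,
        date=date,
        true_onset=true_onset,
        true_end=true_end,
        nocturnal_bouts=bouts,
        active_mask=mask,
    )


# ----------------------------------------------------------------------
# signals

def schedule_to_signal(
    active_mask: pd.Series,
    receivers: Sequence[str],
    config: SimulationConfig,
    rng: np.random.Generator,
    *,
    drop_slots: pd.DatetimeIndex | None = None,
) -> pd.DataFrame:
    """Detection records for one bird over a (possibly multi-day) active mask.

    ``active_mask`` is a boolean Series on the 3-min slot grid (as produced by
    :func:`simulate_bird_day` / merged across days).  One independent latent
    signal track is generated per receiver; each slot is then independently
    dropped with probability ``1 - detection_prob``.  ``drop_slots`` marks
    slots lost on all receivers (out-of-range episodes).
    """
    grid = active_mask.index
    n = len(grid)
    active = active_mask.to_numpy(dtype=bool)
    step = config.signal_step_active_dB
    frames = []
    for r_id in receivers:
        baseline = rng.uniform(-120.0, -60.0)
        offset_s = rng.uniform(0.0, 120.0)
        # side alternates at every active slot; magnitude refreshed per move
        flips = np.cumsum(active)
        side = np.where(flips % 2 == 0, 1.0, -1.0)
        mags = rng.uniform(step / 2.0, step / 2.0 + 10.0, size=n)
        move_idx = np.nonzero(active)[0]
        last_move = np.full(n, -1, dtype=np.int64)
        if move_idx.size:
            pos = np.searchsorted(move_idx, np.arange(n), side="right") - 1
            last_move = np.where(pos >= 0, move_idx[np.clip(pos, 0, None)], -1)
        init_mag = rng.uniform(step / 2.0, step / 2.0 + 10.0)
        mag = np.where(last_move >= 0, mags[np.clip(last_move, 0, None)], init_mag)
        latent = baseline + side * mag
        signal = latent + rng.normal(0.0, config.signal_noise_inactive_dB, size=n)

        detected = rng.random(n) < config.detection_prob
        if drop_slots is not None and len(drop_slots):
            detected &= ~grid.isin(drop_slots)
        frames.append(
            pd.DataFrame(
                {
                    "receiver_id": r_id,
                    "timestamp": grid[detected] + pd.Timedelta(seconds=round(offset_s)),
                    "signal_dB": np.round(signal[detected], 1),
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


# ----------------------------------------------------------------------
# whole study

def simulate_study(config: SimulationConfig) -> SyntheticStudy:
    """Simulate the full deployment: detections, metadata, climate and truth."""
    config.validate()
    sites = default_sites(config)
    roster = _build_roster(config, sites)
    latents = _bird_latents(config, roster)
    birds = roster.merge(latents, on="bird_id")
    climate = _simulate_climate(config, sites)
    climate_ix = climate.set_index(["site_id", "date"])

    site_meta = sites.set_index("site_id")

    # solar table for all site-dates
    solar_rows = []
    solar_cache: dict[tuple[str, _date], SolarDay] = {}
    for site in sites.itertuples(index=False):
        for year in config.years:
            for season in config.seasons:
                for d in _block_dates(config, year, season):
                    sd = solar_times(site.latitude, site.longitude, d, site.timezone, site.site_id)
                    solar_cache[(site.site_id, d)] = sd
                    solar_rows.append(
                        {"site_id": site.site_id, "date": d, "sunrise": sd.sunrise, "sunset": sd.sunset}
                    )
    solar_df = pd.DataFrame(solar_rows)

    truth_rows = []
    detection_frames = []
    receiver_ids = {
        s: [f"{s}.rx{i+1}" for i in range(config.n_receivers_per_site)]
        for s in sites.site_id
    }

    for bird in birds.itertuples(index=False):
        tz = site_meta.loc[bird.site_id, "timezone"]
        dates = _block_dates(config, bird.year, bird.season)
        masks = []
        drop_all: list[pd.DatetimeIndex] = []
        for d_idx, d in enumerate(dates):
            rng_day = _rng(config.seed, 2, _crc(bird.bird_id), d.toordinal())
            sd = solar_cache[(bird.site_id, d)]
            tmin = float(climate_ix.loc[(bird.site_id, d), "tmin_c"])
            sched = simulate_bird_day(bird, d, sd, config, rng_day, tmin_c=tmin)

            # out-of-range episode: bird leaves the receiver array entirely
            if rng_day.random() < config.out_of_range_prob_per_day:
                lo, hi = config.out_of_range_len_h
                length = rng_day.uniform(lo, hi)
                start_h = rng_day.uniform(0.0, 24.0 - length)
                ep0 = sched.active_mask.index[0] + pd.Timedelta(hours=start_h)
                ep1 = ep0 + pd.Timedelta(hours=length)
                drop_all.append(sched.active_mask.index[(sched.active_mask.index >= ep0)
                                                        & (sched.active_mask.index < ep1)])

            masks.append(sched.active_mask)
            n_night = sum(
                int((b1 - b0) / pd.Timedelta(seconds=config.scan_interval_s))
                for b0, b1 in sched.nocturnal_bouts
            )
            truth_rows.append(
                {
                    "bird_id": bird.bird_id,
                    "site_id": bird.site_id,
                    "species": bird.species,
                    "habitat": bird.habitat,
                    "season": bird.season,
                    "year": bird.year,
                    "date": d,
                    "true_onset": sched.true_onset,
                    "true_end": sched.true_end,
                    "true_rel_onset_h": (sched.true_onset - sd.sunrise).total_seconds() / 3600.0,
                    "true_rel_end_h": (sched.true_end - sd.sunset).total_seconds() / 3600.0,
                    "n_nocturnal_active_slots": n_night,
                }
            )

        # merge per-day masks (nocturnal spillover ORs into the next day)
        full = pd.concat(masks)
        full = full.groupby(full.index).any().sort_index()
        rng_sig = _rng(config.seed, 3, _crc(bird.bird_id))
        drop_idx = drop_all[0].append(drop_all[1:]) if drop_all else None
        det = schedule_to_signal(
            full, receiver_ids[bird.site_id], config, rng_sig, drop_slots=drop_idx
        )
        det.insert(0, "tag_id", bird.bird_id)
        detection_frames.append(det)

    detections = pd.concat(detection_frames, ignore_index=True)
    detections = detections.sort_values(["tag_id", "receiver_id", "timestamp"]).reset_index(drop=True)
    truth = pd.DataFrame(truth_rows)
    birds_out = birds.copy()
    birds_out.loc[~birds_out.sex_known, "sex"] = ""
    return SyntheticStudy(
        detections=detections,
        birds=birds_out,
        sites=sites,
        climate=climate,
        truth=truth,
        solar=solar_df,
        config=config,
    )


# ----------------------------------------------------------------------
# trait-level generators (no signal layer) for model validation

def simulate_timing_dataset(
    config: SimulationConfig | None = None,
    *,
    n_birds_per_cell: int = 13,
    n_days: int = 20,
    seasons: Sequence[str] = ("pre_breeding",),
    years: Sequence[int] = (2020,),
    seed: int = 0,
) -> pd.DataFrame:
    """Relative onset/end observations drawn directly from the latent trait model.

    Bypasses the signal/detection layer: responses are the generator's true
    relative times, so hierarchical-model fits can be validated against the
    configured variance components without change-point estimation error.
    """
    if config is None:
        config = SimulationConfig()
    config = replace(
        config,
        n_birds_per_species_per_habitat=n_birds_per_cell,
        n_days=n_days,
        seasons=tuple(seasons),
        years=tuple(years),
        seed=seed,
    )
    config.validate()
    sites = default_sites(config)
    roster = _build_roster(config, sites)
    latents = _bird_latents(config, roster)
    birds = roster.merge(latents, on="bird_id")
    climate = _simulate_climate(config, sites).set_index(["site_id", "date"])

    rows = []
    for bird in birds.itertuples(index=False):
        for d in _block_dates(config, bird.year, bird.season):
            rng = _rng(config.seed, 2, _crc(bird.bird_id), d.toordinal())
            h = bird.habitat
            e_onset = rng.normal(0.0, config.within_sd_onset_h[h])
            e_end = rng.normal(0.0, config.within_sd_end_h[h])
            tmin = float(climate.loc[(bird.site_id, d), "tmin_c"])
            precip = float(climate.loc[(bird.site_id, d), "precip_mm"])
            urban = h == "urban"
            sex_on = config.sex_onset_shift_h if bird.sex == "male" else 0.0
            sex_en = config.sex_end_shift_h if bird.sex == "male" else 0.0
            rel_onset = (
                config.species_base_onset_h[bird.species]
                + (config.mean_onset_shift_urban_h[bird.species] if urban else 0.0)
                + config.season_effect_onset_h.get(bird.season, 0.0)
                + sex_on
                + _site_effect(config, bird.site_id, 0)
                + _date_effect(config, d, 0)
                + bird.dev_onset_between_h
                + e_onset
            )
            rel_end = (
                config.species_base_end_h[bird.species]
                + (config.mean_end_shift_urban_h[bird.species] if urban else 0.0)
                + config.season_effect_end_h.get(bird.season, 0.0)
                + config.year_effect_end_h.get(bird.year, 0.0)
                + config.tmin_effect_end_h_per_c * (tmin - config.tmin_season_mean_c[bird.season])
                + sex_en
                + _site_effect(config, bird.site_id, 1)
                + _date_effect(config, d, 1)
                + bird.dev_end_between_h
                + e_end
            )
            rows.append(
                {
                    "bird_id": bird.bird_id,
                    "site_id": bird.site_id,
                    "species": bird.species,
                    "habitat": h,
                    "season": bird.season,
                    "year": bird.year,
                    "sex": bird.sex,
                    "sex_known": bird.sex_known,
                    "date": d,
                    "relative_onset_h": rel_onset,
                    "relative_end_h": rel_end,
                    "tmin_c": tmin,
                    "precip_mm": precip,
                }
            )
    return pd.DataFrame(rows)


def simulate_activity_dataset(
    config: SimulationConfig | None = None,
    *,
    n_birds_per_cell: int = 5,
    n_days: int = 10,
    seasons: Sequence[str] = ("pre_breeding",),
    years: Sequence[int] = (2020,),
    n_diurnal_slots: int = 120,
    n_nocturnal_slots: int = 80,
    seed: int = 0,
) -> pd.DataFrame:
    """Per bird-day active/scored counts drawn directly from the latent model.

    Counts are binomial given the bird-day probability, whose logit carries
    correlated between-bird and between-day (observation-level) deviations.
    """
    if config is None:
        config = SimulationConfig()
    config = replace(
        config,
        n_birds_per_species_per_habitat=n_birds_per_cell,
        n_days=n_days,
        seasons=tuple(seasons),
        years=tuple(years),
        seed=seed,
    )
    config.validate()
    sites = default_sites(config)
    roster = _build_roster(config, sites)
    latents = _bird_latents(config, roster)
    birds = roster.merge(latents, on="bird_id")
    climate = _simulate_climate(config, sites).set_index(["site_id", "date"])

    base = {}
    for h in config.habitats:
        sig_d = np.hypot(config.between_sd_logit_diurnal[h], config.within_sd_logit_diurnal[h])
        sig_n = np.hypot(config.between_sd_logit_nocturnal[h], config.within_sd_logit_nocturnal[h])
        base[h] = (
            _solve_base_logit(config.diurnal_active_prob[h], sig_d),
            _solve_base_logit(config.nocturnal_active_prob[h], sig_n),
        )

    rows = []
    for bird in birds.itertuples(index=False):
        h = bird.habitat
        for d in _block_dates(config, bird.year, bird.season):
            rng = _rng(config.seed, 7, _crc(bird.bird_id), d.toordinal())
            sd_d = config.within_sd_logit_diurnal[h]
            sd_n = config.within_sd_logit_nocturnal[h]
            rho = config.corr_within_diurnal_nocturnal[h]
            z1, z2 = rng.standard_normal(2)
            e_di = sd_d * z1
            e_no = sd_n * (rho * z1 + np.sqrt(max(0.0, 1 - rho**2)) * z2)
            p_di = special.expit(base[h][0] + bird.dev_diurnal_between_logit + e_di)
            p_no = special.expit(base[h][1] + bird.dev_nocturnal_between_logit + e_no)
            common = {
                "bird_id": bird.bird_id,
                "site_id": bird.site_id,
                "species": bird.species,
                "habitat": h,
                "season": bird.season,
                "year": bird.year,
                "date": d,
                "tmin_c": float(climate.loc[(bird.site_id, d), "tmin_c"]),
                "precip_mm": float(climate.loc[(bird.site_id, d), "precip_mm"]),
            }
            rows.append(
                {
                    **common,
                    "window": "diurnal",
                    "n_scored": n_diurnal_slots,
                    "n_active": int(rng.binomial(n_diurnal_slots, p_di)),
                }
            )
            rows.append(
                {
                    **common,
                    "window": "nocturnal",
                    "n_scored": n_nocturnal_slots,
                    "n_active": int(rng.binomial(n_nocturnal_slots, p_no)),
                }
            )
    df = pd.DataFrame(rows)
    df["proportion"] = df.n_active / df.n_scored
    return df
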