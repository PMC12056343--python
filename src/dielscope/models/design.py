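"""Fixed- and random-effect design construction shared by all model fits.

The fixed-effect structure mirrors the study design: habitat (urban vs
forest reference), species, time of year (pre- vs post-breeding), year,
standardized daily minimum temperature and precipitation, plus the
habitat x species and habitat x season interactions (and, for the sex
models, sex and its interactions with habitat, season and species).
Factors observed at a single level are dropped from the design together
with their interactions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["ModelSpec", "DesignInfo", "build_design", "RankDeficiencyError"]


class RankDeficiencyError(ValueError):
    """The fixed-effect design matrix is not full column rank."""


@dataclass
class ModelSpec:
    """Sampling configuration for one model fit."""

    response: str = "relative_onset_h"
    chains: int = 4
    warmup: int = 800
    draws: int = 3000
    thin_location: int = 4     # thinning for exact location-parameter draws
    seed: int = 0
    prior_sd_scale: float = 2.5    # half-t(3) scale multiplier on response SD
    beta_prior_mult: float = 10.0  # Normal prior SD on slopes, x response SD
    # JAGS-specific (binomial models)
    n_adapt: int = 1000
    n_burn: int = 1000
    n_iter: int = 3000
    thin: int = 2
    max_rhat: float = 1.01


@dataclass
class DesignInfo:
    """Design matrix plus the factor bookkeeping needed for contrasts."""

    X: np.ndarray
    colnames: list[str]
    species_levels: list[str]
    season_levels: list[str]
    habitat_ref: str = "forest"
    species_ref: str = ""
    season_ref: str = ""
    scales: dict = field(default_factory=dict)


def _zscore(x: pd.Series) -> tuple[np.ndarray, float, float]:
    mu = float(x.mean())
    sd = float(x.std(ddof=0))
    if sd == 0:
        return np.zeros(len(x)), mu, 1.0
    return ((x - mu) / sd).to_numpy(), mu, sd


def build_design(df: pd.DataFrame, *, include_sex: bool = False) -> DesignInfo:
    """Fixed-effect design matrix with treatment coding.

    Reference levels: forest habitat, alphabetically-first species, first
    season level sorted (post_breeding), smallest year.  Continuous
    covariates are centred and scaled per fit.

    Raises
    ------
    RankDeficiencyError
        if the resulting matrix is rank deficient (e.g. a single-sex input
        to a sex model), naming the offending structure.
    """
    n = len(df)
    cols: list[np.ndarray] = [np.ones(n)]
    names: list[str] = ["intercept"]

    urban = (df["habitat"] == "urban").to_numpy(dtype=float)
    habitats = sorted(df["habitat"].unique())
    if len(habitats) > 1:
        cols.append(urban)
        names.append("habitat_urban")

    species_levels = sorted(df["species"].unique())
    species_ref = species_levels[0]
    sp_dummies = {}
    for s in species_levels[1:]:
        d = (df["species"] == s).to_numpy(dtype=float)
        sp_dummies[s] = d
        cols.append(d)
        names.append(f"species_{s}")

    season_levels = sorted(df["season"].unique())
    season_ref = season_levels[0]
    sn_dummies = {}
    for t in season_levels[1:]:
        d = (df["season"] == t).to_numpy(dtype=float)
        sn_dummies[t] = d
        cols.append(d)
        names.append(f"season_{t}")

    year_levels = sorted(df["year"].unique())
    for yv in year_levels[1:]:
        cols.append((df["year"] == yv).to_numpy(dtype=float))
        names.append(f"year_{yv}")

    scales = {}
    for raw, name in (("tmin_c", "tmin_z"), ("precip_mm", "precip_z")):
        if raw in df.columns:
            z, mu, sd = _zscore(df[raw])
            scales[name] = (mu, sd)
            cols.append(z)
            names.append(name)

    if len(habitats) > 1:
        for s, d in sp_dummies.items():
            cols.append(urban * d)
            names.append(f"habitat_urban:species_{s}")
        for t, d in sn_dummies.items():
            cols.append(urban * d)
            names.append(f"habitat_urban:season_{t}")

    if include_sex:
        sex_levels = sorted(df["sex"].unique())
        if len(sex_levels) < 2:
            raise RankDeficiencyError(
                f"sex model needs both sexes; found only {sex_levels}"
            )
        male = (df["sex"] == "male").to_numpy(dtype=float)
        cols.append(male)
        names.append("sex_male")
        if len(habitats) > 1:
            cols.append(male * urban)
            names.append("sex_male:habitat_urban")
        for t, d in sn_dummies.items():
            cols.append(male * d)
            names.append(f"sex_male:season_{t}")
        for s, d in sp_dummies.items():
            cols.append(male * d)
            names.append(f"sex_male:species_{s}")

    X = np.column_stack(cols)
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        raise RankDeficiencyError(
            f"fixed-effect design is rank deficient (rank {rank} < {X.shape[1]} columns); "
            "check for empty factor combinations"
        )
    return DesignInfo(
        X=X,
        colnames=names,
        species_levels=species_levels,
        season_levels=season_levels,
        species_ref=species_ref,
        season_ref=season_ref,
        scales=scales,
    )
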