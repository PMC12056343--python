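"""Binomial GLMMs for diurnal/nocturnal activity levels (JAGS engine).

Responses are per bird-day-window counts (n_active of n_scored 3-min
slots).  The fixed-effect structure matches the timing models; random
structure: site and date intercepts, habitat-specific bird intercept SDs
(between-individual variation) and a habitat-specific observation-level
random effect (OLRE) supplying the within-individual variance analogue on
the logit scale.  The bivariate model couples the diurnal and nocturnal
responses through habitat-specific between-individual and OLRE-level
correlations, testing the hypothesised nocturnal/diurnal trade-off.

Priors: half-Student-t(3, 0, 2.5) on all SDs (logit scale), N(0, 5^2) on
fixed effects, Uniform(-1, 1) on correlations.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import special

from .design import ModelSpec, build_design
from .jags import run_jags
from .posterior import PosteriorSummary, _rhat_ess

__all__ = ["fit_activity_model", "fit_bivariate_activity_model"]

_HAB_ORDER = ("urban", "forest")  # JAGS habitat index 1 = urban, 2 = forest

_PRIORS = """
  for (k in 1:P) { beta[k] ~ dnorm(0, 0.04) }
  for (h in 1:2) {
    sigma_B[h] ~ dt(0, 0.16, 3) T(0,)
    tau_B[h] <- pow(sigma_B[h], -2)
    sigma_W[h] ~ dt(0, 0.16, 3) T(0,)
    tau_W[h] <- pow(sigma_W[h], -2)
  }
  sigma_site ~ dt(0, 0.16, 3) T(0,)
  tau_site <- pow(sigma_site, -2)
  sigma_date ~ dt(0, 0.16, 3) T(0,)
  tau_date <- pow(sigma_date, -2)
"""

# the OLRE is non-centered (e = sigma_W * z): with sparse counts the
# observation-level effects are prior-dominated and the centered form
# funnels badly
_UNIVARIATE_MODEL = """
model {
  mu <- X %*% beta
  for (i in 1:N) {
    y[i] ~ dbin(p[i], size[i])
    logit(p[i]) <- mu[i] + u_site[site[i]] + u_date[date[i]] + b[bird[i]] + sigma_W[hab[i]] * z[i]
    z[i] ~ dnorm(0, 1)
  }
  for (j in 1:J) { b[j] ~ dnorm(0, tau_B[habb[j]]) }
  for (s in 1:S) { u_site[s] ~ dnorm(0, tau_site) }
  for (d in 1:D) { u_date[d] ~ dnorm(0, tau_date) }
""" + _PRIORS + "}\n"

# diurnal components (data-rich) are centered; nocturnal components
# (sparse counts) are non-centered given the diurnal member of the pair
_BIVARIATE_MODEL = """
model {
  mud <- Xd %*% betad
  mun <- Xn %*% betan
  for (i in 1:N) {
    yd[i] ~ dbin(pd[i], sized[i])
    yn[i] ~ dbin(pn[i], sizen[i])
    logit(pd[i]) <- mud[i] + u_site_d[site[i]] + u_date_d[date[i]] + b1[bird[i]] + e1[i]
    logit(pn[i]) <- mun[i] + u_site_n[site[i]] + u_date_n[date[i]] + b2[bird[i]] + e2[i]
    e1[i] ~ dnorm(0, tau_Wd[hab[i]])
    z2[i] ~ dnorm(0, 1)
    e2[i] <- rho_W[hab[i]] * sigma_Wn[hab[i]] / sigma_Wd[hab[i]] * e1[i]
             + sigma_Wn[hab[i]] * sqrt(1 - pow(rho_W[hab[i]], 2)) * z2[i]
  }
  for (j in 1:J) {
    b1[j] ~ dnorm(0, tau_Bd[habb[j]])
    b2[j] ~ dnorm(rho_B[habb[j]] * sigma_Bn[habb[j]] / sigma_Bd[habb[j]] * b1[j],
                  tau_Bc[habb[j]])
  }
  for (s in 1:S) {
    u_site_d[s] ~ dnorm(0, tau_site_d)
    u_site_n[s] ~ dnorm(0, tau_site_n)
  }
  for (d in 1:D) {
    u_date_d[d] ~ dnorm(0, tau_date_d)
    u_date_n[d] ~ dnorm(0, tau_date_n)
  }
  for (k in 1:Pd) { betad[k] ~ dnorm(0, 0.04) }
  for (k in 1:Pn) { betan[k] ~ dnorm(0, 0.04) }
  for (h in 1:2) {
    sigma_Bd[h] ~ dt(0, 0.16, 3) T(0,)
    tau_Bd[h] <- pow(sigma_Bd[h], -2)
    sigma_Bn[h] ~ dt(0, 0.16, 3) T(0,)
    tau_Bc[h] <- 1.0 / (pow(sigma_Bn[h], 2) * (1 - pow(rho_B[h], 2)))
    sigma_Wd[h] ~ dt(0, 0.16, 3) T(0,)
    tau_Wd[h] <- pow(sigma_Wd[h], -2)
    sigma_Wn[h] ~ dt(0, 0.16, 3) T(0,)
    rho_B[h] ~ dunif(-0.99, 0.99)
    rho_W[h] ~ dunif(-0.99, 0.99)
  }
  sigma_site_d ~ dt(0, 0.16, 3) T(0,)
  tau_site_d <- pow(sigma_site_d, -2)
  sigma_site_n ~ dt(0, 0.16, 3) T(0,)
  tau_site_n <- pow(sigma_site_n, -2)
  sigma_date_d ~ dt(0, 0.16, 3) T(0,)
  tau_date_d <- pow(sigma_date_d, -2)
  sigma_date_n ~ dt(0, 0.16, 3) T(0,)
  tau_date_n <- pow(sigma_date_n, -2)
}
"""


def _codes(values: pd.Series) -> tuple[np.ndarray, pd.Index]:
    codes, levels = pd.factorize(values, sort=True)
    return codes + 1, levels  # JAGS is 1-based


def _marginal_profile(beta: np.ndarray, colnames: list[str], habitat: str,
                      species: list[str], seasons: list[str]) -> np.ndarray:
    """Linear predictor of the marginal (species/season-averaged) profile."""
    eta = beta[..., colnames.index("intercept")].copy()

    def add_avg(prefix: str, levels: list[str]) -> None:
        nonlocal eta
        if len(levels) < 2:
            return
        terms = []
        for lv in levels:
            name = f"{prefix}{lv}"
            terms.append(
                beta[..., colnames.index(name)] if name in colnames else 0.0
            )
        eta = eta + np.mean(np.broadcast_arrays(*terms), axis=0)

    add_avg("species_", species)
    add_avg("season_", seasons)
    if habitat == "urban" and "habitat_urban" in colnames:
        eta += beta[..., colnames.index("habitat_urban")]
        add_avg("habitat_urban:species_", species)
        add_avg("habitat_urban:season_", seasons)
    return eta


def _logit_normal_mean(mu: np.ndarray, sigma: np.ndarray, nodes: int = 21) -> np.ndarray:
    x, w = np.polynomial.hermite_e.hermegauss(nodes)
    w = w / w.sum()
    return np.sum(
        w * special.expit(mu[..., None] + sigma[..., None] * x), axis=-1
    )


def fit_activity_model(
    levels: pd.DataFrame, window: str, spec: ModelSpec
) -> PosteriorSummary:
    """Fit the binomial GLMM for one window ('diurnal' or 'nocturnal').

    ``levels`` needs columns n_active, n_scored, window, bird_id, site_id,
    date, habitat, species, season, year, tmin_c, precip_mm; only rows for
    the requested window are used.  Population-level active proportions per
    habitat (``prop_urban``/``prop_forest`` draws) are derived by the
    inverse link of the marginal predictions, integrating the random
    effects by quadrature.
    """
    df = levels.loc[levels["window"] == window].reset_index(drop=True)
    if df.empty:
        raise ValueError(f"no rows for window {window!r}")
    if (df["n_active"] > df["n_scored"]).any():
        raise ValueError("n_active exceeds n_scored")
    design = build_design(df)
    site, _ = _codes(df["site_id"])
    date, _ = _codes(df["date"])
    bird, bird_levels = _codes(df["bird_id"])
    hab_obs = np.where(df["habitat"].to_numpy() == "urban", 1, 2)
    habb = (
        df.assign(_b=bird).groupby("_b")["habitat"].first().sort_index()
        .map({"urban": 1, "forest": 2}).to_numpy()
    )
    data = {
        "y": df["n_active"].to_numpy(int),
        "size": df["n_scored"].to_numpy(int),
        "X": design.X,
        "N": len(df),
        "P": design.X.shape[1],
        "J": len(bird_levels),
        "S": int(site.max()),
        "D": int(date.max()),
        "site": site,
        "date": date,
        "bird": bird,
        "hab": hab_obs,
        "habb": habb,
    }
    inits = {
        "beta": np.zeros(design.X.shape[1]),
        "sigma_B": [0.5, 0.5],
        "sigma_W": [0.5, 0.5],
        "sigma_site": 0.3,
        "sigma_date": 0.3,
    }
    params = ["beta", "sigma_B", "sigma_W", "sigma_site", "sigma_date"]

    def run(factor: int) -> dict[str, np.ndarray]:
        return run_jags(
            _UNIVARIATE_MODEL, data, params,
            n_chains=max(3, min(spec.chains, 4)),
            n_adapt=spec.n_adapt * factor, n_burn=spec.n_burn * factor,
            n_iter=spec.n_iter * factor, thin=spec.thin,
            seed=spec.seed, inits=inits,
        )

    raw = run(1)
    draws, beta_draws = _pack_univariate(raw, design)
    diag = _rhat_ess({k: v for k, v in draws.items() if k.startswith("sigma")})
    converged = bool((diag["rhat"] < spec.max_rhat).all())
    if not converged:
        raw = run(2)
        draws, beta_draws = _pack_univariate(raw, design)
        diag = _rhat_ess({k: v for k, v in draws.items() if k.startswith("sigma")})
        converged = bool((diag["rhat"] < spec.max_rhat).all())

    # marginal active proportions per habitat: inverse-link of the marginal
    # prediction, integrating the phenotype-level random effects (bird and
    # observation level) by quadrature; site/date intercepts at their mean
    for h in _HAB_ORDER:
        eta = _marginal_profile(
            beta_draws, design.colnames, h, design.species_levels, design.season_levels
        )
        sig = np.sqrt(draws[f"sigma_B_{h}"] ** 2 + draws[f"sigma_W_{h}"] ** 2)
        draws[f"prop_{h}"] = _logit_normal_mean(eta, sig)
    draws["delta_prop"] = draws["prop_urban"] - draws["prop_forest"]

    return PosteriorSummary(
        draws=draws,
        beta_draws=beta_draws,
        colnames=design.colnames,
        species_levels=design.species_levels,
        season_levels=design.season_levels,
        response=f"activity_{window}",
        model="binomial_glmm",
        converged=converged,
        failure="" if converged else "R-hat above threshold after retry",
        meta={"diagnostics": diag, "n_obs": len(df), "n_birds": len(bird_levels)},
    )


def _pack_univariate(raw: dict, design) -> tuple[dict[str, np.ndarray], np.ndarray]:
    draws: dict[str, np.ndarray] = {}
    for i, h in enumerate(_HAB_ORDER):
        draws[f"sigma_B_{h}"] = raw["sigma_B"][:, :, i]
        draws[f"sigma_W_{h}"] = raw["sigma_W"][:, :, i]
    draws["sigma_site"] = raw["sigma_site"]
    draws["sigma_date"] = raw["sigma_date"]
    draws["delta_sigma_B"] = draws["sigma_B_urban"] - draws["sigma_B_forest"]
    draws["delta_sigma_W"] = draws["sigma_W_urban"] - draws["sigma_W_forest"]
    beta_draws = raw["beta"]  # (chains, draws, P)
    return draws, beta_draws


def fit_bivariate_activity_model(
    levels: pd.DataFrame, spec: ModelSpec
) -> PosteriorSummary:
    """Joint binomial model of diurnal and nocturnal activity levels.

    One row per bird-day pairing the two windows (either side may be
    missing); habitat-specific between-individual (rho_B) and
    observation-level (rho_W) diurnal-nocturnal correlations are estimated,
    along with their cross-habitat differences.
    """
    df = levels.copy()
    keys = ["bird_id", "site_id", "habitat", "species", "season", "year", "date",
            "tmin_c", "precip_mm"]
    wide = (
        df.pivot_table(index=keys, columns="window", values=["n_active", "n_scored"],
                       aggfunc="first")
        .reset_index()
    )
    wide.columns = ["_".join(c).rstrip("_") if c[1] else c[0] for c in wide.columns]
    for col in ("n_active_diurnal", "n_scored_diurnal", "n_active_nocturnal", "n_scored_nocturnal"):
        if col not in wide.columns:
            wide[col] = np.nan
    design = build_design(wide)
    site, _ = _codes(wide["site_id"])
    date, _ = _codes(wide["date"])
    bird, bird_levels = _codes(wide["bird_id"])
    hab_obs = np.where(wide["habitat"].to_numpy() == "urban", 1, 2)
    habb = (
        wide.assign(_b=bird).groupby("_b")["habitat"].first().sort_index()
        .map({"urban": 1, "forest": 2}).to_numpy()
    )

    def counts(col: str, fallback: int) -> tuple[list, np.ndarray]:
        y = wide[f"n_active_{col}"]
        n = wide[f"n_scored_{col}"].fillna(fallback).astype(int).to_numpy()
        y_json = [None if pd.isna(v) else int(v) for v in y]
        return y_json, n

    yd, sized = counts("diurnal", 120)
    yn, sizen = counts("nocturnal", 80)

    data = {
        "yd": yd, "sized": sized, "yn": yn, "sizen": sizen,
        "Xd": design.X, "Xn": design.X,
        "N": len(wide), "Pd": design.X.shape[1], "Pn": design.X.shape[1],
        "J": len(bird_levels), "S": int(site.max()), "D": int(date.max()),
        "site": site, "date": date, "bird": bird, "hab": hab_obs, "habb": habb,
    }
    p0 = design.X.shape[1]
    inits = {
        "betad": np.zeros(p0), "betan": np.zeros(p0),
        "sigma_Bd": [0.5, 0.5], "sigma_Bn": [0.5, 0.5],
        "sigma_Wd": [0.5, 0.5], "sigma_Wn": [0.5, 0.5],
        "rho_B": [0.0, 0.0], "rho_W": [0.0, 0.0],
        "sigma_site_d": 0.3, "sigma_site_n": 0.3,
        "sigma_date_d": 0.3, "sigma_date_n": 0.3,
    }
    params = [
        "betad", "betan", "sigma_Bd", "sigma_Bn", "sigma_Wd", "sigma_Wn",
        "rho_B", "rho_W",
    ]

    def run(factor: int) -> dict[str, np.ndarray]:
        return run_jags(
            _BIVARIATE_MODEL, data, params,
            n_chains=max(3, min(spec.chains, 4)),
            n_adapt=spec.n_adapt * factor, n_burn=spec.n_burn * factor,
            n_iter=spec.n_iter * factor, thin=spec.thin,
            seed=spec.seed, inits=inits,
        )

    raw = run(1)
    draws = _pack_bivariate(raw)
    core = {k: v for k, v in draws.items() if k.startswith(("rho", "sigma"))}
    diag = _rhat_ess(core)
    converged = bool((diag["rhat"] < spec.max_rhat).all())
    if not converged:
        raw = run(2)
        draws = _pack_bivariate(raw)
        core = {k: v for k, v in draws.items() if k.startswith(("rho", "sigma"))}
        diag = _rhat_ess(core)
        converged = bool((diag["rhat"] < spec.max_rhat).all())

    return PosteriorSummary(
        draws=draws,
        beta_draws=raw["betad"],
        colnames=design.colnames,
        species_levels=design.species_levels,
        season_levels=design.season_levels,
        response="activity_bivariate",
        model="binomial_glmm_bivariate",
        converged=converged,
        failure="" if converged else "R-hat above threshold after retry",
        meta={"diagnostics": diag, "n_obs": len(wide), "n_birds": len(bird_levels)},
    )


def _pack_bivariate(raw: dict) -> dict[str, np.ndarray]:
    draws: dict[str, np.ndarray] = {}
    for i, h in enumerate(_HAB_ORDER):
        draws[f"rho_B_{h}"] = raw["rho_B"][:, :, i]
        draws[f"rho_W_{h}"] = raw["rho_W"][:, :, i]
        draws[f"sigma_B_diurnal_{h}"] = raw["sigma_Bd"][:, :, i]
        draws[f"sigma_B_nocturnal_{h}"] = raw["sigma_Bn"][:, :, i]
        draws[f"sigma_W_diurnal_{h}"] = raw["sigma_Wd"][:, :, i]
        draws[f"sigma_W_nocturnal_{h}"] = raw["sigma_Wn"][:, :, i]
    draws["delta_rho_B"] = draws["rho_B_urban"] - draws["rho_B_forest"]
    draws["delta_rho_W"] = draws["rho_W_urban"] - draws["rho_W_forest"]
    return draws
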