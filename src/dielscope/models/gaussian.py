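"""Bayesian heteroscedastic linear mixed models for activity-timing traits.

Model (per response y = relative onset, relative end or duration, hours):

    y_i = x_i' beta + u_site[s(i)] + u_date[d(i)] + u_bird[b(i)] + eps_i
    u_site ~ N(0, sigma_site^2);  u_date ~ N(0, sigma_date^2)
    u_bird[j] ~ N(0, sigma_B[habitat(j)]^2)      (between-individual, per habitat)
    eps_i ~ N(0, sigma_W[habitat(i)]^2)          (within-individual, per habitat)

Sampling exploits the Gaussian structure: all location parameters
(beta and every random intercept) are integrated out analytically via
Henderson's mixed-model equations, leaving a 6-dimensional marginal
posterior over the log standard deviations, which is explored with an
adaptive random-walk Metropolis sampler (multiple chains).  For a thinned
subset of the variance draws the location parameters are then drawn
exactly from their multivariate-normal full conditional, giving exact
joint posterior draws without any approximation beyond MCMC error.

Priors: half-Student-t(3, 0, 2.5 * sd(y)) on every SD; independent
N(0, (10 * sd(y))^2) on each fixed effect (covariates are standardized).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.linalg import cho_factor, cho_solve

from .design import ModelSpec, DesignInfo, build_design, RankDeficiencyError
from .posterior import PosteriorSummary, _rhat_ess

__all__ = ["fit_timing_model", "fit_sex_timing_model", "GaussianLocationScale"]

SEXABLE = ("blackbird", "chaffinch", "great_tit")

_LOG_SD_MIN, _LOG_SD_MAX = -9.0, 7.0


def _half_t_logpdf(sigma: np.ndarray, scale: float, df: float = 3.0) -> np.ndarray:
    z = sigma / scale
    return -0.5 * (df + 1.0) * np.log1p(z * z / df)


class GaussianLocationScale:
    """Collapsed-likelihood machinery for one dataset/design.

    Variance-parameter vector theta (log scale):
    [sigma_site, sigma_date, sigma_B_urban, sigma_B_forest,
     sigma_W_urban, sigma_W_forest].
    """

    VAR_NAMES = (
        "sigma_site", "sigma_date",
        "sigma_B_urban", "sigma_B_forest",
        "sigma_W_urban", "sigma_W_forest",
    )

    def __init__(self, df: pd.DataFrame, response: str, design: DesignInfo,
                 prior_sd_scale: float = 2.5, beta_prior_mult: float = 10.0):
        y = df[response].to_numpy(dtype=float)
        self.n = y.size
        self.y_sd = float(np.std(y)) or 1.0
        self.prior_scale = prior_sd_scale * self.y_sd
        self.design = design

        X = design.X
        p = X.shape[1]
        site_codes, self.site_levels = pd.factorize(df["site_id"], sort=True)
        date_codes, self.date_levels = pd.factorize(df["date"], sort=True)
        bird_codes, self.bird_levels = pd.factorize(df["bird_id"], sort=True)
        bird_hab = (
            df.assign(_b=bird_codes).groupby("_b")["habitat"].first().sort_index()
        )
        q_s, q_d, q_b = len(self.site_levels), len(self.date_levels), len(self.bird_levels)

        def onehot(codes: np.ndarray, q: int) -> np.ndarray:
            Z = np.zeros((self.n, q))
            Z[np.arange(self.n), codes] = 1.0
            return Z

        W = np.concatenate(
            [X, onehot(site_codes, q_s), onehot(date_codes, q_d), onehot(bird_codes, q_b)],
            axis=1,
        )
        self.m = W.shape[1]
        self.p = p
        # variance-group code per coefficient:
        # -1 = fixed effect, 0 = site, 1 = date, 2 = bird urban, 3 = bird forest
        groups = np.concatenate(
            [
                np.full(p, -1),
                np.full(q_s, 0),
                np.full(q_d, 1),
                np.where(bird_hab.to_numpy() == "urban", 2, 3),
            ]
        )
        self.groups = groups
        self.beta_prior_var = (beta_prior_mult * self.y_sd) ** 2

        urban_obs = (df["habitat"] == "urban").to_numpy()
        self.n_u = int(urban_obs.sum())
        self.n_f = self.n - self.n_u
        Wu, Wf = W[urban_obs], W[~urban_obs]
        yu, yf = y[urban_obs], y[~urban_obs]
        self.A_u, self.A_f = Wu.T @ Wu, Wf.T @ Wf
        self.r_u, self.r_f = Wu.T @ yu, Wf.T @ yf
        self.s_u, self.s_f = float(yu @ yu), float(yf @ yf)
        if self.n_u == 0 or self.n_f == 0:
            raise ValueError("both habitats must be present in the data")

    # ------------------------------------------------------------------
    def _prior_variances(self, theta: np.ndarray) -> np.ndarray:
        v = np.empty(self.m)
        v[self.groups == -1] = self.beta_prior_var
        sig2 = np.exp(2.0 * theta)
        for g in range(4):
            v[self.groups == g] = sig2[g]
        return v

    def _assemble(self, theta: np.ndarray):
        s2_wu, s2_wf = np.exp(2.0 * theta[4]), np.exp(2.0 * theta[5])
        d = self._prior_variances(theta)
        C = self.A_u / s2_wu + self.A_f / s2_wf
        C[np.diag_indices_from(C)] += 1.0 / d
        r = self.r_u / s2_wu + self.r_f / s2_wf
        return C, r, d, s2_wu, s2_wf

    def loglik(self, theta: np.ndarray) -> float:
        """Marginal log-likelihood with all location parameters integrated out."""
        C, r, d, s2_wu, s2_wf = self._assemble(theta)
        try:
            cf = cho_factor(C, lower=True, check_finite=False)
        except np.linalg.LinAlgError:
            return -np.inf
        logdet_C = 2.0 * float(np.sum(np.log(np.diag(cf[0]))))
        quad = float(r @ cho_solve(cf, r, check_finite=False))
        ll = -0.5 * (
            self.n * np.log(2.0 * np.pi)
            + self.n_u * np.log(s2_wu)
            + self.n_f * np.log(s2_wf)
            + float(np.sum(np.log(d)))
            + logdet_C
            + self.s_u / s2_wu
            + self.s_f / s2_wf
            - quad
        )
        return ll

    def logpost(self, theta: np.ndarray) -> float:
        if np.any(theta < _LOG_SD_MIN) or np.any(theta > _LOG_SD_MAX):
            return -np.inf
        sigma = np.exp(theta)
        # half-t prior on sigma plus the log-sigma Jacobian
        lp = float(np.sum(_half_t_logpdf(sigma, self.prior_scale) + theta))
        return lp + self.loglik(theta)

    def draw_locations(self, theta: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        """Exact draw of (beta, random effects) | theta, y."""
        C, r, _, _, _ = self._assemble(theta)
        cf = cho_factor(C, lower=True, check_finite=False)
        mean = cho_solve(cf, r, check_finite=False)
        z = rng.standard_normal(self.m)
        # C = L L'; draw = mean + L^-T z
        from scipy.linalg import solve_triangular

        dev = solve_triangular(cf[0], z, lower=True, trans="T", check_finite=False)
        return mean + dev

    def init_theta(self, df: pd.DataFrame, response: str) -> np.ndarray:
        """Moment-based starting point for the log-SD vector."""
        g = df.groupby("bird_id")[response]
        bird_means = g.mean()
        resid_sd = df.groupby("habitat")[response].std().reindex(["urban", "forest"])
        hab_of_bird = df.groupby("bird_id")["habitat"].first()
        sd_b = bird_means.groupby(hab_of_bird).std().reindex(["urban", "forest"])
        vals = np.array(
            [
                0.3 * self.y_sd,
                0.3 * self.y_sd,
                np.nan_to_num(sd_b.iloc[0], nan=0.3 * self.y_sd) * 0.7 or 0.1,
                np.nan_to_num(sd_b.iloc[1], nan=0.3 * self.y_sd) * 0.7 or 0.1,
                np.nan_to_num(resid_sd.iloc[0], nan=self.y_sd) or 0.3,
                np.nan_to_num(resid_sd.iloc[1], nan=self.y_sd) or 0.3,
            ]
        )
        return np.log(np.clip(vals, 1e-3, None))


def _laplace_proposal(logpost, x0: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Posterior mode and a proposal Cholesky from the local curvature."""
    from scipy.optimize import minimize

    res = minimize(lambda t: -logpost(t), x0, method="Nelder-Mead",
                   options={"maxiter": 800, "xatol": 1e-4, "fatol": 1e-4})
    # keep clear of the hard log-SD bounds so curvature stays finite
    mode = np.clip(res.x, _LOG_SD_MIN + 1.0, _LOG_SD_MAX - 1.0)
    d = mode.size
    h = 1e-3
    H = np.empty((d, d))
    f0 = logpost(mode)
    for i in range(d):
        for j in range(i, d):
            ei, ej = np.zeros(d), np.zeros(d)
            ei[i] = h
            ej[j] = h
            if i == j:
                H[i, i] = (logpost(mode + ei) - 2 * f0 + logpost(mode - ei)) / h**2
            else:
                H[i, j] = H[j, i] = (
                    logpost(mode + ei + ej) - logpost(mode + ei - ej)
                    - logpost(mode - ei + ej) + logpost(mode - ei - ej)
                ) / (4 * h**2)
    cov = None
    if np.all(np.isfinite(H)):
        try:
            cov = np.linalg.inv(-H)
            np.linalg.cholesky(cov)  # must be positive definite
        except np.linalg.LinAlgError:
            cov = None
    if cov is None or not np.all(np.isfinite(cov)):
        cov = np.eye(d) * 0.05
    return mode, cov


def _adaptive_metropolis(
    logpost, x0: np.ndarray, warmup: int, draws: int, rng: np.random.Generator,
    cov0: np.ndarray | None = None,
) -> tuple[np.ndarray, float]:
    """Single-chain adaptive random-walk Metropolis (Haario-style).

    Proposal covariance starts from ``cov0`` (e.g. a Laplace approximation)
    and adapts to the empirical covariance of the history during warmup with
    Robbins-Monro scale tuning toward ~30% acceptance, then freezes for the
    sampling phase.
    """
    d = x0.size
    x = x0.copy()
    lp = logpost(x)
    if not np.isfinite(lp):
        lp = -np.inf
    lam = 2.38 / np.sqrt(d)
    cov = np.eye(d) * 0.05 if cov0 is None else cov0
    chol = np.linalg.cholesky(cov)
    history = np.empty((warmup + draws, d))
    accepted = 0
    n_acc_window = 0
    for it in range(warmup + draws):
        prop = x + lam * chol @ rng.standard_normal(d)
        lp_prop = logpost(prop)
        if not np.isfinite(lp_prop):
            lp_prop = -np.inf
        if lp_prop - lp > np.log(rng.random()):
            x, lp = prop, lp_prop
            accepted += 1
            n_acc_window += 1
        history[it] = x
        if it < warmup and (it + 1) % 50 == 0:
            rate = n_acc_window / 50.0
            n_acc_window = 0
            lam *= np.exp((rate - 0.30) / np.sqrt(1.0 + it / 50.0))
            if it + 1 >= 200:
                emp = np.cov(history[max(0, it - 500): it + 1].T)
                try:
                    chol = np.linalg.cholesky(emp + 1e-8 * np.eye(d))
                except np.linalg.LinAlgError:
                    pass
    return history[warmup:], accepted / (warmup + draws)


def _fit_gaussian(
    df: pd.DataFrame, spec: ModelSpec, design: DesignInfo, model_name: str
) -> PosteriorSummary:
    machine = GaussianLocationScale(
        df, spec.response, design,
        prior_sd_scale=spec.prior_sd_scale, beta_prior_mult=spec.beta_prior_mult,
    )
    theta0 = machine.init_theta(df, spec.response)
    mode, cov0 = _laplace_proposal(machine.logpost, theta0)
    sd0 = np.sqrt(np.diag(cov0))

    def run(warmup: int, draws: int) -> tuple[np.ndarray, np.ndarray]:
        chains = []
        locs = []
        for c in range(spec.chains):
            rng = np.random.default_rng(
                np.random.SeedSequence([spec.seed & 0x7FFFFFFF, 101, c])
            )
            start = np.clip(
                mode + 2.0 * sd0 * rng.standard_normal(mode.size),
                _LOG_SD_MIN + 0.5, _LOG_SD_MAX - 0.5,
            )
            hist, _ = _adaptive_metropolis(
                machine.logpost, start, warmup, draws, rng, cov0=cov0
            )
            chains.append(hist)
            keep = hist[:: spec.thin_location]
            locs.append(
                np.stack([machine.draw_locations(t, rng)[: machine.p] for t in keep])
            )
        return np.stack(chains), np.stack(locs)

    theta_draws, beta_draws = run(spec.warmup, spec.draws)
    draws = _pack_gaussian_draws(theta_draws)
    diag = _rhat_ess({k: draws[k] for k in GaussianLocationScale.VAR_NAMES})
    converged = bool((diag["rhat"] < spec.max_rhat).all())
    if not converged:  # one retry with a longer run
        theta_draws, beta_draws = run(2 * spec.warmup, 2 * spec.draws)
        draws = _pack_gaussian_draws(theta_draws)
        diag = _rhat_ess({k: draws[k] for k in GaussianLocationScale.VAR_NAMES})
        converged = bool((diag["rhat"] < spec.max_rhat).all())

    return PosteriorSummary(
        draws=draws,
        beta_draws=beta_draws,
        colnames=design.colnames,
        species_levels=design.species_levels,
        season_levels=design.season_levels,
        response=spec.response,
        model=model_name,
        converged=converged,
        failure="" if converged else
        f"R-hat above {spec.max_rhat} after retry: "
        + ", ".join(diag.loc[diag.rhat >= spec.max_rhat, "parameter"]),
        meta={"diagnostics": diag, "n_obs": machine.n, "n_birds": len(machine.bird_levels)},
    )


def _pack_gaussian_draws(theta_draws: np.ndarray) -> dict[str, np.ndarray]:
    sig = np.exp(theta_draws)  # (chains, draws, 6)
    names = GaussianLocationScale.VAR_NAMES
    out = {name: sig[:, :, i] for i, name in enumerate(names)}
    out["delta_sigma_B"] = out["sigma_B_urban"] - out["sigma_B_forest"]
    out["delta_sigma_W"] = out["sigma_W_urban"] - out["sigma_W_forest"]
    for h in ("urban", "forest"):
        sb2 = out[f"sigma_B_{h}"] ** 2
        sw2 = out[f"sigma_W_{h}"] ** 2
        out[f"repeatability_{h}"] = sb2 / (sb2 + sw2)
    out["delta_repeatability"] = out["repeatability_urban"] - out["repeatability_forest"]
    return out


def fit_timing_model(df: pd.DataFrame, spec: ModelSpec) -> PosteriorSummary:
    """Fit the six-species timing LMM with habitat-specific variances.

    ``df`` needs columns: the response named in ``spec.response``,
    bird_id, site_id, date, habitat, species, season, year, tmin_c,
    precip_mm.  Incomplete cases are dropped.  Requires at least two birds
    per habitat.
    """
    df = df.dropna(subset=[spec.response]).copy()
    birds_per_hab = df.groupby("habitat")["bird_id"].nunique()
    if (birds_per_hab < 2).any() or len(birds_per_hab) < 2:
        raise ValueError(
            f"need >= 2 birds in each habitat; got {birds_per_hab.to_dict()}"
        )
    design = build_design(df)
    return _fit_gaussian(df, spec, design, model_name="timing_lmm")


def fit_sex_timing_model(df: pd.DataFrame, spec: ModelSpec) -> PosteriorSummary:
    """Timing LMM restricted to the sexable species, with sex interactions.

    Adds sex and the sex x habitat, sex x season and sex x species
    interactions.  Only blackbird, great tit and chaffinch (sexable from
    plumage) with known sex are retained.

    Raises
    ------
    RankDeficiencyError
        for degenerate designs such as single-sex input.
    """
    df = df.dropna(subset=[spec.response]).copy()
    df = df[df["species"].isin(SEXABLE) & (df["sex"].isin(["male", "female"]))]
    if df.empty:
        raise ValueError("no sexed observations for the sexable species")
    design = build_design(df, include_sex=True)
    return _fit_gaussian(df, spec, design, model_name="timing_lmm_sex")
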