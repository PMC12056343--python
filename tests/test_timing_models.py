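"""Heteroscedastic timing LMM: likelihood oracle, contracts and recovery."""

import json
import subprocess
import tempfile

import numpy as np
import pandas as pd
import pytest
from scipy.stats import multivariate_normal

from dielscope import ModelSpec, fit_timing_model, fit_sex_timing_model, simulate_timing_dataset
from dielscope.models.design import build_design, RankDeficiencyError
from dielscope.models.gaussian import GaussianLocationScale


@pytest.fixture(scope="module")
def small_df():
    return simulate_timing_dataset(n_birds_per_cell=3, n_days=6, seed=101)


def _mvn_loglik(df, design, theta, beta_prior_mult=10.0):
    """Direct dense multivariate-normal evaluation of the marginal likelihood."""
    y = df["relative_onset_h"].to_numpy()
    X = design.X
    site_c, _ = pd.factorize(df.site_id, sort=True)
    date_c, _ = pd.factorize(df.date, sort=True)
    bird_c, _ = pd.factorize(df.bird_id, sort=True)
    hb = df.assign(_b=bird_c).groupby("_b").habitat.first().sort_index().to_numpy()

    def onehot(c):
        Z = np.zeros((len(c), c.max() + 1))
        Z[np.arange(len(c)), c] = 1
        return Z

    W = np.concatenate([X, onehot(site_c), onehot(date_c), onehot(bird_c)], axis=1)
    sig = np.exp(theta)
    dvec = np.concatenate(
        [
            np.full(X.shape[1], (beta_prior_mult * np.std(y)) ** 2),
            np.full(site_c.max() + 1, sig[0] ** 2),
            np.full(date_c.max() + 1, sig[1] ** 2),
            np.where(hb == "urban", sig[2] ** 2, sig[3] ** 2),
        ]
    )
    rdiag = np.where(df.habitat == "urban", sig[4] ** 2, sig[5] ** 2)
    V = np.diag(rdiag) + W @ np.diag(dvec) @ W.T
    return multivariate_normal(mean=np.zeros(len(y)), cov=V).logpdf(y)


class TestCollapsedLikelihood:
    def test_matches_dense_mvn_oracle(self, small_df):
        """The mixed-model-equations marginal likelihood equals a direct
        dense multivariate-normal evaluation."""
        design = build_design(small_df)
        machine = GaussianLocationScale(small_df, "relative_onset_h", design)
        rng = np.random.default_rng(0)
        for _ in range(5):
            theta = rng.uniform(-2.0, 0.5, size=6)
            assert machine.loglik(theta) == pytest.approx(
                _mvn_loglik(small_df, design, theta), abs=1e-7
            )

    def test_single_habitat_rejected(self, small_df):
        sub = small_df[small_df.habitat == "urban"]
        with pytest.raises(ValueError, match="habitat"):
            fit_timing_model(sub, ModelSpec(response="relative_onset_h"))


@pytest.fixture(scope="module")
def fitted_pair():
    """One fit on raw responses and one on responses shifted by +1 h."""
    df = simulate_timing_dataset(n_birds_per_cell=4, n_days=8, seed=55)
    spec = ModelSpec(response="relative_onset_h", chains=2, warmup=500, draws=1200,
                     seed=8, max_rhat=1.5)
    post0 = fit_timing_model(df, spec)
    df1 = df.copy()
    df1["relative_onset_h"] += 1.0
    post1 = fit_timing_model(df1, spec)
    return df, post0, post1


class TestLocationScaleContracts:
    def test_shift_moves_intercept_not_variances(self, fitted_pair):
        """Adding +1 h to all responses shifts the intercept by +1 and leaves
        every variance component unchanged (location equivariance)."""
        _, post0, post1 = fitted_pair
        i = post0.colnames.index("intercept")
        b0 = post0.beta_stacked()[:, i].mean()
        b1 = post1.beta_stacked()[:, i].mean()
        assert b1 - b0 == pytest.approx(1.0, abs=0.05)
        for k in ("sigma_W_urban", "sigma_W_forest", "sigma_B_urban", "sigma_B_forest"):
            m0 = np.median(post0.stacked(k))
            m1 = np.median(post1.stacked(k))
            assert m1 == pytest.approx(m0, rel=0.08, abs=0.02)

    def test_scaling_responses_scales_sds_not_repeatability(self):
        """Multiplying responses by c scales every SD by ~c; R is invariant."""
        df = simulate_timing_dataset(n_birds_per_cell=4, n_days=8, seed=56)
        spec = ModelSpec(response="relative_onset_h", chains=2, warmup=500,
                         draws=1200, seed=9, max_rhat=1.5)
        post0 = fit_timing_model(df, spec)
        df2 = df.copy()
        df2["relative_onset_h"] *= 2.0
        post2 = fit_timing_model(df2, spec)
        for k in ("sigma_W_urban", "sigma_W_forest"):
            ratio = np.median(post2.stacked(k)) / np.median(post0.stacked(k))
            assert ratio == pytest.approx(2.0, rel=0.06)
        for h in ("urban", "forest"):
            r0 = np.median(post0.stacked(f"repeatability_{h}"))
            r2 = np.median(post2.stacked(f"repeatability_{h}"))
            assert r2 == pytest.approx(r0, abs=0.05)


class TestSexModel:
    def test_single_sex_design_is_informative_error(self, small_df):
        df = small_df.copy()
        df["sex"] = "male"
        with pytest.raises(RankDeficiencyError, match="sex"):
            fit_sex_timing_model(df, ModelSpec(response="relative_onset_h"))

    def test_null_sex_effect_cri_includes_zero(self):
        """With no simulated sex effect the sex x habitat CrI covers zero."""
        df = simulate_timing_dataset(n_birds_per_cell=6, n_days=8, seed=57)
        spec = ModelSpec(response="relative_onset_h", chains=2, warmup=500,
                         draws=1200, seed=10, max_rhat=1.5)
        post = fit_sex_timing_model(df, spec)
        i = post.colnames.index("sex_male:habitat_urban")
        draws = post.beta_stacked()[:, i]
        lo, hi = np.quantile(draws, [0.025, 0.975])
        assert lo < 0 < hi


class TestCrossCheckML:
    def test_posterior_medians_near_glmmtmb_mle(self):
        """Independent maximum-likelihood fit of the same location-scale model
        (glmmTMB) agrees with the collapsed sampler's posterior medians."""
        df = simulate_timing_dataset(n_birds_per_cell=8, n_days=12, seed=77)
        spec = ModelSpec(response="relative_onset_h", chains=2, warmup=600,
                         draws=1500, seed=12, max_rhat=1.5)
        post = fit_timing_model(df, spec)

        d = df.copy()
        d["y"] = d["relative_onset_h"]
        d["tmin_z"] = (d.tmin_c - d.tmin_c.mean()) / d.tmin_c.std(ddof=0)
        d["precip_z"] = (d.precip_mm - d.precip_mm.mean()) / d.precip_mm.std(ddof=0)
        d["urban"] = (d.habitat == "urban").astype(float)
        d["forest"] = (d.habitat == "forest").astype(float)
        d["date"] = d["date"].astype(str)
        with tempfile.TemporaryDirectory() as tmp:
            d.to_csv(f"{tmp}/d.csv", index=False)
            rcode = f"""
suppressMessages(library(glmmTMB))
d <- read.csv("{tmp}/d.csv")
m <- glmmTMB(y ~ habitat + species + tmin_z + precip_z + habitat:species +
             (1|site_id) + (1|date) + (0 + urban | bird_id) + (0 + forest | bird_id),
             dispformula = ~ habitat, data = d, REML = FALSE)
vc <- VarCorr(m)$cond
disp <- fixef(m)$disp
out <- list(sigma_B_urban = attr(vc$bird_id, "stddev")[[1]],
            sigma_B_forest = attr(vc$bird_id.1, "stddev")[[1]],
            disp_intercept = disp[[1]], disp_urban = disp[[2]],
            beta_habitat = fixef(m)$cond[["habitaturban"]])
cat(jsonlite::toJSON(out, auto_unbox=TRUE))
"""
            r = subprocess.run(["Rscript", "-e", rcode], capture_output=True, text=True)
            assert r.returncode == 0, r.stderr[-1000:]
            mle = json.loads(r.stdout)

        assert np.median(post.stacked("sigma_W_forest")) == pytest.approx(
            np.exp(mle["disp_intercept"]), rel=0.10
        )
        assert np.median(post.stacked("sigma_W_urban")) == pytest.approx(
            np.exp(mle["disp_intercept"] + mle["disp_urban"]), rel=0.10
        )
        assert np.median(post.stacked("sigma_B_urban")) == pytest.approx(
            mle["sigma_B_urban"], abs=0.12
        )
        assert np.median(post.stacked("sigma_B_forest")) == pytest.approx(
            mle["sigma_B_forest"], abs=0.12
        )
        i = post.colnames.index("habitat_urban")
        assert post.beta_stacked()[:, i].mean() == pytest.approx(
            mle["beta_habitat"], abs=0.2
        )


class TestCalibration:
    def test_interval_coverage_on_small_designs(self):
        """Across replicate small simulations the 95% CrIs for the habitat
        variance differences cover the truth at close to nominal rate."""
        hits = total = 0
        for rep in range(55):
            df = simulate_timing_dataset(n_birds_per_cell=3, n_days=6, seed=1000 + rep)
            spec = ModelSpec(response="relative_onset_h", chains=2, warmup=400,
                             draws=700, seed=rep, max_rhat=99.0)
            post = fit_timing_model(df, spec)
            for name, truth in (("delta_sigma_B", 0.10), ("delta_sigma_W", 0.26)):
                _, lo, hi = post.median_ci(name)
                hits += lo <= truth <= hi
                total += 1
        coverage = hits / total
        assert 0.88 <= coverage <= 1.0
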