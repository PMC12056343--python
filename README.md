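# dielscope

Analysis of diel activity rhythms from automated radio telemetry, built for
studies that contrast urban and forest songbird populations in both the
**mean** and the **variability** of their daily activity schedules.

Automated receivers log the signal strength (dB) of radio-tagged birds every
3 minutes. While a bird roosts, its position relative to the receivers is
fixed and the received strength is stable; as soon as it moves, consecutive
readings jump. dielscope turns those raw logs into behavioural traits and
fits the hierarchical models that separate population differences from
between- and within-individual variation:

1. **Signal differential** — per receiver, d_t = |s_t − s_{t−1}| on the
   3-min grid, averaged across a site's receivers (gaps are never
   differenced across, and missing slots stay missing).
2. **Onset and end of activity** — a sliding two-block Gaussian change-point
   search: for each candidate split k of the windowed series the summed
   block log-likelihoods L(k) = ℓ(x₁…x_k) + ℓ(x_{k+1}…x_n) at the MLEs are
   profiled, and k* = argmax L(k). Onset is searched in
   [sunrise − 4 h, sunrise + 2 h), end in [sunset − 4 h, sunset + 4 h);
   estimates are kept only when the bird was detected > 75 % of the window.
   A Bayesian broken-stick (flat-then-sloped) fit provides an independent
   cross-check. Traits are expressed relative to sunrise/sunset (NOAA solar
   geometry, zenith 90.833°).
3. **Activity levels** — each scored slot is *active* when d_t > 10 dB;
   the active proportion is computed in fixed diurnal (10:00–16:00) and
   nocturnal (22:00–02:00) windows, retained at ≥ 50 % coverage.
4. **Hierarchical models** — for timing traits, a Bayesian location–scale
   LMM:

       y_ij = x_ij'β + site + date + bird_j + ε_ij,
       bird_j ~ N(0, σ²_B,h(j)),   ε_ij ~ N(0, σ²_W,h(ij))

   with habitat-specific between-individual (σ_B) and residual (σ_W) SDs,
   giving posterior contrasts Δσ_B, Δσ_W, repeatability
   R_h = σ²_B,h / (σ²_B,h + σ²_W,h), and urban−forest marginal effects per
   species and season. Activity levels use binomial GLMMs with
   habitat-specific observation-level random effects (OLRE), and a
   bivariate binomial model estimates the between-individual and
   within-individual diurnal–nocturnal correlations per habitat.
   Inference is the credible-interval rule: an effect is supported when its
   95 % CrI excludes zero.

A synthetic-telemetry generator with full ground truth (per-bird and
per-day latent deviations, true onsets, activity masks, receiver noise,
dropout) makes every stage testable without any field data.

Gaussian location–scale models are fitted by a collapsed sampler written in
this package (adaptive Metropolis on the variance components with all
location parameters marginalized exactly via Henderson's mixed-model
equations); binomial and bivariate models run on JAGS through `rjags`.

## Worked example

```python
from dielscope import (SimulationConfig, simulate_study, ModelSpec,
                       fit_timing_model, repeatability, habitat_contrasts)
from dielscope.pipeline import detect_all, levels_all, _merge_climate
from dielscope.preprocess import snap_to_grid

cfg = SimulationConfig(n_birds_per_species_per_habitat=2, n_days=10, seed=1)
study = simulate_study(cfg)
study.detections["slot"] = snap_to_grid(study.detections["timestamp"])

estimates, acct = detect_all(study.detections, study.birds, study.sites, study.solar)
print(acct["onset"])
# {'raw': 960, 'estimated': 829, 'low_coverage': 131, 'too_short': 0, 'missing': 0}

sub = estimates[estimates.onset_status == "estimated"]
print(sub.groupby("habitat").relative_onset_h.mean().round(2))
# forest   -0.14
# urban    -0.62

post = fit_timing_model(
    _merge_climate(sub, study.climate),
    ModelSpec(response="relative_onset_h", seed=1),
)
print(post.median_ci("delta_sigma_W"))   # (0.205, 0.129, 0.281)
print(repeatability(post, "forest")["median"])  # 0.118
print(habitat_contrasts(post, by="species").round(2).iloc[0].tolist())
# ['species', 'blackbird', -0.39, -1.25, 0.44, False]
```

Reading the output: 829 of 960 bird-day morning windows survive the
strict >75 % coverage rule; urban birds in this small synthetic deployment
start activity ~29 min earlier than forest birds on average; the
within-individual SD of onset is higher in urban birds
(Δσ_W = +0.21 h, 95 % CrI [+0.13, +0.28], excluding zero); and with only
two birds per species-site cell the per-species habitat contrasts are
correctly reported as inconclusive (CrIs spanning zero).

The same pipeline runs from the shell:

```bash
dielscope simulate --seed 42 --out study/
dielscope run --config study.yaml --seed 42 --out results/
```

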