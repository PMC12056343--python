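# Methods

## Signal model and preprocessing

Receivers scan each tag every 180 s and log signal strength in dB. The
movement proxy is the signal differential d_t = |s_t − s_{t−1}|, computed
per receiver only when both slots of the pair were detected on that
receiver, then averaged across the site's receivers that have a defined
pair at t. Three choices matter here and are deliberate:

- **Timestamps are floored** to the 180-s grid boundary (receivers scan
  tags sequentially, so raw stamps jitter within a slot).
- **Gaps break pairs**: differencing across a detection gap would inflate
  differentials, so a missing slot voids both adjacent pairs for that
  receiver.
- **Missing is missing**: slots with no defined pair on any receiver stay
  NaN rather than zero — imputing zeros would fabricate inactivity.

Coverage rules are strict per their phrasings: timing windows require
detection *more than* 75 % of the window; activity-level windows require
*at least* 50 %.

## Solar anchoring

Sunrise/sunset use the NOAA solar-position equations at zenith 90.833°
(refraction + solar radius), matching civil sunrise tables; agreement with
an independently coded low-precision ephemeris is within 2 min at the
study latitudes (~56° N). All windows are built in the site's civil local
time (DST-aware); the 3-min grid itself is uniform in absolute time. The
nocturnal window (22:00–02:00) is keyed to the date its night starts on.

## Change-point estimation

For the windowed differential series the two-block Gaussian split profiles
L(k) = ℓ(x₁…x_k) + ℓ(x_{k+1}…x_n), each block at its MLE
(μ̂ = mean, σ̂² = biased MLE variance floored at 10⁻⁶ dB²; the floor keeps
constant blocks finite). Numerical choices:

- minimum block size 5 slots (15 min) — Gaussian MLEs need a few points;
- ties break to the earliest split (deterministic, conservative for onset);
- missing slots inside the window are dropped before splitting, with
  indices mapped back to slot times (the 75 % rule bounds the missingness);
- the estimate is the first slot of the second block: the first active
  slot for onset, the first quiet slot for end (the end window is
  time-reversed so the same quiet-to-active split form applies);
- a support statistic (max − median of the L profile) is recorded with
  every estimate. No hard support threshold is applied; flat, featureless
  windows are retained but carry near-zero support, and the broken-stick
  validator flags them (support < 15 log-likelihood units) instead of
  silently excluding them.

The broken-stick validator fits, for each candidate breakpoint, a constant
mean before and an OLS line after, with a common Gaussian variance; the
profile likelihood under a discrete uniform breakpoint prior is normalised
into a posterior over the breakpoint and its median is reported. It is an
empirical-Bayes-style grid posterior intended purely as a cross-check of
the change-point estimates (their agreement on noisy step fixtures has
correlation > 0.9).

## Activity levels

A scored slot is *active* when d_t > 10 dB. Equality resolves to inactive:
the two published clauses ("higher than" / "lower than" 10 dB) are both
strict, leaving d_t = 10 unassigned, and inactive is the conservative
completion. Proportions are computed over scored slots, and the raw counts
(n_active, n_scored) are retained because the binomial models consume
counts.

## Hierarchical models

**Timing traits** (relative onset, relative end, duration; hours) use a
Gaussian location–scale mixed model with fixed effects habitat, species,
season, year, standardized tmin and precipitation, plus habitat×species and
habitat×season; random intercepts for site and calendar date (crossed, one
level per date); habitat-specific bird-ID intercept SDs σ_B,h; and
habitat-specific residual SDs σ_W,h. Sex models (blackbird, great tit,
chaffinch) add sex and its interactions with habitat, season and species,
and reject single-sex designs with a rank-deficiency error.

Sampling exploits the model's Gaussian structure: fixed effects and all
random intercepts are marginalized exactly through Henderson's mixed-model
equations, so the posterior explored by MCMC is 6-dimensional
(log σ_site, log σ_date, log σ_B,urban, log σ_B,forest, log σ_W,urban,
log σ_W,forest). An adaptive random-walk Metropolis sampler (proposal
initialised from a Laplace approximation at the posterior mode, Haario
covariance adaptation during warmup, ~30 % target acceptance) runs 4
chains × 2 000–3 000 kept draws; location parameters are then drawn
exactly from their multivariate-normal conditional for a thinned subset,
so contrasts come from exact joint draws. The marginal likelihood is
verified in the tests against a dense multivariate-normal evaluation
(agreement ~10⁻¹²), and the posterior medians against an independent
maximum-likelihood fit of the same model in glmmTMB.

**Activity levels** use binomial GLMMs on (n_active, n_scored) with the
same fixed-effect structure, site/date intercepts, habitat-specific bird
SDs and a habitat-specific observation-level random effect (OLRE) as the
within-individual variance analogue on the logit scale. These run on JAGS
(rjags; `glm` module loaded). The OLRE is non-centered (e = σ_W·z): with
sparse nocturnal counts the observation effects are prior-dominated and
the centered form funnels badly. The bivariate model couples the diurnal
and nocturnal responses: diurnal components are centered (data-rich),
nocturnal bird and observation effects are expressed conditionally on
their diurnal partners through habitat-specific correlations ρ_B,h and
ρ_W,h (the nocturnal OLRE additionally non-centered). Population-level
active proportions per habitat are the inverse-link of the marginal
(species/season-averaged) prediction, integrating the bird and OLRE
effects by Gauss–Hermite quadrature; site/date intercepts are held at
their zero mean, which matches the generator where activity heterogeneity
is bird- and day-level.

**Priors** are pinned explicitly (software-default priors are not
reproducible across stacks): half-Student-t(3, 0, 2.5·sd(y)) on every SD
(2.5 on the logit scale for binomial models), Normal(0, (10·sd(y))²) (or
N(0, 5²) logit) on fixed effects, and Uniform(−1, 1) on correlations —
equivalent to LKJ(1) for a single 2×2 correlation.

**Repeatability** is R_h = σ²_B,h / (σ²_B,h + σ²_W,h) per posterior draw.
Site and date variance are excluded from the denominator; the printed
magnitudes this produces are the two-component form, and including the
design variances would shrink all R values by a few points.

**Inference** follows the credible-interval rule exclusively: an effect is
supported when the central 95 % CrI excludes zero. No p-values exist
anywhere in the package.

**Convergence**: R-hat and bulk ESS per parameter (arviz); one automatic
retry at doubled length when any monitored R-hat exceeds the threshold,
then an explicit non-convergence flag on the posterior (never silent
acceptance). At desk scale the collapsed Gaussian sampler passes
R-hat < 1.01 routinely; the JAGS binomial fits are run with shorter chains
and carry their full R-hat table in `meta["diagnostics"]` — the
weakly-identified nocturnal variance components mix slowly at small n and
their diagnostics should be inspected before interpreting those specific
SDs.

## Synthetic-telemetry generator

The generator emulates the study design it is meant to exercise: two urban
sites (Glasgow) and two forest sites (Loch Lomond), six species, 3-min
scans by 3 receivers per site, pre-breeding (from 1 March) and
post-breeding (from 5 October) blocks in two years, 6 birds per
species-habitat cell per block by default.

Ground truth per bird-day: relative onset = species baseline + urban shift
+ season effect + site effect + date effect + between-bird deviation
(σ_B,h) + day deviation (σ_W,h); analogously for end (plus a small year
effect and a −0.02 h/°C minimum-temperature effect on end). Defaults
encode: urban onset advances of 33 and 30 min for blackbird and robin and
small shifts for the others (urban/forest cohort means ≈ −0.46 / −0.13 h);
σ_B = 0.35/0.25 h and σ_W = 0.81/0.55 h (urban/forest), i.e.
Δσ_B = +0.10, Δσ_W = +0.26 and onset repeatabilities of ≈ 0.16/0.17; end
SDs σ_B = 0.31/0.21 h and σ_W = 0.88/0.83 h, jointly reproducing
Δσ_B ≈ +0.10, Δσ_W ≈ +0.05 and end repeatabilities ≈ 0.115/0.060;
diurnal activity ≈ 48.5 / 49.7 % and nocturnal 4.1 / 1.6 % (urban/forest)
with logit-scale heterogeneity whose habitat differences mirror the
lower forest consistency in timing but higher forest variability in
activity levels, and within-individual diurnal–nocturnal correlation −0.3
in forest, 0 in urban. Activity-level intercepts are solved so the
logit-normal *mean* equals the configured proportion (not the median), so
pooled classified proportions are directly comparable to the configured
rates. The end-of-activity shifts are set moderate (chaffinch largest);
raw end/duration cohort means therefore sit lower than a field cohort
whose species/season composition differs — the generator prioritises the
onset means, variance structure and activity levels over jointly matching
every raw descriptive.

Signal layer: each bird-receiver pair gets a fixed baseline
U(−120, −60) dB; while inactive the latent signal holds its position
(differential = receiver noise only, 2 dB); each active slot moves the
latent signal to the opposite side of the baseline at distance
U(step/2, step/2 + 10), so every active-slot differential is ≥ step
(20 dB) by construction and the active/inactive differential distributions
are separable at 10 dB with error well below 1 %. Slots drop independently
with probability 1 − 0.85 per receiver, plus whole-array out-of-range
episodes (probability 0.3 per bird-day, 2–12 h) that give the 75 %/50 %
coverage filters realistic work (~70–80 % retention). Daytime rest gaps
(per-slot inactivity at 1 − diurnal_active_prob inside [onset, end)) and
sparse nocturnal bouts in 22:00–02:00 complete the diel square wave.
Randomness is keyed by (seed, purpose, bird, date) substreams, so adding
birds never perturbs existing birds' draws and identical configs are
byte-identical.

What the generator does **not** emulate: radio propagation and
triangulation, spatially correlated dropout, multi-day behavioural
autocorrelation, weather-driven activity, or receiver hardware drift.
Passing tests therefore demonstrate that the pipeline recovers truth under
the stated noise/dropout model, not that field data meet those
assumptions.

## Problem sizes and test design

Desk-scale runs keep everything on one CPU: change-point recovery uses
~500 high-SNR bird-days (no rest gaps or dropout, step/noise = 10 — a
recovery target of "the first active slot" is only well defined for a
clean square wave); variance-component recovery uses 20 replicates of 156
birds × 20 days with 4 × 2 000 kept draws; the bivariate model uses 60
birds × 12 days; the pooled-proportion check simulates homogeneous
(zero-heterogeneity) cohorts because an exact binomial reference interval
is only valid without overdispersion. The full-scale MCMC settings of a
field analysis (e.g. 3 × 50 000 iterations) remain available through
`ModelSpec`.

## Known limitations

- The change-point search fits exactly one transition per window; birds
  with genuinely multimodal mornings get the likelihood-dominant break.
- End-of-activity estimates are noisier than onsets: the 8-h end window
  can contain early nocturnal bouts after the true end, and occasional
  large misses inflate the measured within-individual SD of the end trait
  beyond its latent value (more so in the more nocturnal urban birds).
- With two sites per habitat, a single simulation's site-effect draws can
  absorb a sizeable share of a configured habitat shift; cohort-level
  descriptives from one seed carry that design-level uncertainty, which is
  exactly what the site random intercept in the models accounts for.
- Days with no discernible transition are retained with near-zero support
  rather than excluded; downstream sensitivity analyses can filter on the
  recorded support statistic.
- With four sites, σ_site is weakly identified; its posterior is
  prior-influenced and it is excluded from repeatability by design.
- The binomial OLRE SDs for sparse nocturnal data mix slowly in JAGS at
  small sample sizes; correlations (ρ_B, ρ_W) and marginal proportions are
  robust well before the nuisance SDs fully converge.
- Latitudes beyond ±66.5° (polar day/night) are rejected explicitly.
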