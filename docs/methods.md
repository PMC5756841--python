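# Methods

## The model chain

`nestphen` implements a three-stage analysis of grass-height effects on
ground-nest survival, plus the generator used to study it.

### Daily nest survival

A nest alive on day *t−1* survives to day *t* with probability
`S_{i,t}`, `logit(S_{i,t}) = β₀ + x_i′β`. Failure is absorbing. Nests are
visited periodically, so the state between visits is unobserved; for a
visit interval of *L* days the likelihood contribution is `∏ₜ S_{i,t}` if
the nest was alive at both ends and `1 − ∏ₜ S_{i,t}` if it was found
failed. This is the exact marginal over the unknown failure day — latent
daily-state imputation (as a JAGS formulation would use) is exactly
equivalent for an absorbing state, and marginalizing removes latent-variable
mixing from the sampler entirely. Exposure for a successful nest ends at
hatch day (incubation is 27 days from initiation); a failed nest's last
interval runs to the visit at which failure was discovered.

Nest success is the product of daily survival over the 27-day incubation.
Success curves over a grass-height grid are computed per posterior draw and
summarized pointwise (mean, 2.5/97.5 percentiles); covariates other than
grass height are held at their mean (their centered value, zero), and
time-varying age terms, when present, follow the within-incubation
trajectory day by day.

### Phenology correction

Within each study-area × year stratum, OLS of nest-mean measured height on
day of measurement (centered at the stratum median day; the slope is
invariant to centering) estimates the growth rate in cm/day. Each nest's
height is standardized to its hatch date by subtracting
`(measurement day − hatch day) × slope`. The response is the nest mean of
the replicated height measurements, not the replicates, matching how such
data are summarized in the field. Strata are fitted independently — no
shrinkage — and a stratum with fewer than 3 usable nests raises an error
rather than extrapolating. Slope-estimation uncertainty is *not* propagated
into the survival model (two-stage plug-in).

### Pooled tests

The pooled mixed model regresses **measured** height on centered day of
measurement with stratum random effects; phenology is controlled by the DAY
term, so heights must be paired with the day they were measured. (Pairing a
hatch-date-corrected height with a measurement-date DAY builds a spurious
fate effect into the regression by construction: a failed nest's corrected
height refers to a date later than its DAY.) The random structure —
intercepts only vs intercepts and slopes with unstructured 2×2 covariance —
is chosen by REML AICc, `AICc = −2ℓ + 2k + 2k(k+1)/(n−k−1)` with *k*
counting fixed effects, variance/covariance components, and the residual.
The fate effect is then tested by a likelihood-ratio test between ML refits
of the selected structure with and without a hatched/failed indicator
(χ², 1 df) — the conventional REML-for-structure / ML-for-fixed-effects
split. The one-sided Kolmogorov–Smirnov test compares **corrected** heights:
`D⁺ = sup_x [F̂_failed(x) − F̂_hatched(x)]`, positive when hatched-nest
heights are stochastically larger; p is `exp(−2D⁺²mn/(m+n))`, replaced by
exact enumeration over all `C(m+n, m)` label assignments when `m+n ≤ 20`
(ECDFs are evaluated at all pooled jump points, so ties are deterministic).

## The generator

`simulate_study` emulates a multi-site, multi-year nest study:

| parameter | default | meaning |
|---|---|---|
| `n_sites × n_years` | 4 × 3 | strata (study-area × year) |
| `nests_per_stratum` | 50 | nests per stratum |
| `season_start/end_day` | 110–180 | ordinal-day nesting window |
| `incubation_days` | 27 | initiation → hatch |
| `beta0_logit` | logit(0.96) | daily survival at mean height (27-day success ≈ 0.33) |
| `beta_grass_surv` | 0 | true per-cm effect on logit daily survival |
| `grass_intercept_mean/sd` | 15 / 3 cm | stratum height at mid-season |
| `grass_slope_mean/sd` | 0.3 / 0.1 cm/day | stratum growth rates |
| `nest_height_sd` | 3 cm | persistent nest deviation from the stratum line |
| `replicate_sd`, `n_replicates` | 2 cm, 10 | within-nest measurement noise (field studies took 8–20 samples) |
| `visit_interval_days` | 4 | revisit schedule |
| `protocol` | FATE_DATE | FATE_DATE / HATCH_DATE / SCHEDULED |

Defaults were chosen once as a realistic sage-grouse-like study (≈15 cm
grass, ≈0.3 cm/day growth, daily survival 0.96) and are the conditions every
statistical test in the suite runs under. Visit frequency is a free
parameter — published protocols do not report it — and 4 days is an
assumption, not a claim about any field study.

Mechanics and choices:

- Each nest's daily survival depends on its **true hatch-date height**
  (stratum line + persistent nest deviation), centered at the configured
  population mean height (`grass_intercept_mean`), so `beta0_logit` is the
  daily survival of an average nest and stratum-level height differences do
  carry survival signal when the true effect is nonzero.
- Nests are found at initiation (an optional discovery delay exists,
  default 0; nests failing before discovery are never observed and are
  redrawn). Failure is discovered at the first visit on or after the true
  failure day. Hatch is confirmed at the first scheduled check on or after
  hatch day, so under FATE_DATE successful nests are measured 0–3 days
  *past* hatch while failed nests are measured well before their would-be
  hatch date — the timing asymmetry that produces the bias.
- Consequently hatched-nest corrections are small and negative and
  failed-nest corrections larger and positive, and the dataset-mean
  correction is positive when failures are the majority. Field datasets
  with sparser or later visits can show the opposite overall sign; the
  generator makes no attempt to reproduce any particular study's visit
  timing.
- Grass growth is linear within season because the correction model is a
  per-stratum linear regression; the generator deliberately matches the
  analysis's assumed structure. Real phenology (green-up, senescence,
  species mixtures, drooping) is *not* emulated, so passing tests show the
  chain is internally correct and calibrated under its own assumptions —
  not that a linear correction suffices for any particular field system.
- No abandonment/censoring: fates are binary hatched/failed.

## Inference details

- **Sampler**: adaptive random-walk Metropolis. The posterior mode is
  located by Nelder–Mead plus a BFGS polish whose inverse-Hessian seeds the
  proposal covariance (a Laplace approximation; without it a short warmup
  can freeze a badly scaled proposal). During warmup the proposal adapts
  (Haario-style running covariance; global scale tuned toward 35%
  acceptance every 50 iterations), then is frozen. Chains start from the
  mode jittered by one posterior-scale standard deviation; per-chain RNGs
  are split from the master seed, so runs are exactly reproducible.
  Split-chain R-hat and effective sample size come from ArviZ; any R-hat
  above 1.1 flags the result as non-converged, which is reported, never
  discarded (the CLI exits nonzero unless `--allow-nonconverged`).
- **Priors**: independent Normal(0, 1000) on all coefficients. The optional
  year effect is a set of year offsets with a shared Normal(0, σ_year)
  prior and half-Normal(0, 5) hyperprior on σ_year, sampled on log σ with
  the Jacobian included.
- **Centering**: grass height is centered (not standardized) at the dataset
  mean so the coefficient stays per-cm; age and age² are centered at the
  mean exposure-day age.
- **Likelihood evaluation**: with no time-varying covariates, daily survival
  is constant within a nest and each nest collapses to
  (design row, total survived exposure, optional final failed-interval
  length), making one evaluation O(nests); with age terms the general
  per-day path is used. Both paths agree to 1e-12 and are tested against
  brute-force enumeration of failure-day placements.
- **Mixed models** are fitted with statsmodels `MixedLM` through a fixed
  optimizer cascade (lbfgs, powell, then bfgs/nm/cg while no converged
  optimum is in hand), keeping the best finite likelihood — this keeps
  nested ML fits ordered for the LRT and the whole fit deterministic.
  Variance components live on statsmodels' internal scale-free
  parameterization, which keeps covariance matrices positive semidefinite;
  estimates at the zero boundary are flagged (`boundary=True`), not
  suppressed. Single-stratum data reduce to explicit OLS at the boundary
  (one group cannot identify a random intercept).
- **Numerics**: `log S = −log(1+e^−η)` and `log(1−e^ℓ)` via `expm1/log1p`
  branches; degenerate OLS inputs (zero day spread, zero height variance)
  raise or resolve explicitly rather than returning NaN.

## Problem sizes in the test suite

Statistical checks run at sizes chosen to make their Monte-Carlo error small
relative to the asserted bands: 50 replicate studies of 500 nests for
credible-interval coverage and for bias reproduction/removal (MCMC scaled to
3 chains × 2,000 kept after 1,000 warmup — coverage and sign conclusions are
insensitive to chain length well before this), 500 replicates for LRT type-I
calibration, 100 per scenario for AICc structure selection, 1,000 random
intervals for the likelihood oracle, and all sample-size pairs with
`m+n ≤ 14` for exact-vs-reported KS agreement. The acceptance script runs
the full 3 × 30,000 MCMC on single 500-nest studies.

## Known limitations

- Incubation-only success (the 27-day product) overstates true nest success
  whenever failure can occur before detection or during laying; the package
  reports the incubation product by design.
- The two-stage correction treats the phenology slope as known; its
  sampling error is invisible to the survival model's credible intervals.
- Conditional R² for the mixed models (a descriptive sometimes reported
  alongside such analyses) is not computed; it describes variance
  decomposition of a particular dataset rather than the estimators this
  package exists to check.
- The pooled LMM treats nests as independent within strata and assumes
  Gaussian residuals for heights; heavy-tailed measurement error would
  affect the LRT's finite-sample calibration.
- Whether reanalyzed field studies centered or scaled their covariates is
  generally unreported, so per-cm coefficient magnitudes are comparable
  across datasets only under this package's centering convention.
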