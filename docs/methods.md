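# Methods

## The model

`sipipe` implements a two-stage analysis of recruitment–environment
coupling in small pelagic fish.

**Stage 1 — Synchronicity Index.** For each area and recruitment year *t*,
the observation window is the closed interval of calendar months from the
spawning onset month of year *t* − 1 (April by default) to the month
preceding the acoustic survey of year *t* (survey months: July for the
Strait of Sicily and the Gulf of Lions, June for the Adriatic). Over that
window the SI is the percentage bend correlation between monthly CHL and
MLD. For one margin with bend fraction β:

- M = median; W_i = |x_i − M|; ω̂ = m-th smallest W with
  m = ⌊(1 − β)n + 0.5⌋;
- percentage bend location: with ψ_i = (x_i − M)/ω̂, i₁ = #{ψ < −1},
  i₂ = #{ψ > 1}, loc = (Σ_{|ψ|≤1} x_i + ω̂(i₂ − i₁))/(n − i₁ − i₂);
- scores a_i = clip((x_i − loc)/ω̂, −1, 1).

SI = Σ a_i b_i / √(Σ a_i² Σ b_i²), tested with t = ρ√((n−2)/(1−ρ²)) against
Student-t with n − 2 df. The CI resamples month *pairs* with replacement
(B = 2999 by default) and takes the percentile interval of the replicate
correlations. Up to a fraction β of marginal outliers (anomalous bloom
months, mixing events) cannot bias the estimate, which is why a plain
Pearson correlation is not used.

**Stage 2 — pooled robust regression.** Within each area, recruitment, SI
and windowed-mean SST are min–max scaled to [0, 1] so that ecosystems whose
absolute abundances differ by orders of magnitude can be pooled. The
response is y = ln(1 + R_scaled) ∈ [0, ln 2] — note the order: the log is
applied to the *scaled* abundance (log-then-scale would be a different
model). The pooled fit of y on (1, SI_scaled, SST_scaled) is Huber
M-estimation solved by IRLS; coefficient intervals come from resampling
whole observation rows with replacement (random-X bootstrap), refitting,
and summarizing the replicates three ways: Normal (estimate ± z·sd of
replicates), percentile (order statistics of the replicates, Efron rank
⌊(B+1)·level⌋), and BCa (percentile levels adjusted by the bias-correction
z₀ = Φ⁻¹(fraction of replicates below the estimate) and the acceleration
a = Σd³/(6(Σd²)^{3/2}) from jackknife leave-one-out estimates d_i = θ̄ − θ_(i)).
A classical Pearson correlation between annual SI and SST per area is
reported as a collinearity screen before both enter the model.

## Tunable parameters

| parameter | default | meaning |
|---|---|---|
| `beta` | 0.2 | bend fraction; proportion of marginal outliers tolerated |
| `bend_rank_rule` | `"round"` (⌊(1−β)n+0.5⌋) | ω̂ rank convention; `"floor"` reproduces implementations using ⌊(1−β)n⌋ |
| `n_boot` | 2999 | bootstrap replicates, both stages |
| `conf_level` | 0.95 | CI level |
| `tuning_k` | 1.345 | Huber constant, 95% Gaussian efficiency |
| scale estimator | MAD × 1.4826 | robust residual scale, recomputed each IRLS iteration |
| `tol`, `max_iter` | 1e−8, 50 | IRLS convergence (max coefficient change) |
| `stratify_by_area` | off | resample rows within area instead of pooled |

Significance conventions: an SI is flagged significant when its bootstrap
CI excludes zero (the t-test rule is computed and reported alongside as
`significant_ttest`); a regression coefficient is flagged per interval
family, and the pipeline's summary notion of significance is "all three
families exclude zero".

## Numerical choices and degenerate inputs

- Medians use the midpoint convention for even n.
- ω̂ = 0 (more than the bend fraction of values tied at the median) is a
  degenerate-scale error; bootstrap resamples hitting it are skipped and
  logged, and more than 10% of skips aborts the interval.
- |ρ| = 1 returns p = 0 with an infinite t statistic.
- Percentile endpoints are always members of the replicate set; BCa uses
  the same rank rule, so it reduces to the percentile interval exactly when
  z₀ = 0 and a = 0, and all families collapse to the point estimate when
  the replicate set is constant (zero-residual data).
- An exact regression fit (robust scale below 1e−12) terminates IRLS with
  unit weights; rank-deficient designs raise a collinearity error.
- Missing months inside a window are always an error: the pipeline assumes
  complete monthly series (as its intended inputs are), and the generator
  emits complete series. Relaxed pairwise-complete handling is a known
  omission, not a silent behavior.
- Bootstrap seeds: every SI derives its generator from
  (root seed, CRC32(area id), recruit year), so per-year results are
  independent of evaluation order; the regression bootstrap uses the root
  seed directly. Identical inputs and seeds give byte-identical outputs.

## The synthetic-data generator

`sipipe.simulate` emulates the phenology the SI is designed to detect with
a single annual cosine harmonic per variable — the simplest structure that
produces MLD-driven CHL seasonality:

- MLD_t = μ_MLD + A_MLD·cos(2π(t − φ)/12) + ε, deepest in late winter
  (φ = 1 month);
- CHL_t follows the same cycle delayed by `phase_lag` months (0 = perfect
  synchrony, 6 = anti-phase);
- SST_t shares the cycle plus a linear trend (0.02 °C/yr by default);
- ε is i.i.d. Gaussian per month (an AR(1) option exists, off by default —
  the SI makes no distributional assumption, so the independent null
  suffices); CHL and MLD are floored at 0.01 in their own units.

The three default area scenarios place means and amplitudes inside the
observed regimes (MLD ≈ 12–50 m SoS, 12–76 m GoL, 12–72 m AS; CHL
0.05–0.49, 0.09–0.93 and 0.16–1.28 mg/m³) and set phase lags of 0, 1 and 2
months with noise such that the analytic plus-noise correlation
cos(2π·lag/12)/√((1+v₁)(1+v₂)) (v = noise/signal variance ratio) lands at
the SI regimes the three ecosystems exhibit (≈ 0.8, ≈ 0.6, ≲ 0.5).
Simulated per-area SI means are 0.85, 0.67 and 0.30. Spans are 18, 18 and
15 recruitment years (2002–2019, 2002–2019, 2004–2018).

Recruitment is generated from the regression model itself: per area,
y = β₀ + β_SI·SI_scaled + β_SST·SST_scaled + ε, ε ~ N(0, σ_y), y clipped
to [0, ln 2], abundance = A_min + (e^y − 1)(A_max − A_min) with per-area
abundance bounds spanning the observed orders of magnitude
(~10⁵–2·10⁷ thousand individuals). Defaults: β = (0.21, 0.21, −0.07),
σ_y = 0.25.

**Why σ_y = 0.25, and the inversion caveat.** The analysis standardizes
recruitment by the *realized* series extremes, so the response it fits
always spans [0, ln 2] per area. The generative inverse is therefore
faithful only when the generated y itself attains both ends of that range
— exactly (one can show pipeline-response = y for a monotone abundance map
iff expm1(y_min) = 0 and expm1(y_max) = 1). With the default coefficients
the noise-free linear predictor spans only ≈ [0.14, 0.42], so at low noise
the recovered SI slope is inflated by the log-range stretch (≈ ×2.9 at
zero noise). The default σ_y = 0.25 puts the generator in the faithful
regime: clipping anchors each area's realized response to its scaling
extremes, and the post-clipping residual spread (≈ 0.22) matches the
residual scale implied by the reported uncertainty of the slope (bootstrap
SE ≈ 0.09 at n = 51 → σ ≈ 0.18–0.19). Consequences tested rather than
assumed: with a full-span truth (β = (0, ln 2, 0)) and zero noise the
pipeline recovers the coefficients to 1e−8; with the default truth and
zero noise the inflation is asserted and bounded; at default noise the
recovery experiment (200 seeded studies, B = 999) recovers the SI slope
with median error ≲ 0.02 and ≈ 95% BCa coverage, and reports a null SST
effect as non-significant in ≳ 95% of runs.

**What the generator does not emulate** — and hence what passing tests do
not show about real data: multi-modal bloom shapes (e.g. subtropical
regimes), autocorrelated and non-Gaussian environmental noise (by
default), observation error in acoustic abundance estimates, regime shifts
or trends in recruitment unrelated to SI, and any spatial structure. The
recovery results certify the estimation machinery, not the ecological
model.

## Problem sizes

The default study (and everything the acceptance script reports) uses the
real design sizes: 18 + 18 + 15 = 51 area-years and B = 2999. The test
suite's repeated-simulation experiments use 200 studies at B = 999 for
parameter recovery, 500 replications at B = 599 for SI-CI coverage, and
bootstrap sizes of a few hundred in smoke tests, chosen to keep the suite
in the minutes range while leaving Monte-Carlo error well below the margins
being asserted.

## Known limitations

- The intercept is pooled; no per-area fixed or random effects, mirroring
  the single-model design the pipeline reproduces.
- The SI window assumes survey timing is fixed across years.
- The Huber ψ, k = 1.345 and MAD scale are conventional choices; the
  analysis they summarize did not pin them, and alternatives (bisquare,
  different k) are not implemented.
- BCa assumes the jackknife acceleration is stable, which can be optimistic
  at n ≈ 50 with influential rows; the three families are reported side by
  side precisely so disagreement is visible.
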