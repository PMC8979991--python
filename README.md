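# sipipe

Pipeline linking European anchovy recruitment to an environmental
**Synchronicity Index (SI)** in three Mediterranean ecosystems — the Strait
of Sicily (SoS), the Gulf of Lions (GoL) and the Adriatic Sea (AS).

Anchovy recruitment (the abundance of Age-1 fish entering the population) is
thought to depend on how tightly *enrichment* (chlorophyll-a, CHL) and
*concentration/retention* (mixed layer depth, MLD) processes co-evolve during
a cohort's first year of life. `sipipe` quantifies that synchrony and relates
it to recruitment:

1. **Observation window.** For recruitment year *t*, the window runs from the
   spawning onset (April of year *t* − 1) to the month preceding the acoustic
   survey of year *t* (July for SoS/GoL, June for AS): 15 months for SoS and
   GoL, 14 for AS.
2. **Synchronicity Index.** Over each window, SI = the *percentage bend
   correlation* ρ_pb between monthly CHL and MLD (bend fraction β = 0.2) — a
   robust Pearson correlation on bend-standardized, clipped deviations that a
   fraction β of marginal outliers cannot bias. A 95% CI comes from 2999
   resamples of month pairs.
3. **Pooled robust regression.** Per area, recruitment R, SI and windowed
   mean SST are min–max scaled to [0, 1]; the response is
   y = ln(1 + R_scaled) ∈ [0, ln 2], and the pooled model

       y = β₀ + β_SI · SI_scaled + β_SST · SST_scaled + ε

   is fit by Huber M-estimation (IRLS, k = 1.345). Coefficient uncertainty
   comes from a random-X (case-resampling) bootstrap with 2999 replicates,
   reported as Normal, percentile and BCa 95% intervals.
4. **Synthetic studies.** A generator produces seasonal CHL/MLD/SST series
   with a controllable CHL–MLD phase lag and recruitment drawn from the
   regression model, so the whole pipeline is testable end to end and its
   ability to recover known coefficients can be measured.

## Worked example

```python
from sipipe.pipeline import run_synthetic

result = run_synthetic("outputs", seed=1, n_boot=2999)
for est in result.si_estimates[:1]:
    print(est.area_id, est.recruit_year, round(est.rho_pb, 3), est.significant)
print(result.cis.to_frame().head(3).to_string(index=False))
```

prints

```
SoS 2002 0.801 True
coefficient  estimate family    ci_low  ci_high  significant
  Intercept  0.122497 normal -0.033981 0.278975        False
         SI  0.419534 normal  0.241585 0.597484         True
        SST -0.037511 normal -0.264626 0.189603        False
```

The first line is one area-year SI: CHL and MLD co-varied strongly over the
15-month window (ρ_pb = 0.801) and the bootstrap CI excludes zero.
The table is one interval family of the fit on this synthetic study: a
significantly positive SI effect on standardized recruitment and a
non-significant SST effect, the qualitative structure the index is designed
to expose. Per-area SI averages for this run are 0.85 (SoS), 0.67 (GoL) and
0.30 (AS), reflecting the decreasing CHL–MLD synchrony built into the three
default scenarios.

The same run from a shell:

```bash
sipipe run --synthetic --seed 1 --boot 2999 --out outputs
```

which writes `si_table.csv` (one SI row per area-year), `fit_table.csv`
(3 coefficients × 3 interval families), `diagnostics.csv` (residual
normality, heteroscedasticity and lag-1 autocorrelation checks),
`pearson_screen.csv` (per-area SI–SST collinearity screen) and a
`manifest.json` recording the seed, bootstrap size and config hash.

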