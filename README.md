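# fluorisk

Probabilistic health-risk assessment of fluoride in drinking water.

Chronic ingestion of fluoride above ~1.5 mg/L causes dental and, at higher
doses, skeletal fluorosis. `fluorisk` is a Python package for analysts who
need to turn site-level water-quality measurements into population risk
estimates: deterministic hazard quotients per sampling site and age cohort,
fluorosis-endpoint prevalence, Monte Carlo uncertainty propagation with
contribution-to-variance sensitivity analysis, and a neural-network
surrogate that predicts the hazard quotient directly from exposure features.

## Model

For a receptor cohort with body weight `BW` (kg), water ingestion rate `IR`
(L/day), exposure frequency `EF` (days/year), exposure duration `ED` (years)
and averaging time `AT` (days), a concentration `C` (mg/L) gives

```
TDI = C · IR                          total daily intake, mg/day
CDI = C · IR · EF · ED / (BW · AT)    chronic daily intake, mg/kg/day
HQ  = CDI / RfD                       hazard quotient, dimensionless
```

with the fluoride reference dose `RfD = 0.06` mg/kg/day. `HQ > 1` flags a
potential non-carcinogenic risk. Three default cohorts ship with the package
(children 2–6, teenagers 7–18, adults 18–62); all satisfy `EF·ED = AT`, so
their HQ reduces to `C·IR/(BW·RfD)`.

Uncertainty is propagated by Monte Carlo: each input gets a parametric
distribution (point, uniform, triangular, truncated normal, lognormal, or a
mixture), joint draws are pushed through the equations, and risk is
summarized by percentiles (P95 is the headline statistic). Input importance
is ranked by contribution to variance, the normalized squared Spearman rank
correlation between each input and HQ.

The surrogate is a small feed-forward network (ReLU hidden layers, linear
output, L2 penalty) selected from a candidate grid by 5-fold
cross-validation and trained with early stopping on a held-out validation
split; because HQ is a smooth deterministic function of its six features,
the surrogate reaches R² > 0.99 on held-out data.

A packaged 17-site district configuration (summary statistics of five
replicates per site) drives all examples, and a constrained synthetic
generator reconstructs replicate vectors whose min/max match the summaries
exactly and whose means match to within 0.005 mg/L.

## Worked example

```python
import fluorisk as fk

sites = [fk.SiteRecord.from_summary(s.site_id, s.location_name,
                                    fk.SiteSummary(s.min, s.max, s.mean, s.std))
         for s in fk.default_site_specs()]
results = fk.exposure_table(sites, fk.DEFAULT_COHORTS)

summary = fk.district_summary(sites, threshold=1.5)
print(f"district mean {summary.mean_of_means:.2f} mg/L, "
      f"{summary.exceedance_pct:.1f}% of site means > {summary.threshold} mg/L")

for cohort, mean_hq in fk.mean_hq_by_cohort(results).items():
    print(f"{cohort:10s} mean HQ {mean_hq:.2f}")

report = fk.classify_sites(results)
for name, p in report.cohorts.items():
    print(f"{name:10s} dental-fluorosis prevalence {p.fraction_pct_display}% "
          f"({p.n_exceeding}/{p.n_total} sites)")
```

prints

```
district mean 2.30 mg/L, 88.2% of site means > 1.5 mg/L
children   mean HQ 1.99
teenagers  mean HQ 1.53
adults     mean HQ 1.23
children   dental-fluorosis prevalence 94% (16/17 sites)
teenagers  dental-fluorosis prevalence 88% (15/17 sites)
adults     dental-fluorosis prevalence 65% (11/17 sites)
```

The district mean concentration (2.30 mg/L) exceeds the 1.5 mg/L guideline
at 15 of 17 sites; children carry the highest risk (site HQs from 0.50 to
3.29), and under the dental endpoint 94% of sites put children above HQ = 1.

The same pipeline is available from the shell:

```sh
fluorisk hq  --out run                 # exposure table + district summary
fluorisk mcs --seed 1 --out run        # Monte Carlo P95 + tornado CSV
fluorisk ann --seed 1 --out run        # surrogate training + metrics
fluorisk report --run run --out report.json
```

`fluorisk mcs --seed 1` reports P95 HQs of 3.39 / 2.58 / 2.09 for
children / teenagers / adults under the default input distributions, with
concentration contributing ~75% of the output variance, body weight ~17%
and ingestion rate ~8%.

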