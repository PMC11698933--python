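# Methods

## Exposure model

The deterministic engine implements the standard drinking-water ingestion
model: chronic daily intake `CDI = C·IR·EF·ED/(BW·AT)` (mg/kg/day) and
hazard quotient `HQ = CDI/RfD`, with total daily intake `TDI = C·IR`
(mg/day) reported alongside. Both intake quantities are exposed with
explicit unit labels because field reports frequently tabulate `C·IR` under
a "CDI" heading; keeping the two separate preserves compatibility with such
tables while keeping the mg/kg/day quantity dimensionally honest.

Default cohort parameters (units: AT days, EF days/year, ED years, BW kg,
IR L/day, RfD mg/kg/day):

| cohort    | AT    | EF  | ED | BW | IR   | RfD  |
|-----------|-------|-----|----|----|------|------|
| children  | 1460  | 365 | 4  | 15 | 0.78 | 0.06 |
| teenagers | 4745  | 365 | 13 | 50 | 2.0  | 0.06 |
| adults    | 14600 | 365 | 40 | 78 | 2.5  | 0.06 |

All three satisfy `EF·ED = AT`, so HQ collapses to `C·IR/(BW·RfD)`. A
cohort violating that identity is legal but triggers a validation warning,
since in practice it indicates a transcription error.

Numerical conventions: display rounding is half-away-from-zero (HQ to 2
decimals, TDI to 3, concentrations to 2); raw values are always retained
next to their rounded twins. District exceedance is computed on site means
with a strict inequality (a site exactly at the threshold does not count);
replicate-level exceedance is additionally reported when replicates exist.
A degenerate site with `min = mean = max` and zero spread is legal.

## Endpoint prevalence

A site counts toward an endpoint's prevalence when its mean-concentration
HQ strictly exceeds the endpoint threshold (default 1.0). Only the dental
endpoint ships with defaults; endpoint-specific reference doses for bone or
skeletal fluorosis must be supplied by the user as overrides — the package
deliberately refuses to invent reference doses it cannot source. Display
fractions are rounded to the nearest integer percent; unrounded values are
retained.

## Monte Carlo engine

Inputs are treated as independent (no copulas). Supported families: point,
uniform, triangular, truncated normal, lognormal (log-scale parameters,
optional bounds by rejection) and finite mixtures. Each input draws from a
substream keyed by the input's *name* (a hash folded into the seed), so the
draws for one input are invariant to which other inputs appear in the
specification — this makes degenerate-equivalence and ablation tests exact.

Default study configuration: the concentration is a uniform mixture over
per-site triangular(min, mode = mean, max) distributions — bounded,
assumption-light, and anchored entirely in the reported summaries; body
weight and ingestion rate are truncated normals centred on the cohort
values, bounded at ±3 sd. Their coefficients of variation default to 0.15
(BW) and 0.10 (IR): population body-weight spread is generally larger than
per-capita drinking-water-intake spread, and distinct CVs make the default
importance ranking (C > BW > IR) well defined — with equal CVs the
multiplicative model gives BW and IR identical expected contributions and
the ranking would be decided by sampling noise. EF, ED and AT stay at point
masses. These defaults are this package's own modelling choices; they are
not a reconstruction of any particular proprietary tool's fitted
distributions, so cross-study P95 comparisons should be read as
order-of-magnitude checks.

Percentiles use linear interpolation between order statistics. Default
iteration count is 10,000. Sensitivity is "contribution to variance":
`ρ_i²/Σ_j ρ_j² × 100%` with ρ the Spearman rank correlation between an
input's draws and HQ; point-mass inputs get exactly 0%, and the signed ρ is
retained for tornado-chart direction. A convergence check tracks the
cumulative P95 across blocks and flags a maximum relative drift above 1%.

## Synthetic replicates

Per-site replicate vectors are reconstructed from (min, max, mean, std)
targets: the two extremes are fixed exactly, the interior values start at
the mean-balancing point, and a seeded zero-sum perturbation is added whose
amplitude is solved in closed form to match the target variance — capped so
no value leaves [min, max]. Consequences: min/max are attained exactly and
the mean is exact up to float rounding under every seed, while std is
matched only approximately (observed within ~8% on the default
configuration, guaranteed within ±30%): with five replicates the extremes
and mean already fix three degrees of freedom, so the variance cannot
always be reached. Mean takes priority because every downstream headline
number (HQ tables, district summary, prevalence) depends on means and
extremes, not on the replicate spread. Replicates are exchangeable; no
temporal sampling structure is modelled.

What the generator does *not* emulate: measurement error correlated across
sites, seasonal trends, or spatial autocorrelation — passing tests on
synthetic studies therefore validate the pipeline's algebra and protocols,
not field-data robustness.

## Surrogate

The learnable function is `HQ(C, EF, IR, ED, BW, AT)` — deterministic and
piecewise smooth — so the surrogate task is function approximation, not
noise-robust regression; near-perfect held-out R² is the expected outcome
and is used as the pipeline's integration check.

Dataset: one row per water replicate (85 rows for the default study). Each
row is assigned one cohort uniformly at random (seeded) so that all six
features vary across rows; assigning every cohort to every replicate would
triple the row count and make the cohort features block-constant. The
target is the analytic HQ. Split fractions 0.8/0.1/0.1 land on 69/8/8 rows;
the 10% validation split drives early stopping, the 10% test split is used
only for final metrics. Standardization (z-scoring) is fitted on training
rows only; the EF column is constant under the default cohorts and is
centred but not rescaled.

Hyperparameter grid: architectures (64,32,16), (128,64,32), (64,32),
(128,64); L2 strengths 0.01 and 0.1; learning rates 0.01 and 0.001 —
ranked by 5-fold cross-validated MSE inside the training split, ties broken
by fewer parameters, diverging candidates marked failed rather than fatal.
Final training runs full-batch Adam one epoch at a time (the optimizer's
moment estimates persist across epochs), records per-epoch train/validation
MSE, stops after 100 epochs without validation improvement (cap 2000
epochs, cross-validation fits capped at 800), and restores the best-epoch
weights. Reaching the epoch cap returns the model with an explicit
non-convergence flag. Restart-to-restart spread matters at this data size,
so reported accuracy is the best of 5 seeded restarts.

Models serialize to JSON (weights, scaler statistics, history, metrics);
prediction runs a numpy forward pass from the stored matrices and warns
when a query lies outside the training hull widened by 20% per feature.

## Problem sizes

Defaults throughout are the study-scale settings: 17 sites × 5 replicates,
10,000 Monte Carlo iterations, the full 16-candidate hyperparameter grid
with 5-fold cross-validation and 5 training restarts. The test suite and
the acceptance script run these sizes directly; only smoke tests of the
training loop use a single reduced candidate.

## Known limitations

- Single contaminant; no multi-contaminant hazard index.
- Independent Monte Carlo inputs; no correlated sampling, no Sobol indices.
- Rank-correlation sensitivity misattributes strongly non-monotone effects
  (not an issue for the multiplicative intake model).
- The surrogate interpolates; outside the training hull it extrapolates
  with a warning and no error bound.
- No spatial interpolation or mapping outputs.
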