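# Methods

## The transfer-function model

WA-PLS regresses one climate variable on pollen percentages. Percentages
(0–100) are used directly as the abundances `y_ik`; the algorithm is
invariant to rescaling any sample by a positive constant, so proportions
give identical output (tested). Because every percent row sums to 100, the
site weights `w_i = y_i+/y_++` are uniform and the internal weighted
least-squares deshrinking coincides with ordinary least squares; the
weighted formulation is kept so that count matrices or unequal row sums are
handled correctly if supplied.

Deshrinking is implicit in the final regression of climate on the
standardized component scores (inverse-style); there is no separate
classical deshrinking step. With one component this reduces exactly to
weighted averaging with inverse deshrinking, which the suite verifies
against an independently coded estimator at 1e-8.

Numerical choices:

* a component whose weighted site-score sd falls below 1e-12 raises
  `DegenerateComponentError` naming the component (no gradient information);
* taxa with zero column sums in training are dropped with a logged warning
  (their scores are undefined); at prediction time, taxa unknown to the
  model are ignored after taxon harmonization (zero-filled columns carry no
  weight);
* the final regression is solved by `lstsq` on the square-root-weighted
  design, not the normal equations;
* an optional square-root transform of abundances is available
  (`sqrt_transform=True`) but off by default, since percentages untransformed
  are the common convention for these data.

Components default to 2 (WA-PLS2), configurable.

## Cross-validation

Leave-one-out refits the model n times and predicts each withheld site;
RMSEP_loo is the rms residual. The bootstrap validator resamples sites with
replacement `n_boot` times (library default 1000), predicts the out-of-bag
sites each cycle, and decomposes the error as `RMSEP_boot² = s1² + s2²`,
where `s2` is the rms of each site's mean out-of-bag error (systematic
part) and `s1` the rms of the per-site sd of out-of-bag predictions
(training-set sampling part). A site that is never out-of-bag at least
twice raises an error advising a larger `n_boot`. Seed-swept tests and the
acceptance script use `n_boot = 500`, at which the estimate is already
stable to well under the tolerances being checked.

Note that even when a hindcast is exactly the apparent fit (the identity
experiment, training and target sets equal), RMSEP_boot exceeds the
apparent RMSE by whatever margin the model overfits — 5–30 % under the
default count noise — so the hindcast-vs-RMSEP contrast is only meaningful
in sign and large magnitudes, not within that band.

## Analog analysis

Squared chord distance on the percent scale, `Σ_k (√p_k − √q_k)²`, ranges 0
to 200 and makes published minimum-distance magnitudes directly comparable;
a config switch computes on the proportion scale (values 100× smaller). The
measure is symmetric and zero only at equality but does not satisfy the
triangle inequality, so it is reported as a dissimilarity. Era summaries
select samples by age-interval midpoint; ties in nearest-site search go to
the first site in file order. No-analog thresholds are deliberately not
applied — raw distances are reported.

## Hindcast bias experiments

Residuals are predicted − observed, so positive means warm bias. The
observed reference for a hindcast is the target set's own climate table; in
the synthetic experiments this pairing is exact, and the disturbance
scenario's climate offset emulates the imperfect pairing of real studies
(normals measured decades after the pollen was deposited). The summary
`improvement_percent` is `100 × (RMSE_hindcast − RMSEP_boot) / RMSEP_boot`,
rounded to an integer.

## The synthetic-data generator

The generator emulates the structure of a Minnesota-style study — it defines
the study conditions for all tests, not a tunable benchmark:

* **Taxon pool**: 25 taxa by default; unimodal (Gaussian) response to each
  of two climate variables (February and May monthly mean temperature, °C),
  multiplied across variables — the canonical response model behind
  weighted averaging. Optima uniform on each gradient (February −16…−6 °C,
  May 8…18 °C, a realistic upper-Midwest spread), tolerances uniform on
  1–4 °C, heights log-uniform on 0.5–2, ecological groups (ruderal /
  arboreal / herb) assigned round-robin so groups are climate-neutral in
  expectation.
* **Sites**: 133 by default, matching the density of a well-populated
  regional pollen network. Site climates share one latent gradient position
  (latitude-like) plus 0.6 °C jitter per variable, so months correlate
  across sites as they do across real stations.
* **Counts**: multinomial with 300 grains per sample, a typical pollen sum.
* **Disturbance scenario** (the "modern" twin): expected abundances scaled
  by group (ruderal ×3, arboreal ×0.6, herb ×0.8 — the direction and order
  of magnitude of post-settlement land-clearance shifts), counts resampled,
  and the climate table shifted by the normals warming (February +2.07 °C,
  May +1.57 °C, the observed late-20th-century minus mid-19th-century
  monthly differences). Because the compositional perturbation is
  climate-neutral in expectation, the injected hindcast bias is the climate
  offset itself, which the bias-recovery tests check to ±0.3 °C over seeds.
* **Down-core record**: AD 1116–2002 at 4-year contiguous intervals
  (a trailing shorter interval is kept and logged); each sample is generated
  from the mean climate over its interval. The default history is a
  Medieval baseline at the gradient centre, a −1.0 °C Little Ice Age step
  over 1450–1850, a +2.0 °C linear ramp from 1850 to the end of the record,
  and 1.0 °C interannual white noise.

What the generator does **not** emulate: spatial autocorrelation among
sites, pollen dispersal and taphonomy, varve-thickness variability,
vegetation lags behind climate, and secular drift within the calibration
normals. Passing tests therefore demonstrate that the statistical machinery
recovers known signals under the stated noise model — not that any
particular real-world record is unbiased.

## Comparison statistics

Interval alignment averages the annual instrumental series over each
sample's inclusive varve-year interval; samples partially outside the
series are dropped with a log message. Location tests default to Welch's
unequal-variance t (the degrees of freedom printed in the reference
comparisons for 15-per-group data are only consistent with
Welch–Satterthwaite); `equal_var=True` restores pooled Student's t. The
variance F-test is two-sided by doubling the smaller tail. Period and era
membership is by interval midpoint throughout. `variance_captured` is the
plain ratio `100 × var(reconstruction)/var(instrumental)` over aligned
samples; note that published "variance captured" figures computed by other
(unstated) definitions can differ several-fold from this ratio — e.g. an
aligned sd ratio of 0.38/2.17 corresponds to ≈3.1 % under this definition —
so cross-study comparisons should compare definitions first.

`extend_series_by_regression` splices a short station record onto a longer
correlated neighbour: OLS over the overlap, gap years filled with fitted
values, observed years kept verbatim, adjusted r² reported. At least 10
overlap years are required.

## Formats and conventions

CSV interchange: comma-separated, UTF-8, `.` decimal, first column `id`.
Percent rows within 100 ± 0.5 are accepted on read and renormalized with a
logged warning (legacy rounding); internally constructed matrices are held
to 1e-6. Taxon matching trims whitespace and case-folds; no synonym
resolution. Ages are calendar years AD with intervals inclusive on both
ends (a 4-year sample 1820–1823 covers four instrumental years). The pollen
sum is the input matrix's full taxon set; excluding disturbance indicators
(e.g. *Ambrosia*, Poaceae) and renormalizing is provided as an explicit
sensitivity transform, idempotent under re-application.

## Problem sizes

Default test and acceptance-script sizes: 133 sites × 25 taxa, 300 grains,
500 bootstrap cycles, 20-seed sweeps for direction-recovery properties and
5-seed sweeps for parameter recovery. These sizes give stable estimates for
every quantity checked while keeping a full run in the seconds-to-a-minute
range.
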