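# pollenclim

Tools for quantitative paleoclimate reconstruction from pollen assemblages,
aimed at paleoecologists who build pollen–climate transfer functions and
want to audit them: fit and cross-validate WA-PLS models, assess modern
analogs, quantify the bias introduced by training on a calibration set from
the wrong era, and compare down-core reconstructions with early instrumental
temperature records.

The scientific question the package addresses: inferring past temperature
from sedimentary pollen assumes the pollen–climate relationship is
stationary in time. Where humans have reshaped vegetation (land clearance,
fire suppression, agriculture), a *modern* calibration set couples disturbed
pollen rain to late-20th-century climate normals, and a transfer function
trained on it can systematically misread pre-industrial assemblages —
typically running warm and attenuating low-frequency variance. `pollenclim`
makes that failure mode measurable, and ships a synthetic-data generator
with known ground truth so the whole chain is testable end to end.

## The core method

**WA-PLS** (weighted-averaging partial least squares) relates a sites × taxa
matrix of pollen percentages `y_ik` to a climate variable `x_i`. With
marginal totals `y_i+`, `y_+k` and site weights `w_i = y_i+ / y_++`,
component `a` is extracted from the current residual `r_i` (initialized to
`x_i`) by

1. taxon scores  `u_k = Σ_i y_ik r_i / y_+k`  (weighted averaging of the residual),
2. site scores  `s_i = Σ_k y_ik u_k / y_i+`,
3. orthogonalization of `s` against earlier components under the site
   weights, then standardization to weighted mean 0 / sd 1,
4. a weighted least-squares regression of `x` on components `1..a`
   (the deshrinking step); its residuals feed the next component.

Two components (WA-PLS2) is the conventional choice. Component 1 alone is
classical weighted averaging with inverse deshrinking; the test suite checks
that equivalence against an independently coded WA estimator.

Around the estimator: leave-one-out cross-validation (RMSEP_loo), bootstrap
cross-validation with the `RMSEP_boot² = s1² + s2²` decomposition, the
squared chord distance `d(p, q) = Σ_k (√p_k − √q_k)²` for analog screening,
cross-era hindcast experiments, and reconstruction-vs-instrumental
statistics (interval averaging, Welch/paired t, variance-ratio F, OLS
trend, moving average, variance-captured).

## Worked example

```python
import numpy as np
import pollenclim as pc

# a 133-site calibration set with known truth, and its disturbed twin
model  = pc.make_species_pool(25, seed=11)
cal    = pc.generate_calibration(model, n_sites=133, seed=7)
modern = pc.apply_disturbance(cal, pc.DisturbanceScenario(), seed=13)

cv = pc.loo_cross_validate(cal, "feb_mean_temp")
print(np.corrcoef(cv.predicted, cv.observed)[0, 1], cv.rmsep_loo)

report = pc.bias_experiment(cal, modern, "feb_mean_temp", n_boot=500, seed=1)
print(report.mean_bias, report.rmse, report.boot.rmsep_boot,
      report.improvement_percent)
```

prints (to the shown precision):

```
LOO r = 0.986, RMSEP_loo = 0.50 °C, apparent RMSE = 0.48 °C
hindcast mean bias = +2.08 °C
hindcast RMSE = 2.15 °C vs RMSEP_boot = 0.50 °C -> +330%
```

Reading: the pre-settlement-style set cross-validates cleanly (r = 0.986
against the generating climate, half-degree prediction error). Training
instead on the disturbed twin — whose pollen was perturbed by land-clearance
factors and whose climate table carries +2.07 °C warmer normals — and
hindcasting onto undisturbed assemblages recovers that injected offset as a
+2.08 °C warm bias, and the cross-era RMSE is several times the reference
set's own bootstrap prediction error. The analog analysis shows the same
asymmetry from the assemblage side: pre-1850 down-core samples sit at a mean
minimum squared chord distance of 3.3 from the undisturbed set but 12.3 from
the disturbed one.

A command-line interface wraps the same library:

```
pollenclim simulate --seed 3 --out-dir study/
pollenclim fit --pollen study/cal1870_pollen.csv --climate study/cal1870_climate.csv \
    --variable feb_mean_temp --save study/model.json
pollenclim reconstruct --model study/model.json --fossil study/fossil.csv --out-dir study/
pollenclim analogs --fossil study/fossil.csv --pollen study/modern_pollen.csv \
    --climate study/modern_climate.csv --out-dir study/
```

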