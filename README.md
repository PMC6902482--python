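# overlapdyn

Dynamics of joint space use between two GPS-tracked animals.

Ecologists often need to know not just *whether* two individuals share
space, but *how their shared space use changes through time* — after a
resource appears, a disturbance hits, or a season turns. `overlapdyn`
implements a time-series framework for exactly that question:

1. partition each animal's GPS fixes into a-priori time windows (e.g.
   weeks);
2. estimate each animal's **utilization distribution** (UD) per window by
   kernel density estimation;
3. compute **Bhattacharyya's Affinity** (BA) between the two UDs per
   window, yielding a bounded (0, 1) time series of joint space use;
4. regress that series on covariates with a **Gaussian-copula marginal
   beta regression** whose errors follow an ARMA(p, q) process, so that
   serial dependence is modelled without distorting the interpretation of
   the regression coefficients.

It also ships the accompanying simulation study quantifying how the bias
and precision of the BA estimator and of regression effect sizes depend
on GPS sampling intensity.

## The model

Per animal *i* and window *t*, the UD is a fixed-kernel estimate with a
bivariate normal kernel,

    UD_it(x) = 1/(n h²) Σ_j (2π)^{-1} exp(-‖x - X_j‖² / (2h²)),

with the bivariate reference smoothing parameter
h = sqrt((s²x + s²y)/2) · n^(-1/6). Overlap between the two animals in
window *t* is

    BA_t = ∬ √(UD_1t(x, y)) √(UD_2t(x, y)) dx dy ∈ [0, 1],

computed by cell-centre quadrature on a grid shared by both UDs. For two
circular bivariate normal UDs with common σ and means d apart,
BA = exp(-d²/(8σ²)) in closed form — the truth oracle used throughout the
tests and the simulation study.

The BA series is modelled marginally as Beta(μ_t, κ) with
logit(μ_t) = X_tᵀβ (mean–precision parameterization, shapes μκ and
(1-μ)κ). Dependence between windows enters through a Gaussian copula: the
latent scores z_t = Φ⁻¹(F(y_t; μ_t, κ)) are jointly normal with the
correlation structure of a stationary, invertible ARMA(p, q) process.
Because the margin is continuous the likelihood is available in closed
form and is maximized directly; β keeps its GLM interpretation, and
covariate effects are reported on the BA scale as
logistic(x_toᵀβ) - logistic(x_fromᵀβ) with delta-method or bootstrap
intervals. An interrupted time-series design is a one-line special case:
a step covariate x_t = 1{t ≥ t_event}.

## Worked example

```python
import numpy as np
from overlapdyn import StepScenario, run_replicate

scenario = StepScenario()   # 100 windows, separation 3.580 -> 1.319 at t=50
print(f"true BA: {scenario.true_ba_before:.4f} -> {scenario.true_ba_after:.4f} "
      f"(step effect {scenario.true_effect:.4f})")

rep = run_replicate(scenario, n_locs=150, rng=np.random.default_rng(42))
fit = rep.fit
for name, est, se in zip(fit.param_names, fit.params, fit.se):
    print(f"{name:>8s}  {est:9.4f}  (se {se:.4f})")
eff = rep.effect
print(f"effect on BA scale: {eff.delta:.3f}  "
      f"95% CI [{eff.ci_low:.3f}, {eff.ci_high:.3f}]")
```

prints

```
true BA: 0.2015 -> 0.8046 (step effect 0.6031)
  beta_0    -1.2400  (se 0.0281)
  beta_1     2.6388  (se 0.0408)
   kappa   143.9663  (se 20.3142)
effect on BA scale: 0.578  95% CI [0.564, 0.591]
```

Reading this: with 150 locations per window the fitted pre-change mean BA
is logistic(-1.240) ≈ 0.22, the post-change mean logistic(1.399) ≈ 0.80,
and the estimated step effect 0.578 sits slightly below the true 0.603 —
the characteristic small negative bias caused by overestimating low BA
values at finite sampling intensity.

The same pipeline is available from the shell for real tracking data:

```sh
overlapdyn ba-series fixes.csv --id-a M09 --id-b F13 \
    --origin 2017-04-01 --width 7D --out ba.csv
overlapdyn fit ba.csv --change-week 25 --p 1 --q 1 --out report.json \
    --residuals-out residuals.csv
overlapdyn diagnose residuals.csv
overlapdyn simulate --n-reps 20 --intensities 50,150,1000 --seed 1 \
    --out-dir study/
```

Coordinates must already be in a projected (planar) coordinate system;
the package performs no geographic reprojection. The window origin is a
required user choice — calendar-anchored and deployment-anchored weeks
give materially different series.

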