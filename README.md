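# hcmb3 — the half-circular modified Burr-III distribution

`hcmb3` is a Python toolkit for modelling **axial (half-circular) data** —
angles defined modulo π, such as the posterior corneal curvature of the eye,
crystal optical axes, or particle long-axis orientations. Ordinary circular
distributions live on [0, 2π) and waste their flexibility on directions that
axial data cannot distinguish; `hcmb3` instead provides a three-shape-parameter
law on [0, π) built by **inverse stereographic projection** of the modified
Burr-III distribution: with x = tan(θ/2),

    G(θ) = [1 + γ tan(θ/2)^(−β)]^(−α/γ),          α, β, γ > 0,  0 < θ < π,

whose density can be symmetric, positively or negatively skewed, uni- or
bimodal, with increasing or bathtub hazard. Its sub-models (γ = 1 gives the
half-circular Burr III; α = γ the half-circular log-logistic; γ → 0 the
half-circular generalized inverse Weibull) and the projected gamma and
Burr XII laws are included for model comparison.

The package is aimed at statisticians and biomedical researchers who need to
fit, compare and simulate half-circular models:

* **Distribution core** — pdf, cdf, closed-form quantile, hazard rate, seeded
  inverse-transform sampling, empirical mode search (`HalfCircularMB3`).
* **Circular summaries** — trigonometric moments (α_p, β_p) by adaptive
  quadrature, mean direction μ = arctan(β₁/α₁), mean resultant length
  ρ = √(α₁²+β₁²), circular variance v = 1 − ρ, SD, skewness and kurtosis,
  with empirical counterparts for samples.
* **Eight estimators** — maximum likelihood (with observed-information SEs and
  asymptotic CIs), ordinary/weighted least squares on the cdf, percentile
  matching, maximum product of spacings, and the Cramér–von Mises,
  Anderson–Darling and right-tail Anderson–Darling minimum-distance methods —
  exposed both as functions and as a scikit-learn style
  `HalfCircularMB3Estimator` (`fit` / `score` / `get_params`).
* **Goodness of fit** — AIC/CAIC/BIC, modified A* and W* statistics, the
  Kolmogorov–Smirnov test, the TTT (total time on test) transform, and a
  ranked multi-family comparison table.
* **Monte Carlo harness** — reproducible bias/MSE comparison of all eight
  estimators across sample sizes (`SimDesign`, `run_simulation`,
  `rank_methods`).
* **CLI** — `hcmb3 fit | gof | summarize | simulate | ttt | fixture` over
  delimited-text or XLSX angle files (radians or degrees).

## Worked example

```python
import numpy as np
from hcmb3 import HalfCircularMB3, HalfCircularMB3Estimator, summarize_distribution

# a seeded synthetic sample of 500 axial angles from hcMB-III(2, 3, 4)
theta = HalfCircularMB3(2, 3, 4).rvs(500, seed=42)

est = HalfCircularMB3Estimator(method="MLE").fit(theta)
print("MLE:", np.round(est.params_, 3), "SE:", np.round(est.result_.se, 3))

s = summarize_distribution(est.params_)
print(f"rho = {s.resultant_length_rho:.4f}  variance = {s.variance_v:.4f}")
```

prints

```
MLE: [2.128 3.211 4.464] SE: [0.471 0.283 1.599]
rho = 0.8176  variance = 0.1824
```

— the fitted shapes recover the generating triple (2, 3, 4) well within one
standard error each, and the fitted law has mean resultant length 0.82
(a concentrated axial distribution). The same analysis from the shell:

```sh
hcmb3 fixture --params 2,3,4 -n 500 --seed 42 --out sample.csv
hcmb3 fit sample.csv --method all          # all eight estimators
hcmb3 gof sample.csv                       # six-family AIC/BIC/A*/W*/K-S table
hcmb3 summarize --params 2,3,4             # quadrature circular summary
```

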