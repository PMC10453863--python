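# rtentropy

Entropy measures for response-time (RT) distributions, built on the
survivor function.

Psychologists and neuroscientists routinely analyse RT distributions to
infer processing capacity, effort and efficiency, but the classical
differential entropy `-∫ f log f` is unusable for this: it can be
negative, and it cannot be estimated consistently from empirical
distributions. The **cumulative residual entropy (CRE)** solves both
problems by replacing the density with the survivor function
`S(t) = Pr{T > t}`:

```
CRE = -∫ S(t) · log S(t) dt           (always ≥ 0)
```

`rtentropy` implements, for duration data:

- the five canonical RT functions — density `f(t)`, CDF `F(t)`, survivor
  `S(t)`, hazard `h(t) = f/S`, integrated hazard `H(t) = -log S(t)` — for
  the **ex-Gaussian** (Gaussian(μ, σ) ⊛ exponential(τ); mean μ+τ,
  variance σ²+τ²) and **exponential** (rate λ) models;
- the **CRE** with analytic (`CRE = 1/λ` for the exponential), quadrature
  and empirical plug-in estimators (step / linear / natural-spline
  survivor interpolation);
- the **CRE density** `ε′(t) = -S log S` and the **instantaneous CRE**
  `iCRE(t) = -log S(t)` — the information (in bits, nats or bans) gained
  from the stimulus by time `t`, numerically identical to `H(t)`;
- the **information-gain rate**: the OLS slope of `iCRE(t)` against `t`,
  in information units per ms (equal to λ for the exponential and to the
  tail rate `1/τ` for the ex-Gaussian);
- a six-condition **simulation study** comparing these measures across
  parametric manipulations of the RT distribution.

## Worked example

```python
import numpy as np
from rtentropy import ExGaussian, RTEntropy, cre_from_survivor

model = ExGaussian(mu=400, sigma=30, tau=60)       # a typical RT condition
sample = model.rvs(10_000, seed=42)

res = RTEntropy(sample, condition="baseline").fit()
print(res.summary())

exact = cre_from_survivor(model.survivor())        # [0, 2500] ms, 1 ms grid
print(f"\nexact quadrature CRE: {exact.value:.3f} nats x ms")
print(f"exact tail rate 1/tau: {1/60:.6f} nats/ms")
```

prints

```
          RT entropy analysis
==============================================
condition:        baseline
n observations:   10000
log base / unit:  2.71828 (nats)
CRE method:       empirical_step
integration:      [0, 996.234] ms
----------------------------------------------
CRE                    66.8029  nats x ms
iCRE slope            0.016174  nats/ms
  std err             0.000012
  intercept            -6.5124  nats
  fit window      [546.5, 978.8] ms (1000 points)
  residual SS           0.5437
excluded S=0 pts       1
==============================================

exact quadrature CRE: 66.258 nats x ms
exact tail rate 1/tau: 0.016667 nats/ms
```

The plug-in CRE (66.80) estimates the exact survivor-quadrature value
(66.26): the total uncertainty the condition induces, in time-weighted
information units. The iCRE slope (0.0162 nats/ms, fitted over the late,
linear part of the curve) estimates the asymptotic rate at which the
stimulus delivers information — `1/τ = 0.0167` for this model. Shifting
μ leaves both quantities unchanged; raising σ raises the CRE but not the
rate; doubling τ roughly doubles the CRE and halves the rate.

The same analysis runs from the shell:

```sh
rtentropy simulate --model exgauss --mu 400 --sigma 30 --tau 60 \
    --n 10000 --seed 42 --out sample.csv
rtentropy cre sample.csv --base e --method step
rtentropy slope sample.csv
rtentropy study --out study/          # the full six-condition study
```

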