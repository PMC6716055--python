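# levyhrv

Stochastic-dynamics modelling and analysis of heart-rate variability (HRV),
for physiologists and physicists studying the statistics of inter-beat
fluctuations.

Healthy inter-beat increments I(n) = B(n+1) − B(n) follow a symmetric
Lévy-stable law (index α ≈ 1.5–1.7) whose variance is infinite — yet real
hearts are stable.  `levyhrv` implements a control-theoretic resolution:
the increments obey a Langevin equation

    dI = −(λ₀ I + λ₂ₙ I^{2n+1}) dt + dξ(t),    dξ ~ symmetric α-stable,

where the polynomial drift models the collective feedback of the sinoatrial
pacemaker network near criticality.  The associated fractional
Fokker–Planck equation (Riesz–Feller operator, Fourier symbol −|ω|^α) has a
stationary density with inverse-power-law tail

    P_ss(I) ∝ |I|^(−μ),    μ = α + 2n + 1,

so cubic control (n = 1) tempers the free Lévy tail μ = α+1 to μ = α+3 > 3
and restores a finite second moment — a dynamical tempering, distinct from
exponential truncation.  The package provides:

* exact α-stable sampling (Chambers–Mallows–Stuck) and the Fourier-cosine
  stable density, under one characteristic-function convention;
* Euler–Maruyama integration of the controlled dynamics with a stiffness
  guard for heavy-tailed kicks, plus the analytic width law
  σ_α²(t) = σ²(1−e^{−αλ₀t})/(λ₀α);
* the Riesz–Feller operator on a grid (spectral and Grünwald–Letnikov
  routes), stationarity residuals, and tail-exponent estimation
  (truncated-Pareto MLE + bootstrap CI);
* the HRV observable battery: mean RR / SDNN / rMSSD, VLF/LF/HF band powers,
  DFA α₁/α₂, spectral scaling H, and the multiscale non-Gaussianity index
  λ_s of the Castaing log-normal mixture model;
* ground-truth synthetic RR generators (Gaussian, stable, cascade,
  Langevin-driven) and a small CLI.

## Worked example

```python
import numpy as np
from levyhrv import (ControlPolynomial, StableLaw, SimulationConfig,
                     LangevinModel, fit_tail_exponent)

model = LangevinModel(ControlPolynomial(lambda2n=1.0, order_n=1),  # cubic control
                      StableLaw(alpha=1.5))
cfg = SimulationConfig(dt=1e-3, n_steps=20_000 + 25_000 * 50, burn_in=20_000,
                       n_realizations=32, seed=77, record_stride=50)
ens = model.simulate(cfg)
fit = fit_tail_exponent(ens.values, window=(0.999, 0.99995))
print("theory mu =", model.predicted_tail_exponent())
print(fit.summary())
```

prints

```
theory mu = 4.5
IPL tail fit
  mu_hat     : 4.590
  95% CI     : [4.249, 4.981]
  log-log fit: 4.978
  window     : quantiles (0.999, 0.99995)
  tail points: 760
```

The fitted density-tail exponent of the simulated stationary increments
(4.59, CI [4.25, 4.98]) covers the fractional Fokker–Planck prediction
μ = α + 2n + 1 = 4.5; without the cubic term the same pipeline recovers the
free-flight value μ = α + 1 = 2.5.

Analysing an RR recording (plain text, one interval in ms per line):

```
levyhrv generate --kind cascade --lam 0.5 --length 30000 --seed 4 --out rr.txt
levyhrv analyze rr.txt --scales 5,25
```

returns the full metric battery plus the non-Gaussianity profile
(`lambda_25` ≈ 0.5 for this surrogate, ≈ 0 for a Gaussian one).

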