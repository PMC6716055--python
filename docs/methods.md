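# Methods

## The model

Healthy heart rhythm fluctuates heavily: the beat-to-beat increments
I(n) = B(n+1) − B(n) of the RR-interval series B(n) are well described by a
symmetric Lévy-stable law with index α ≈ 1.5–1.7, whose variance is infinite.
Taken literally that implies unbounded growth of ⟨I²⟩ — physiologically
impossible — so some control process must temper the extremes.  The package
implements a candidate mechanism: the collective dynamics of the sinoatrial
pacemaker network, poised near criticality, contributes a polynomial
restoring force, giving the Langevin equation

    dI = −(λ₀ I + λ₂ₙ I^{2n+1}) dt + dξ(t),

with dξ a delta-correlated symmetric α-stable driver representing the
competing autonomic inputs.  Near criticality the linear rate λ₀ → 0 and the
leading even-order feedback gain λ₂ₙ I^{2n} dominates; n = 1 (cubic drift) is
the reduction of a cooperative two-state network at its tipping point.

The probability density of I obeys a fractional Fokker–Planck equation whose
spatial operator is the symmetric Riesz–Feller derivative (Fourier symbol
−|ω|^α) multiplied by a noise strength σ².  Its stationary solution has an
inverse-power-law (IPL) tail

    P_ss(I) ∝ |I|^(−μ),   μ = α + 2n + 1,

so linear control leaves the free-flight tail μ = α + 1 (infinite variance
for α < 2) while any nonlinear control order n ≥ 1 pushes μ above 3 and
restores a finite second moment: the process is "tempered" dynamically, not
by exponential truncation of the noise.  The IPL law is strictly a tail
asymptote — a pure power law is not normalisable at the origin — so full
steady states are only ever represented numerically.

### Conventions

All stable laws use E[exp(iωX)] = exp(−scale^α |ω|^α); α = 2 is Gaussian with
variance 2·scale², α = 1 Cauchy with half-width `scale`.  The Fokker–Planck
noise strength σ² equals scale^α of the driver per unit time, which makes the
width formula σ_α²(t) = σ²(1 − e^{−αλ₀t})/(λ₀α) (free limit σ²t, stationary
limit σ²/(λ₀α)) consistent with the sampling rule below.  Only symmetric
(skewness-zero) laws are supported; asymmetric and exponentially tempered
stable laws are out of scope.  Time units are arbitrary; RR intervals are
milliseconds.

## Numerics

**Stable sampling** is the Chambers–Mallows–Stuck transform (exact for all
α ∈ (0,2]).  The density is evaluated by the Fourier-cosine integral with an
oscillatory-weight quadrature, cutting the frequency domain where the
characteristic function falls below 10⁻¹².

**Stochastic integration** is explicit Euler–Maruyama with noise increment
scale·dt^{1/α}·ζ per step (forced by self-similarity of the stable process).
A stiffness guard handles the rare huge kicks that land far up the polynomial
potential, where a full explicit step would overshoot: whenever
|drift|·dt > 0.5|I| + 0.5, the deterministic relaxation over that step is
sub-cycled with Euler sub-steps bounded by a fifth of the local relaxation
time 1/(λ₀ + (2n+1)λ₂ₙ I^{2n}).

**Sampling-artifact control.**  A discrete chain recorded every dt
over-weights excursions whose deterministic relaxation time is below dt, so
for the cubic-control runs the sample histogram beyond
|I| ≈ sqrt(1/(λ₂ₙ·dt)) follows the raw jump law |I|^{−(α+1)} instead of the
stationary μ = α+3 tail.  The cubic-control study conditions therefore use
dt = 10⁻³ (artifact boundary ≈ 32, far beyond the fit window) with recording
every 50 steps.  The linearly controlled chain is an AR(1) with stable
innovations whose marginal stationary law is *exactly* stable at any dt, so
those runs keep dt = 10⁻² and record every half relaxation time (stride
0.5/(λ₀·dt)) for near-independent samples.

**Tail-exponent estimation** uses the maximum-likelihood index of a Pareto
law truncated at the fit window's upper edge (density exponent μ =
exceedance index + 1), cross-checked by log-log regression on log-spaced
histogram bins, with a percentile bootstrap for the 95% CI.  When the input
is an ensemble matrix, the bootstrap resamples whole realizations, which
keeps the CI honest under the serial dependence of recorded trajectories.
The generic default window is quantiles (0.995, 0.9999) of |samples| — past
the stable core, before bootstrap starvation, and exact on pure Pareto
input.  The tail-law experiments use the deeper (0.999, 0.99995) window:
on *exact* α = 1.5 stable samples the local density log-slope at the 99.5th
percentile of |X| is still −2.56 (asymptote −2.5), and the cubic-control
crossover approaches its asymptote from the steep side, so shallower windows
carry a visible pre-asymptotic bias in both cases.  These windows were fixed
from the exact-density diagnostics, not tuned on simulation outcomes.

**Riesz–Feller operator.**  Two independent routes: multiplication of the
DFT by −|ω|^α, and fractional centred differences (a Grünwald–Letnikov-type
discretisation of the singular integral, second-order accurate).  They agree
to 10⁻³ relative L² on Gaussian test functions on a [−80, 80] grid of 2¹²
points for α ≳ 1.2; for α < 1 the operator output decays as |x|^{−(1+α)} and
the two boundary treatments (periodic wrap vs truncation) diverge at the
few-percent level on any practical domain.  α = 2 delegates to the plain
second derivative.  The operator is kept pure; σ² is applied at the equation
level.

**Stationarity residual.**  The residual of
∂_I[(λ₀I + λ₂ₙI^{2n+1})P] + σ²D^α P = 0 is evaluated pointwise and
normalised by the sum of the two terms' magnitudes at log-spaced tail
abscissae.  A raw L² norm is dominated by the crossover region and does not
separate tail exponents; the relative form discriminates the true exponent
from ±1 alternatives by an order of magnitude.  Candidates share a smooth
core and carry power tails matched to the simulated histogram by log-space
least squares.  An exact benchmark anchors the machinery: for α = 1 (Cauchy
noise) and pure cubic drift the stationary density is known in closed form,
P(I) = 1/(πc(1 − y² + y⁴)), y = I/c, c = (σ²/λ₂)^{1/3}, and zeroes the
discrete operator to ~10⁻⁵ relative.

## The observable battery

* **Time domain:** mean RR, SDNN (sample SD), rMSSD (RMS of successive
  differences), all ms.
* **Frequency domain:** the tachogram is cubic-spline resampled at 4 Hz and
  Welch-averaged (Hann, 256-s segments, 50% overlap); band powers are PSD
  integrals over VLF 0.003–0.04, LF 0.04–0.15, HF 0.15–0.4 Hz, in ms².
  At least 5 min of data are required.
* **DFA:** first-order detrended fluctuation analysis on the integrated,
  mean-centred series; α₁ over 4–16 beats, α₂ over 16–64 beats.  F(s) is
  divided by the exact white-noise expectation shape (computable from the
  residual-projector trace), the "modified DFA" correction — without it,
  white noise reads ≈ 0.58 over beats 4–16.  Small-scale estimates of
  strongly correlated signals remain genuinely compressed (a random walk
  reads ≈ 1.4 on α₁ and 1.5 on α₂).
* **Spectral scaling:** H = (β+1)/2 from the log-log slope −β of the
  increment spectrum over 0.004–0.05 cycles/beat.
* **Non-Gaussianity:** increments at beat scale s are computed on the
  locally detrended interval series (polynomial of degree ≤ 3 in
  non-overlapping windows of 2s beats; the degree is capped for narrow
  windows down to mean removal at width 2).  Local detrending makes the
  residual variance position-dependent within a window — which a
  variance-mixture index would misread as non-Gaussianity (λ ≈ 0.09 on pure
  Gaussian input) — so increments are standardized per within-window
  position before pooling.  The index λ is the width of the Castaing
  log-normal variance superposition, estimated from the moment identity
  λ̂² = ln⟨x²⟩ − 2ln⟨|x|⟩ − ln(π/2), clipped at zero; on zero-λ input the
  clipped estimator scatters as n^{−1/4}.  λ₂₅ (scale 25 beats) is the
  conventional summary; scale is counted in beats throughout.

## Synthetic data

The generators emulate the statistical structure of real RR recordings, not
their physiology: no respiratory modulation, no circadian trend, no ectopy.
Targets default to mean 800 ms and SD 100 ms.  Increments (Gaussian, stable,
cascade, or a per-beat-sampled Langevin trajectory) are cumulated from
B(0) = mean, the cumulated series rescaled to the target SD, and positivity
enforced by reflection at a 200 ms floor; the reflected fraction is recorded
and a spec whose output exceeds 5% reflection is rejected (at the defaults
it is below 0.1%).  Note the interval series is then a random-walk-type
signal (DFA ≈ 1.5), which is the model's own picture of B(n); analyses of
*increments* see the intended law.

The cascade generator draws x = σz with ln σ ~ N(0, λ²), exactly the
Castaing mixture per point.  With `block_len > 1` (default 256 in the RR
surrogate) σ is held constant over blocks: iid mixture draws lose their
non-Gaussianity under coarse-graining by the central limit theorem, while
block volatility keeps λ_s flat up to the block length — the feature the
multiscale analysis is meant to detect.  The effective sample size for λ
recovery is then the number of blocks.

Every generator is deterministic per seed (one root seed, child streams
spawned per operation) and records its ground truth in the output metadata.

## Study conditions and problem sizes

The tail-law experiments pool ≥ 8×10⁵ recorded stationary samples over 64
(linear) or 32 (cubic) realizations; the α-grid recovery study runs the
cubic combinations at 0.35× pooled size and the linear ones with λ₀ = 0.5
(faster mixing; the tail law is independent of λ₀).  Because a study
checking six simultaneous 95% CIs has only ~74% joint single-shot coverage,
the recovery tests allow one independent-seed retry per configuration; two
consecutive misses mark a failure.

## Known limitations

* The IPL tail is asymptotic: at feasible sample sizes the fitted exponent
  of the cubic-control runs sits ~0.1–0.2 above α+3 because the crossover
  region decays faster than the asymptote; the bootstrap CI absorbs this.
* The non-Gaussianity index and the cascade generator adopt one specific
  (log-normal, scale-in-beats) reading of the Castaing framework; both are
  isolated behind the module API.
* Band powers and DFA values on synthetic surrogates are self-consistency
  checks, not clinical reference ranges; no artifact/ectopy editing is
  applied (a pre-filter hook exists and ships as identity).
* The cooperative network model whose reduction motivates the cubic drift
  is not implemented; only its near-criticality Langevin form is.
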