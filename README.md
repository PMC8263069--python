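# burstdyn

Tools for characterising transient oscillatory **bursts** in neural time
series — in particular beta-band (13–35 Hz) activity in local field
potentials — and for relating burst statistics to the *dynamics* of the
system generating them.

Neural beta activity is phasic: the band-limited amplitude envelope crosses
any given threshold in episodes ("bursts"), and burst duration carries
clinically relevant information (e.g. in Parkinson's disease, longer
subthalamic beta bursts track motor impairment). Instead of committing to
one arbitrary threshold, `burstdyn` works with the **average burst duration
profile**: the mean duration of supra-threshold episodes as a function of
the envelope-percentile threshold (20th–95th percentile in 5% steps by
convention, with a 100 ms minimum duration for data analysis).

Around this central feature the package provides:

- **Feature extraction** — band-pass filtering around the beta peak,
  Hilbert envelopes, burst detection, duration/amplitude/rate profiles,
  envelope PDFs, Welch spectra (`burstdyn.features`).
- **Linear surrogates** — FT, IAAFT and gradual wavelet reconstruction
  (GWR) surrogates that preserve the spectrum (and value distribution)
  while destroying non-linear structure, plus the **BDDLS** statistic
  ("burst duration distance to linear surrogate"):

  BDDLS = Σ_L (τ̃_data(L) − τ̃_surr(L))² / (mean_L τ̃_surr(L))²,

  with its ON/OFF contrasts and the supporting statistics (adaptive FDR,
  cluster permutation tests, rank tests, Barnard's exact test)
  (`burstdyn.surrogates`, `burstdyn.nonlin_stats`).
- **Envelope models** — time discretizations of dx = μ(x)dt + ζ dW with
  polynomial drift μ; the Ornstein–Uhlenbeck (OU) model μ = −θx is the
  linear special case (`burstdyn.envelope_models`).
- **Analytic burst durations** — to first order in the time step dt the
  average burst duration of the discretized model at threshold L is

  τ̃_L ≈ √(2π dt)/ζ · ∫_L^∞ exp[(2/ζ²)(Λ(x) − Λ(L))] dx,   Λ' = μ,

  which for the OU model reduces to the closed form
  τ̃_L ≈ π √(dt/2θ) · exp(θL²/ζ²) · erfc(√θ L/ζ), and, with thresholds as
  percentile ranks, to a ζ-free expression. The discretization corrections
  (mean boundary step Γ̄, mean overshoot Δ̄, and the derivative correction
  A₀ = (π−4)/(π+4) ≈ −0.12) are exposed and empirically calibratable
  (`burstdyn.analytic_mfpt`).
- **The passage method** — inversion of the relation above: the drift
  function is recovered from a measured burst duration profile via
  μ(L) ≈ −[ζ√(π dt/2) + (ζ²/2) ∂τ̃_L/∂L] / τ̃_L, with a direct
  (bin-averaged first differences) comparator (`burstdyn.passage`).
- **Neural mass model** — a stochastic two-population Wilson–Cowan model of
  the STN–GPe loop, linear or with delayed sigmoid activation
  (`burstdyn.neural_mass`).
- **Fitting** — random starts refined by generalized pattern search
  ("positive basis 2N"), variance-normalized feature costs, and minimal
  envelope-model selection (lowest polynomial degree reaching R² > 0.95,
  with BIC reporting) (`burstdyn.fitting`).
- **Synthetic data** — ARMA and pink-noise linear controls and every model
  class above, as pure functions of (parameters, seed)
  (`burstdyn.synthetic`).

## Worked example

Simulate a discretized OU envelope (θ = 1 s⁻¹, ζ = 1, dt = 1 ms, 2000 s),
measure its burst duration profile, compare with the closed form, and
recover the drift with the passage method:

```python
import numpy as np
from burstdyn import (simulate_ou, burst_profiles, infer_drift_passage,
                      ou_burst_duration_percentile, DEFAULT_PERCENTILES)

env = simulate_ou(theta=1.0, zeta=1.0, dt=1e-3, duration=2000.0, seed=1)
prof = burst_profiles(env, DEFAULT_PERCENTILES, min_duration=0.0)
pred = ou_burst_duration_percentile(1.0, 1e-3, DEFAULT_PERCENTILES)

est = infer_drift_passage(env, zeta=1.0, dt=1e-3)
lo, hi = np.quantile(env.values, [0.2, 0.8])
m = (est.x_grid >= lo) & (est.x_grid <= hi) & np.isfinite(est.mu_hat)
slope = np.polyfit(est.x_grid[m], est.mu_hat[m], 1)[0]
```

This prints (formatted):

```
percentile 0.20: simulated  157.7 ms   analytic  160.2 ms
percentile 0.45: simulated   82.7 ms   analytic   77.9 ms
percentile 0.70: simulated   47.8 ms   analytic   48.4 ms
percentile 0.95: simulated   27.8 ms   analytic   27.2 ms
recovered drift slope: -1.143  (true decay parameter: -1.0)
```

Bursts shorten as the threshold rises, the measured profile tracks the
first-order analytic result within a few percent, and the passage method
recovers the linear drift μ(x) = −θ(x − x̄) to within ~15% from a single
recording — the envelope dynamics are readable off the burst duration
profile.

A command-line interface mirrors the library (`burstdyn --help`):
`filter`, `envelope`, `profile`, `surrogate`, `bddls`, `analytic`,
`simulate envelope|wc`, `fit envelope|wc`, `passage`, `compare-methods`,
`fixtures`.

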