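# Methods

This note records the models implemented in `burstdyn`, their assumptions,
the numerical choices behind them, and what the synthetic-data tests do and
do not establish about real recordings.

## Signals, envelopes, and burst profiles

A recording is a uniformly sampled single channel. For beta-band analysis
the signal is band-pass filtered ±3 Hz around the spectral peak found in
the 13–35 Hz range (for ON/OFF medication pairs, the peak of the OFF
recording is used for both, so the two conditions see the same band). The
filter is a 4th-order Butterworth applied forward and backward (zero
phase); the band is the scientifically specified quantity, the filter
family is an implementation choice. Filtered signals are z-scored
individually so amplitude differences between conditions do not masquerade
as differences in temporal patterning.

The envelope is the modulus of the analytic signal (discrete Hilbert
transform), smoothed by a centered moving average of 5 ms (about a tenth of
a beta cycle), reflected at the edges. Bursts at threshold L are maximal
runs of samples with envelope strictly above L (ties count as below); for
data analysis a burst must last at least 100 ms, while all analytic
formulas model no minimum duration, so every comparison against a formula
uses `min_duration=0`. Runs touching either end of the recording are kept;
they bias durations downward by at most one truncated burst per edge, which
is negligible at the durations used here.

The average burst duration profile evaluates the burst-duration mean (with
SEM, amplitude mean, and rate) at thresholds set to the 20th–95th empirical
percentiles of the envelope in 5% steps (linear interpolation between order
statistics). Thresholds with no qualifying burst are marked missing (NaN),
never zero. With no minimum duration the identity
`rate(L) · τ̃(L) = fraction of samples above L` holds exactly per
realization, which is why the rate profile is treated as derived rather
than as an independent feature. For segment statistics a recording is split
into five equal parts (remainder dropped) and features are computed per
segment; the spectral estimator is Welch with 1 s Hann windows and 50%
overlap (the estimator choice is not critical for any result here and is
configurable).

## Linear surrogates and BDDLS

FT surrogates randomize Fourier phases while keeping amplitudes; IAAFT
surrogates additionally match the value multiset exactly by iterating
amplitude adjustment and rank remapping (convergence when the relative
spectral mismatch changes by < 1e-6 between iterations, or 100 iterations;
the final step is always the rank remap, so the multiset match is exact by
construction). GWR surrogates interpolate between IAAFT (ρ = 0) and the
data (ρ = 1): an undecimated, energy-normalized stationary wavelet
transform (8-tap least-asymmetric Daubechies, depth ⌊log₂N⌋ − 2 capped at
10; the signal is reflect-padded to a multiple of 2^depth and trimmed after
inversion) is taken, squared coefficients are ranked largest-first across
all scales and positions and fixed until their cumulative energy reaches
ρ·total, free coefficients are IAAFT-randomized within each scale, the
transform is inverted, and a final global IAAFT pass (seeded from the
candidate, not from a fresh shuffle) restores the exact value multiset and
the spectrum. Seeding the global pass from the candidate makes ρ = 1 an
exact fixed point returning the data bit-for-bit. The exact per-scale
versus global alternation schedule of the original GWR algorithm is not
fully pinned down in the literature we follow; one per-scale pass followed
by one global pass is used, and the ρ-continuity property (mean |surrogate −
data| non-increasing in ρ) is verified by test.

BDDLS compares a data profile with the across-realization mean profile of
(by convention 19) surrogates: the sum of squared profile differences
divided by the squared mean of the surrogate profile. The scaling makes the
measure invariant to a common amplitude factor, so larger overall burst
durations do not inflate it. Significance is assessed by a surrogate rank
test: the data statistic is ranked among each surrogate's leave-one-out
statistic, giving p = (1 + #{surrogate ≥ data})/(n + 1), with a floor of
0.05 at n = 19. On linear controls (beta-band AR(2), pink noise) the
rejection rate at the 5% level is ~5% by test.

Supporting statistics: the adaptive FDR procedure is the two-stage linear
step-up (the better-calibrated m₀ estimator among the common adaptive
choices; the non-adaptive step-up is available behind `method="bh"`), via
statsmodels, with a hand-stepped oracle in the tests. The cluster
permutation test forms clusters of contiguous histogram bins whose paired
t statistics exceed the two-sided p < 0.05 critical value, scores them by
summed |t|, and builds the null from sign flips (exhaustive when 2^n fits
the permutation budget). Barnard's unconditional exact test uses the pooled
Wald statistic with the nuisance success probability maximized over a grid
(scipy's implementation), one-sided by default — this variant reproduces
the worked-example p = 0.0551 for the 10/16-vs-5/16 table. PSDdiff is
operationalized as the relative difference of band-integrated power, with a
per-frequency variant behind a flag.

## Envelope models and discrete burst durations

Envelope models are time discretizations of dx = μ(x)dt + ζ dW with
polynomial drift μ(x) = Σ dᵢxⁱ, d_deg < 0 (integrability) and constant
noise. The OU model (μ = −θx) is simulated with the exact updating
equation (an AR(1) recursion, evaluated as an IIR filter), started from a
stationary draw; positivity is restored afterwards by shifting the
trajectory up by |0.1th percentile| and flooring at zero, which leaves
percentile-ranked thresholds (and hence burst profiles) untouched. Higher
degrees use Euler–Maruyama with the absolute value of each new point
retained (reflection at 0, negligible at the thresholds analysed), default
step 1 ms, initial state at the largest attracting drift root, 10 s
burn-in, and a divergence guard at |x| > 10⁶.

For the discretized model the average burst duration at threshold L is a
mean first passage time problem with three discreteness corrections:
trajectories starting on the boundary take extra time (mean step above the
boundary Γ̄ = ζ√(2dt/π)), the MFPT derivative at the boundary is reduced by
a factor (1 + A₀), and bursts start from the overshoot distribution (mean
overshoot Δ̄ = (ζ/2)√(π dt/2)). A first-step analysis gives
A₀ ≈ 1/π − 1/2 ≈ −0.18; calibrating A₀ against simulated OU profiles gives
(π−4)/(π+4) ≈ −0.12, the value used throughout (the `calibrate_a0` harness
reruns this calibration: θ ∈ {0.5, 1, 2}, ζ = 1, dt = 1 ms, ≥ 3·10⁴ s per
θ, percentiles 20–95, grid step 0.0025; the objective is linear in 1 + A₀,
so the grid argmin is effectively a least-squares scale fit). Combining the
three corrections, to first order in dt,

τ̃_L ≈ √(2π dt)/ζ · ∫_L^∞ exp[(2/ζ²)(Λ(x) − Λ(L))] dx,

with Λ the drift antiderivative. Consistency anchor: (Γ̄ + Δ̄)(1 + A₀)
equals ζ√(π dt/2) exactly, which is the prefactor that multiplies
T(L) = (2/ζ²)∫…. Special cases: the OU closed form
π√(dt/2θ)·exp(θL²/ζ²)·erfc(√θL/ζ) (evaluated via erfcx for numerical
stability at high thresholds), its percentile form
π√(2dt/θ)·(1−L%)·exp(erf⁻¹(2L%−1)²) in which the noise cancels, and the
Rayleigh drift −θx + ζ²/2x for which the integral collapses to
√(2π dt)·ζ/(2θL). An independent oracle validates the OU result: for a
stationary Gaussian AR(1) sequence the mean supra-threshold run length is
exactly dt·P(x > L)/P(x_t ≤ L, x_{t+1} > L) with the joint probability
given by the bivariate normal orthant; the closed form agrees with this
exact expression to O(dt). Quadratures use adaptive integration with an
x = L + tan(u) substitution for the infinite limit (absolute tolerance
1e-10 s); the general continuous-time MFPT double integral is also provided
and checked against a tridiagonal Markov-chain first-passage solve.

## The passage method

Provided τ̃ and its threshold derivative are measurable and ∂τ̃/∂L ≠ 0 is
not required (only τ̃ > 0), the relation above inverts locally:

μ(L) ≈ −[ζ√(π dt/2) + (ζ²/2) ∂τ̃_L/∂L] / τ̃_L.

(The bracket carries an overall minus sign; with the typically negative
profile derivative the two terms oppose each other, and for the OU model
they cancel exactly at the stationary mean, giving μ = 0 there.)
Operationally: 300 thresholds equally spaced from max/50 to 0.9·max of the
envelope; τ̃ at each threshold with no minimum duration; LOWESS smoothing
(local linear, statsmodels) of τ̃ with a span of the threshold range over
eight; central-difference derivative (one-sided at edges) smoothed with a
span of the range over five; then the formula. An `edge_unsmoothed`
fraction can exempt the fast-decaying left edge from smoothing (useful on
empirical data; default 0). SEM comes from repeating the inference on four
contiguous segments with the noise parameter fixed. Thresholds without
bursts stay missing and are excluded from the smoothing fits. For empirical
envelopes the method's dt is the envelope's time scale of variation
(roughly one oscillation cycle, 0.05 s for beta) rather than the sampling
step; for synthetic envelopes it is the generator step.

When ζ is unknown it is selected from a candidate grid by forward
validation: infer the drift at each candidate, simulate the inferred
dynamics (clamped linear interpolation of the tabulated drift,
Euler–Maruyama, absolute-value positivity; by default five repeats of ten
times the data duration), and score the mismatch of the burst duration
profile and the envelope inverse CDF against the data; both criteria are
variance-normalized SSEs and either can be disabled for diagnostics.

The direct comparator estimates μ by bin-averaging first differences
(x_{i+1} − x_i)/dt in 300 equal-width bins of x_i. In the method
comparison (no smoothing on either side, per-method native grids, SSE
against the true drift over valid grid points) the passage method's error
is consistently smaller on the fifth-degree benchmark — the extreme bins
of the direct method carry few samples and very noisy means.

## Wilson–Cowan model

The STN–GPe loop is modelled as a stochastic two-population Wilson–Cowan
system: excitatory E (STN; stands in for the recorded LFP) and inhibitory I
(GPe) with weights w_EI, w_IE, self-inhibition w_II, constant inputs λ_E,
λ_I, time constants Ω_E, Ω_I, independent white noise of SD ζ on each
population, and either a linear activation βx (with zero delays; λs set to
zero since they only shape transients in the linear model) or a delayed
sigmoid η/(1 + e^{−β(x−1)}) with per-connection delays. Integration is
Euler–Maruyama with ring-buffer delayed state, delays rounded to integer
multiples of dt, history held constant before t = 0, 10 s burn-in, and an
instability guard. A single code path handles all delay values, so zero
delay is trivially bit-identical to the non-delayed model. For the linear
variant the drift matrix eigenvalues predict the spectral peak (Im λ/2π)
in the lightly damped regime, and the Euler one-step map I + A·dt predicts
boundedness of the simulation — both are exercised as oracles in the tests.
Model features (PSD and burst profile of E, envelope = |analytic signal|)
are averaged over repeats (five repeats of 1000 s at paper scale; tests use
shorter repeats).

## Fitting

The cost is the variance-normalized squared error averaged over features
(profile only for envelope models; PSD + profile for Wilson–Cowan), and
R² = 1 − cost. Optimization is generalized pattern search with the
positive-basis-2N poll, complete polling (all 2N directions evaluated, best
taken), mesh doubling on success and halving on failure, stop at mesh
< 1e-5 or 600 calls (defaults), coordinates scaled by their bound widths.

Two choices proved decisive for envelope-model fitting and are this
package's own design:

1. **Canonical units.** Burst duration profiles on percentile-ranked
   thresholds are invariant under the amplitude rescaling
   (dᵢ, ζ) → (k^{1−i}dᵢ, kζ), so the noise SD is fixed to 1 during the
   search and the scale k (plus, for degree 1, an offset absorbing the OU
   positivity shift) is recovered afterwards by matching the model's
   percentile thresholds to the target's. This removes a flat/degenerate
   search direction.
2. **Order-scaled bounds.** The profile's sensitivity to dᵢ grows roughly
   like (amplitude range)^i, so coefficient bounds shrink geometrically
   with order (±8·3⁻ⁱ by default). With uniform bounds the
   coordinate-aligned pattern search stalls in a curved valley; with
   scaled bounds 40 random starts reliably reach the global basin on the
   benchmark targets.

The default envelope objective is the first-order analytic profile
(deterministic, ~0.1 ms per evaluation; models no minimum burst duration);
a simulation objective with common random numbers (fixed per-candidate
seeds, which makes the stochastic objective a well-defined deterministic
function) is available and is the default for Wilson–Cowan fits, where no
analytic profile exists. Wilson–Cowan starts are rejection-filtered to
have a PSD peak within 1 Hz and 30% magnitude of the target's; for the
linear variant candidates are pre-screened by the eigenvalue frequency
(cheap) and their noise SD is rescaled analytically onto the target's
magnitude scale (output amplitude is proportional to ζ), without which the
joint frequency-and-magnitude acceptance rate is impractically small.
Envelope fits whose stationary density has R² < 0 against a supplied
envelope histogram are rejected.

Minimal-model selection fits degrees 1, 2, … until the profile R² exceeds
0.95, reporting the Gaussian-residual BIC = n·ln(RSS/n) + k·ln(n) (k =
coefficients + noise SD, n = 16 thresholds) for every degree tried; zero
RSS maps to a large negative sentinel. On simulated OU targets degree 1 is
selected with θ recovered within a few percent; on the cubic shoulder
benchmark degree 3 is selected with BIC clearly below the linear model's.

## Synthetic data: what it does and does not show

Generators (all pure functions of parameters and seed): ARMA processes
(the beta-band AR(2) with poles at radius 0.97 and 20 Hz mimics filtered
linear noise), 1/f pink noise (spectral shaping, optional band-pass), OU /
polynomial / Rayleigh-equivalent envelopes, and both Wilson–Cowan variants.
The cubic benchmark drift −0.4(x−0.6)((x−1.9)² + 0.05) with ζ = 0.5 is
monostable with a pronounced high-amplitude shoulder — the drift almost
vanishes near x ≈ 1.9, producing the non-monotone burst duration profile
that distinguishes non-linear from linear envelope dynamics; the
fifth-degree benchmark ([1, −2.2, 1.35, −0.3, 0.02, −0.002], ζ = 0.8) has
the same character. These fixtures emulate band-limited stochastic
oscillations with known ground truth; they do not emulate nonstationarity,
recording artifacts, line noise, volume conduction, or the short (~250 s)
and noisy character of clinical recordings. Passing tests therefore
establish correctness of the algorithms and calibration of the formulas
under the models' assumptions (constant additive noise, no delays in the
envelope description), not clinical validity.

Problem sizes in the validation suite are desk-scale choices: formula
comparisons use five repeats of 10⁴ s, the A₀ calibration 3·10⁴ s per
decay value, drift recovery 1000 s, model selection 6000 s targets over 20
seeds, and the type-I study 200 replicates of ~4 s AR(2) segments. Where a
protocol is stochastic the seeds are fixed; sampling variability at these
sizes is the dominant error term in the looser tolerances (e.g. the 15%
slope tolerance for single-realization drift recovery).

## Known limitations

- The burst-duration formulas are first order in dt; at dt = 1 ms and
  θ ≤ 2 s⁻¹ the residual bias is well under 1%, but it grows linearly in
  dt (verified by the √dt-scaling and convergence tests).
- The passage method degenerates where τ̃ is unmeasurable (no bursts) and
  is noisy near the top of the threshold grid, where few bursts exist; the
  slope of recovered drifts from single 1000 s recordings scatters by
  ~10%.
- The envelope description cannot express delays or state-dependent noise;
  the Wilson–Cowan model covers delays but is fitted at much higher cost.
- GWR surrogates inherit a mild conditional bias: surrogate ensembles are
  conditioned on the data's empirical spectrum, so a single data
  realization is not perfectly exchangeable with them at every threshold;
  the rank test (not per-threshold z-scores) is the calibrated inference.
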