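# Methods

## Scope and data model

The unit of analysis is a *kinetic trace*: one well's BRET ratio
(530/470 nm, dimensionless) sampled on a fixed grid, with labels for the
independent experiment, the well and the treatment condition, and a
stimulation time separating baseline from response. Traces are grouped into
an experiment set (several conditions × independent experiments ×
replicate wells on a shared time grid). All entropy metrics are computed by
default on the **post-stimulation segment** (t ≥ stimulation time), because
the scientific contrasts concern ligand-response dynamics; a single config
switch (`segment`) selects the full trace or the baseline instead, and it
governs SampEn and the Rényi spectrum together so the two measures always
see the same data.

## Sample Entropy

SampEn(m, r, N) = −ln((A/B) · N/(N−2)), where B and A are the numbers of
unordered template pairs matching within tolerance r (Chebyshev distance,
self-matches excluded) at template lengths m and m+1.

Numerical conventions:

- **Templates.** Length-k templates are taken at starting indices
  0 … N−k−1, i.e. N−k templates per length — the convention of the common
  reference implementations, under which a constant series of length 10
  with m=1 gives exactly B = C(9,2) = 36 and A = C(8,2) = 28. The truncated
  last template makes SampEn only *approximately* invariant under time
  reversal (boundary effect of order 1/N); the affine-invariance property
  (r tracks the SD) is exact.
- **Tolerance.** r = `r_factor` × sample SD (ddof = 1), default
  `r_factor` = 0.2. A zero-variance series is rejected as degenerate
  (r would collapse to zero and every comparison becomes a tie).
- **Defaults.** m = 1: the traces are short (~60–70 points per segment),
  and m = 1 maximizes template pairs at some cost in pattern sensitivity.
- **Correction.** The N/(N−2) factor is applied *inside* the logarithm,
  behind a default-on flag (`apply_small_sample_correction`); switching it
  off recovers the textbook −ln(A/B), which the oracle tests use.
- **Undefined values.** If no (m+1)-length pair matches (A = 0), SampEn is
  undefined; the function returns NaN with a `RuntimeWarning` rather than
  +∞, and the pipeline logs and skips such traces so means are never
  contaminated by silent infinities.

Counting is vectorized (O(N²) distance matrix; N ≈ 70 here, so neighbor
trees would be overkill); tests verify exact equality of (B, A) with a
plain double-loop implementation.

## Probability estimation and the Rényi spectrum

The value distribution of a segment is estimated by a Gaussian KDE with the
robust Silverman bandwidth h = 0.9·min(s, IQR/1.34)·N^(−1/5) (falling back
to s when the IQR is 0), evaluated at `n_support` evenly spaced points and
normalized to sum to one. Defaults:

- `n_support` = the segment length N, and support = [min, max] of the data.
  This keeps the Hartley normalizer H₀ = ln N identical across equal-length
  traces and avoids the vanishing tail probabilities an extended support
  would create, which negative orders amplify into numerical explosions.
  An `extended` mode (±3h) exists for sensitivity analysis.
- All probabilities are strictly positive (Gaussian kernel), so negative
  orders are well defined; for user-supplied distributions a zero mass
  with α < 0 raises an explicit divergence error, and the Hartley order
  counts states above a configurable `p_threshold` (default 0).

H_α = ln(Σ pᵢ^α)/(1−α) with the limits H₁ (Shannon), H₀ (Hartley) and H_∞
(min-entropy). The sum is evaluated as a log-sum-exp of α·ln pᵢ, so orders
down to −10 remain finite-precision even when the smallest KDE mass is
~10⁻³⁰. Everything is in nats internally; the reported normalized spectrum
H_α/H₀ is base-free (the base cancels), which a test asserts to 10⁻¹².
The classical monotonicity of H_α in α is asserted to 10⁻⁹ on every tested
distribution.

Normalization caveat: H₀ bounds H_α only for α ≥ 0; negative orders can and
do exceed 1 after normalization (they weight the rarest states), which is
exactly why they discriminate burst-like dynamics.

Temporal coarse-graining (non-overlapping means of τ samples) is
implemented as the optional multiscale stage but defaults to τ = 1: with
~60 post-stimulation samples, τ ≥ 3 leaves too few points for stable KDE
and template statistics, and the α sweep already provides the scale axis of
interest.

## Paired statistics

- Pairing unit: the **independent experiment**. Replicate wells within a
  plate share reagents and timing and are not independent, so well values
  are averaged per experiment before pairing. Relatedly, entropies are
  computed per well and then averaged (the default, which keeps the
  replicate variance structure); the `average_wells` switch instead
  averages replicate wells into one mean trace per experiment before any
  entropy is computed.
- t = d̄/(s_d/√n), two-tailed p from the t distribution with n−1 df.
  Identical pairs (s_d = 0) raise a degenerate-comparison error instead of
  producing ±∞.
- Percentile bootstrap CI of the mean difference: n_boot = 1000 resamples
  with replacement, 2.5/97.5 percentiles, deterministic under a fixed seed.
  Known limitation: at small n the percentile interval undercovers (for
  n = 20 normal differences the true coverage is ≈ 91–93%, not 95%; it
  approaches nominal as n grows). BCa was deliberately not used; the
  percentile interval is the simplest method consistent with resampling
  the paired differences, and the package reports it as such.
- No multiple-testing correction by default — the condition contrasts are
  few and predefined; a Holm adjustment (`holm_adjust`) is available.
- Summary tables report mean ± SEM per condition, with wells averaged
  within experiment before the cross-experiment SEM; single-experiment
  groups report SEM as missing.

## Synthetic data generator

The generator emulates the protocol of a real-time BRET experiment: 30 s
sampling, 300 s baseline, 2100 s total (71 samples), ligand addition at the
end of the baseline, and a mono-exponential association
B₀ + A·(1 − e^(−k(t−t_stim))) afterwards. Per-condition noise families:

- `gaussian_iid(σ)` — white measurement noise (control family);
- `ar1(σ, φ)` — stationary AR(1) with lag-1 coefficient φ and stationary
  SD σ, initialized from the stationary law; at φ = 0 it reproduces the
  white-noise draws *exactly* under the same seed (the tests rely on this
  draw-order contract);
- `burst_renewal` — a renewal process of signaling bursts whose waiting
  times are Pareto(scale, tail) distributed; each event adds an
  exponentially decaying transient (height `burst_amplitude`, rate
  `burst_decay`), starting at stimulation, on top of white noise σ. For
  tail ≤ 1 the theoretical mean waiting time diverges; each waiting time is
  truncated at the recording duration so simulation always terminates.
  This family is the model of modulator-induced bursty, heavy-tailed
  signaling dynamics; the renewal structure is what makes the traces
  non-ergodic in the long-waiting-time regime.

Per-trace seeds derive from the config seed as
`numpy.random.SeedSequence(seed, spawn_key=(experiment, condition, well))`,
which numpy documents as stable, so an experiment set is bit-reproducible.

Two experiment designs ship as YAML configs (parameters live in config, not
code, because they are calibration choices rather than measured constants):

**Four-condition signaling design** (`default_simulation_config`): vehicle
(flat, σ = 0.004), AngII (A = 0.05, k = 0.004 s⁻¹, σ = 0.004), LVV-H7
(flat, bursts: tail 1.5, scale 60 s, height 0.02, decay 0.02 s⁻¹, plus
σ = 0.006), AngII+LVV-H7 (A = 0.09, k = 0.008 s⁻¹, σ = 0.002); 3
experiments × 3 wells. These amplitudes sit at a few percent of the
baseline ratio and noise at a few tenths of a percent — the scale of
typical BRET ratio kinetics — and are calibrated so the *qualitative*
entropy ordering of an allosteric-modulation experiment emerges: the
stabilized combined response is most regular (lowest SampEn), the
modulator-alone burst condition least.

**Binding-pair design** (`binding_pair_config`): AngII alone (slow
association, k = 0.001 s⁻¹, A = 0.05, with burst fluctuations) vs
AngII+LVV-H7 (k = 0.0015 s⁻¹, A = 0.06, reduced noise σ = 0.002); 4
experiments × 2 wells. The slow ramp matters: with a fast rise the few
transient samples become the *rarest* values in an otherwise
plateau-concentrated distribution, and the negative-order entropies are
then dominated by that deterministic transient rather than by the noise
structure (reducing σ even *raises* H₋₅, because the Silverman bandwidth
collapses on the plateau cluster and sharpens the density). A ramp that
spans the recording window gives a near-uniform dwell-time density, so the
rare-state tail reflects the stochastic bursts — which is the effect the
design is meant to expose: lower SampEn *and* lower normalized H₋₅ when
the modulator stabilizes the signal.

### What the generator does not emulate

Photophysical artifacts (donor decay, detector saturation), plate-position
and temperature drifts, inter-experiment baseline variability, receptor
desensitization, and any mechanistic receptor-state kinetics. Passing tests
therefore demonstrate that the *pipeline* recovers the orderings its
generator encodes with realistic sample sizes and noise — a power/validity
property of the method, not evidence about any particular laboratory
dataset.

## Determinism and file formats

Traces travel as long-format CSV (`experiment_id, well_id, condition,
time_s, ratio, stim_time_s`; comma separator, `.` decimal, UTF-8, header
mandatory), raw ratios with no baseline subtraction at the I/O layer.
Metrics are written as JSON (full α grid per trace, 17 significant digits —
exact double round-trip) plus long-format CSV; comparisons as CSV. The
`run` stage is end-to-end deterministic: identical config and seed produce
byte-identical outputs, which an acceptance test asserts with file
comparison.

## Problem sizes

Default analyses use the protocol-sized problems: 71-sample traces, 36 (or
16) traces per run, 100-seed robustness sweeps, 1000 bootstrap resamples,
10⁴ null simulations for the type-I calibration check and 2000 trials for
bootstrap coverage — each chosen as the smallest size at which the
corresponding Monte-Carlo fraction is stable to about a percent.
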