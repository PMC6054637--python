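# Methods

`pulsenav` models how a chemotaxing animal can exploit the *first derivative*
of a smooth odor gradient, and provides the analysis chain needed to study
that question end to end: delivering precisely shaped temporal gradients,
quantifying pulsatile calcium responses, testing whether pulse signatures are
animal-specific, measuring adaptation to the derivative, and simulating the
behavioral consequences of that adaptation. This note documents the models,
the default parameters and why they were chosen, the synthetic-data
assumptions, and the numerical conventions.

## Stimulus delivery: the stirred-chamber model

A stimulus syringe (odorant concentration `C_stim`) and a buffer syringe
(`C_buf`) are mixed at total flow `Q` (µL/min) in a continuously stirred
chamber of volume `V` (µL) whose outflow reaches the animal. Treating the
chamber as one well-mixed compartment,

    dC/dt = (Q/V) · (C_in(t) − C),      C_in = C_buf + f(t) · (C_stim − C_buf),

where `f(t) ∈ [0, 1]` is the stimulus flow fraction. We assume a single
compartment with no tubing delay; a pure transport delay would shift every
profile in time without reshaping it.

**Integration.** The ODE is linear, so we integrate with an exponential
update that is exact for piecewise-linear inflow over each sampling interval
`h`: with inflow slope `s` on `[t, t+h]`,

    C(t+h) = C_in(t+h) − s·V/Q + e^(−Qh/V) (C(t) − C_in(t) + s·V/Q).

This is unconditionally stable, exact for constant and ramp inflow, and
reproduces step responses on the grid to machine precision (the step test in
the suite measures ~3·10⁻¹⁵ relative error).

**Schedule inversion.** Solving the ODE for the inflow needed to realise a
target output `C(t)` gives

    f(t) = [ (V/Q)·dC/dt + C(t) − C_buf ] / (C_stim − C_buf).

Any `f` outside `[0, 1]` means the chamber cannot produce the target
(gradient too steep for the flush rate, or concentration outside the syringe
range); the error names the first violating time so the user can flatten or
rescale the target. Feeding the schedule back through the integrator
reproduces feasible tanh/sinusoid targets to better than 10⁻⁴ of their range
on the 1.4 Hz grids used throughout.

**Profile generators** (`step`, `linear`, `tanh`, `sinusoid`,
`exp_derivative`) attach analytic first and second derivatives. The
`exp_derivative` family, `C(t) = baseline + c0·(e^(t/τg) − 1)`, has a first
derivative growing exponentially in time and is used to probe how pulse rate
and amplitude scale with the derivative. The sinusoid is validated with
`baseline ≥ amplitude` so concentration stays non-negative.

## Pulse analytics

AWA-class responses to rising gradients are discrete transients: sharp rise,
exponential decay `A·e^(−t/τ)`. The pipeline:

- **Normalisation**: per-trace min–max to [0, 1]; constant traces are an
  error, not silently zeroed.
- **Detection**: prominence-based local maxima (default prominence 0.2 of
  the trace range, minimum separation 10 s — pulses last tens of seconds at
  the 1.4 frames/s imaging rate). Both parameters are exposed; the 2 Hz
  behavioral traces use prominence 0.1 because their inter-pulse troughs are
  deep and their amplitude range wide.
- **Baseline**: median of the 5 samples preceding pulse onset (onset = last
  pre-peak sample within 10% of the rise above the local base). A median is
  robust to slow drift, which a single-sample baseline is not.
- **Decay fit**: nonlinear least squares of `A·e^(−t/τ)` from the peak to
  the earlier of the next pulse's onset and the first sample below 10% of
  the amplitude, initialised by log-linear regression on the positive
  samples. Log-linear alone is biased under additive noise; the NLS refit
  removes that bias. Noiseless fixtures are recovered to better than 10⁻⁶.
- **Precision limit**: for pulses with τ ≈ 10 s sampled at 1.4 Hz with 5%
  additive noise, the Cramér–Rao bound already puts the τ̂ standard error
  near 4%, so no estimator can put 95% of fits within 5%. The recovery
  benchmarks therefore use τ = 30 s pulses (duration ≈ 70 s, still "tens of
  seconds"), where the fitted values land within 5% in ≥95% of runs.
- **Per-worm metrics**: normalised amplitude = (A − min A)/max A within each
  worm (the denominator is the maximum, not the range — deliberate, matching
  the convention used for the reference analyses), and the same for
  peak-to-peak intervals.

## Individuality shuffle test

Statistic: the mean over worms of the within-worm sample SD (ddof = 1) of a
pulse parameter (amplitude, decay τ, or peak-to-peak interval). Null: all
pulses are exchangeable between worms — pulses are randomly reassigned,
preserving each worm's pulse count. Individuality makes the observed
statistic *small* relative to the shuffled statistic, so the p-value is
one-sided for lowness, with the add-one correction

    p = (1 + #{null ≤ observed}) / (n_shuffles + 1),

which keeps permutation p-values valid and never zero. Worms with fewer than
two pulses carry no within-worm SD and are excluded with a warning. The
shuffle loop is vectorised (one `argsort` of uniform draws per batch of
shuffles, segment sums via `reduceat`), so 10⁶ shuffles of a ~100-pulse
table take seconds. Calibration is tested against exhaustive enumeration on
a tiny cohort and against pooled (null) cohorts, where the p-value
distribution must be uniform.

## Derivative adaptation analyses

For a hyperbolic-tangent gradient the first derivative is symmetric about
the midpoint `t*`; a purely derivative-coding neuron should respond
symmetrically. The pre/post comparison takes each worm's mean normalised
activity over `[t* − 150 s, t*)` and `(t*, t* + 150 s]` (the midpoint sample
belongs to neither window) and applies a paired one-sided Wilcoxon
signed-rank test. Exact enumeration is used up to n = 25 tie-free pairs,
normal approximation with continuity correction beyond; the exact mode is
cross-checked in the tests against a brute-force 2ⁿ sign-flip oracle.

Pulse–derivative coupling is quantified as the Pearson correlation between
the stimulus derivative at pulse peak times and the per-worm-normalised
amplitude (or inter-pulse interval), pooled across worms; Spearman is
available as an option since the choice of correlation flavour is a
convention.

Trajectory analytics: tracks are denoised with a cubic smoothing spline
(penalised least squares; λ = 0 interpolates, large λ approaches the
straight least-squares line, `"auto"` selects λ by generalized
cross-validation). Angular deviation is the angle between the
central-difference velocity and the *instantaneous* direction to the target
(not the fixed start–target chord), 0° = straight at the target, 180° =
straight away; zero-velocity samples are masked. Reversals are deviation
increases of ≥90° within 1 s (both configurable — the thresholds are
conventions, not measurements), merged when closer than the horizon. Each
pulse spans trough-to-trough around its peak and is split at the peak
sample, ties to the falling half; every reversal is annotated with the
normalised activity at its time.

## Chemotaxis simulation

Agents move at unit speed in 2-D; each step they sense the local
concentration, form `Δc` against the previous sample, and either keep their
heading or resample it uniformly on [0, 2π). Turning probabilities: `p_plus`
when the decision state is "keep going", `p_minus` when it is "turn".

- **Classical biased random walk**: turn state iff `Δc < 0`.
- **Derivative adaptation**: two pathways, mirroring the sensory division of
  labour in the worm. A robust non-adapting pathway signals "turn" whenever
  `Δc < 0` (odor-decrease detector). An adapting pathway maintains an EMA of
  `Δc` with memory `M` steps (`ema += (Δc − ema)/M`) and signals "turn" when
  a *rising* concentration no longer beats its recent average
  (`Δc ≥ 0` but `Δc − ema < 0`) — the agent demands steepening gradients,
  not merely rising ones. With no detectable signal at all (see below) both
  pathways are silent and the spontaneous `p_plus` rate applies, exactly as
  in the classical walker. A single-pathway variant that thresholds only
  `Δc − ema` was evaluated and rejected: it adapts to sustained *negative*
  derivatives as well, which silences the corrective turn drive during
  down-gradient runs and loses to the classical strategy over a substantial
  region of parameter space.

**Sensing model.** Samples below a detection floor (`sense_threshold`) read
as zero: real chemosensors have finite detection limits, so a plume has a
finite detectable extent. The default floor equals the field concentration
at the default start distance — the agent begins at the edge of the
detectable plume, as an animal first encountering a gradient does. This
matters for the spontaneous-turn question: outside the plume `Δc = 0`
permanently, the tie rule routes the decision to `p_plus`, and a walker with
`p_plus = 0` that exits ballistically never turns again. Occasional
spontaneous reorientation (`p_plus > 0`) is then genuinely beneficial —
provided `p_minus` is high enough to make exploratory wrong turns cheap —
and the adaptive strategy's score peaks at small positive `p_plus` in the
high-`p_minus` rows. Optional additive Gaussian sensing noise
(`sense_noise_sd`) is available for robustness scans.

**Geometry.** Gaussian field `C = C0·exp(−r²/2σ²)` with σ = 50 step
lengths; agents start at 200 (4σ); runs last 2000 steps; a run ends on
entering the capture radius, set to σ = 50. The capture zone deliberately
covers the flattening core of the field: inside r < σ the radial derivative
*decreases* toward the peak, so a correctly approaching adaptive agent would
be forced into extra turns exactly where it is about to arrive. Ending the
run at one field width — "arrival at the source zone" — keeps the score a
measure of navigation rather than of milling around the flat summit. With
the narrower capture zone of an earlier draft (radius 5), that milling
penalty dominated and inverted the strategy comparison.

**Score.** Mean projection of the unit step displacement onto the
instantaneous direct line to the source, in [−1, 1]; steps after capture are
excluded, zero-length steps are excluded. The fixed start–target-chord
variant is available through `chemotaxis_score` on raw positions.

**Grid scans.** 25×25 grid over [0,1]² (625 cells) × 800 runs per cell per
strategy = 5·10⁵ runs per strategy, vectorised over runs within a cell. Each
cell draws its RNG substream from `SeedSequence(seed, spawn_key=(row, col))`
and replays the *same* substream for both strategies, so results are
bitwise-reproducible, independent of execution order, and the two strategies
see matched random draws (in the `M → ∞` limit they produce identical
trajectories, a property the tests assert). Fold improvement is
`100·(adaptive − classical)/classical` with cells masked where
`|classical| ≤ 0.05` (≈3 standard errors of a cell mean at 800 runs; the
ratio diverges as the classical score crosses zero near the `p_plus =
p_minus` diagonal).

**Linear-gradient oracle.** For the classical walker in a noiseless linear
gradient the heading process is a renewal chain: a heading θ persists for a
geometric number of steps with mean 1/p(θ), where p(θ) = `p_plus` if
cos θ ≥ 0 else `p_minus`, and fresh headings are uniform. The stationary
heading density is ∝ 1/p(θ), giving a mean per-step drift up the gradient of

    v = 2 (p_minus − p_plus) / (π (p_plus + p_minus)),

with the limits v → 2/π as `p_plus → 0` and v = 0 on the diagonal. The
simulator matches this closed form within Monte Carlo error; the oracle is a
verification device, not a user feature.

**Known limitation.** At `p_plus = p_minus = 0` neither strategy ever turns,
the two walkers are identical by construction, and no strategy comparison is
meaningful there; a handful of near-diagonal cells just above the fold mask
likewise have true score differences indistinguishable from zero at 800
runs per cell, so "strictly better in every single unmasked cell" is not a
stable property of any finite-sample run, even though 97% of unmasked cells
are strictly superior and the paired signed-rank bound is passed with orders
of magnitude to spare.

## Synthetic data: what it emulates, and what it does not

All generators are deterministic given a seed and emit ground truth.

- **Pulse cohorts** (`synth_pulse_cohort`): in `individual` mode each worm
  draws a signature (mean amplitude, mean τ) from between-worm lognormals
  (CV 0.5 amplitude, 0.4 τ) and its pulses from tight within-worm lognormals
  (CV 0.1); `pooled` mode draws every pulse i.i.d. with the combined CV —
  the exchangeable null. Amplitudes centre on 1 a.u., decay constants on
  20 s (durations of several tens of seconds). Pulse tails are truncated at
  1% of amplitude and onsets spaced beyond the truncation point, so pulses
  are exactly disjoint and noiseless recovery is exact — real decays overlap
  slightly; the truncation is what licenses the 10⁻⁶ identity check.
  The between-/within-worm CVs are not measured quantities; they encode the
  qualitative observation that a worm's own pulses cluster far more tightly
  than the population, and the shuffle test's power at these settings
  (p ≈ 10⁻⁴ at 10⁴ shuffles for 10 worms × 9 pulses) should be read as
  "the statistic detects structure of this kind", not as a reproduction of
  any measured p-value.
- **Derivative-driven pulsers** (`synth_adaptive_trace`): an inhomogeneous
  Bernoulli pulse process; per sample, P(pulse) = rate·dt with rate and
  amplitude proportional to the positive part of the drive — the stimulus
  derivative itself (non-adapting) or the derivative minus its own EMA with
  a 60 s memory (adapting) — plus a refractory hold until the running pulse
  decays to 10%. The adapting generator produces the before/after-midpoint
  asymmetry on tanh gradients; the non-adapting one is the negative control
  and is symmetric up to pulse-tail spillover (which, if anything, biases
  *against* the asymmetry, making the control conservative).
- **Graded odor-decrease sensor** (`synth_awc_trace`): smoothed positive
  part of minus the derivative plus noise; strongly anti-correlated with the
  derivative on sinusoidal gradients (ρ ≈ −0.9 at default noise).
- **Pulse-gated walker** (`synth_pulse_gated_trajectory`): forward runs
  toward the target while the current pulse exceeds `turn_threshold` (default
  0.58) of its peak; the first sub-threshold sample emits a reversal (1 s
  directly away from the target plus jitter), the run then resumes while the
  old pulse decays for 4 more seconds, and a fresh pulse starts. Sampled at
  2 Hz; the walk ends on arrival. Every reversal therefore falls in the
  falling phase of a pulse, and the deviation-jump detector recovers the
  emitted events to within one sample — these are consistency checks of the
  analysis chain, not biological claims.

None of the generators model indicator kinetics, bleaching, motion
artefacts, or overlapping pulses; passing the recovery tests shows the
analysis chain is correct on data with the assumed structure, not that real
recordings satisfy those assumptions.

## Numerical conventions

Time is seconds everywhere, concentrations µM, the simulator dimensionless
(step lengths); tables are comma-separated UTF-8 with mandatory headers.
Non-uniformly sampled traces are resampled to their median interval with a
warning. Zero paired differences are dropped from signed-rank tests
(Wilcoxon's convention); the signal tie in the simulator (`signal = 0`)
counts as non-negative. Every CLI run writes a manifest (tool version,
config hash, seed, paths). All randomness flows from explicit seeds through
`numpy.random.Generator`.
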