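# Methods

This note documents the models implemented in `poolkin`, the conventions and
numerical choices behind them, and what the synthetic-data generator does and
does not emulate.

## Flash-response kinetics

A spatially uniform [Ca²⁺] step (UV flash photolysis of caged calcium at
t = 0) triggers fusion of primed large dense-core vesicles; fusion adds
membrane area, so baseline-subtracted membrane capacitance ΔC_m(t) tracks
cumulative secretion (≈ 0.94 fF per vesicle). The standard description is

    ΔC_m(t) = A₁(1 − e^(−t/τ₁)) + A₂(1 − e^(−t/τ₂)) + A₃·t,

where A₁, A₂ are the sizes (fF) of the readily and slowly releasable pools
(RRP: τ ≈ 10–20 ms; SRP: τ ≈ hundreds of ms) and A₃ (fF/s) is the sustained
rate of priming followed by immediate fusion.

Some conditions produce S-shaped (convex) traces in which the SRP fuses only
after a delay. Writing the SRP fusion rate as rising gradually towards its
final value, k₂(t) = k_slow(1 − e^(−t/τ_delay)), and keeping the first-order
term of its expansion (valid for long delays, where the two time constants
cannot be identified separately), the SRP term becomes

    ΔC_m,SRP(t) = SRP·(1 − e^(−t²/τ_slow,delay)),

with τ_slow,delay = τ_slow·τ_delay in s². The delayed model substitutes this
term for the slow exponential, keeping the fast exponential and the line.

**Fitting.** Both families have five free parameters, so model selection
compares raw residual sums of squares; ties go to the standard model. A
chi-square goodness-of-fit statistic would require a per-point variance
that capacitance recordings do not supply; with equal parameter counts an
unnormalised RSS comparison selects the same model, and a
baseline-variance-normalised statistic can be derived from the reported
RSS if needed. Fits use bounded
trust-region least squares (amplitudes ≥ 0, τ ∈ [10⁻⁴, 10] s, sustained rate
unbounded — it may legitimately be negative under the delayed model) with
analytic Jacobians and 8 multi-starts pairing log-spaced fast (2 ms–60 ms)
and slow (0.1–2 s, or 0.05–2 s² for the delayed constant) initial time
constants; amplitudes are initialised from the trace end and the terminal
slope. On noiseless model output the generating parameters are recovered to
better than 10⁻⁶ relative error (asserted in tests). Convergence failure on
all starts yields a flagged result, never a silent fallback.

**Window and baseline.** The fit window is t ∈ [0, 5] s after the flash
(total release is conventionally read at 5 s); the baseline is the mean of
the pre-flash samples (t < 0) and is subtracted before fitting. A trace that
does not cover the requested window is rejected.

**Component classification.** An exponential component is assigned to the
RRP when τ ≤ 60 ms and to the SRP when 60 ms < τ ≤ 1 s; slower components
belong to neither pool and are reported in a diagnostics field (the
convention for this case is ours — the source protocol is silent).
For delayed-SRP datasets the upper cut-off is raised to 1.6 s because the
fitted slow constant includes the delay; the delayed component's
characteristic time is taken as √τ_slow,delay, the time at which the SRP
term reaches 1 − 1/e. If both exponentials of a standard fit land in the
same class, the trace is refitted with a single exponential plus line and
the result carries the combined amplitude for that pool. Model-free
readouts at fixed times (60 ms ≈ RRP, 600 ms ≈ RRP+SRP, 0.5 s = burst,
5 s = total) are linearly interpolated relative to the pre-flash baseline.

## Two-pool priming models

A constant upstream depot pool (DP) fills the primed pool PP through a
reversible priming step; k₁·DP is the lumped forward flux, k₋₁ the
depriming rate constant, k_f the fusion rate constant (0 between stimuli).

* **Model I** (chromaffin cell, no release sites):
  dPP/dt = k₁·DP − (k₋₁ + k_f)·PP, recovery time constant 1/(k₋₁ + k_f),
  steady state k₁·DP/(k₋₁ + k_f). k₁·DP carries fF/s.
* **Model II** (release-site-limited, "neuronal"): the pool is capped at
  PP_max and k₁·DP becomes per-site (s⁻¹):
  dPP/dt = k₁·DP·(PP_max − PP) − (k₋₁ + k_f)·PP, recovery time constant
  1/(k₋₁ + k_f + k₁·DP) — sped up by the forward rate — and steady state
  k₁·DP·PP_max/(k₋₁ + k_f + k₁·DP).

Both closed forms are verified against independent stiff ODE integration
(LSODA, rtol 10⁻¹¹) to 10⁻⁸ relative error over [0, 120] s.

**Recovery analysis.** Paired-flash experiments measure Stim2/Stim1 pool
ratios at varying inter-stimulus intervals. The mono-exponential
plateau·(1 − e^(−rate·Δt)) is fitted to the per-cell points by default
(every point carries equal weight; a per-interval-means mode exists, and the
two agree exactly on balanced noiseless designs). With k_f = 0 between
stimuli, rate = k₋₁ under Model I; k₁·DP before stimulation follows from
the steady state (k₋₁ × pool), and multiplying by the fitted plateau gives
the post-stimulation forward rate. The switch of forward rate at the first
flash is modelled as instantaneous; DP depletion is not modelled.
The plateau is constrained ≥ 0.

**Release-site translation.** Assuming the pool rests at a fixed occupancy
of capacity (default 90%, k_f = 0), PP_max = pool/occupancy, and solving
k₋₁ + k₁·DP = rate together with the steady-state condition gives the
closed form k₁·DP = rate·occupancy, k₋₁ = rate·(1 − occupancy). The
translation preserves both the recovery time constant and the steady state,
so Model II recovery with translated parameters is identical to the Model I
curve (asserted to 10⁻⁹); it is exactly invertible.

## Stereology

Total vesicle number per cell from 2D section density δ_v (vesicles/µm²),
vesicle diameter d_v (from 3D tomography), section thickness h = 60 nm,
and resting capacitance C_rest:

1. per-profile cylinder volume π(d_v/2)²h; uncorrected volume fraction
   δ_v·π(d_v/2)²;
2. shape/tangential-slicing correction: sphere volume over the circumscribed
   cylinder of height d_v + h (a vesicle is recognised when ≥ 30 nm of the
   60 nm section cuts it);
3. membrane area C_rest/(10 fF/µm²), cell radius from a sphere, cytoplasm
   volume excluding a nucleus of radius f·r_cell (f = 0.5);
4. N_v = corrected fraction × cytoplasm volume / vesicle volume, identical
   to the single equation N_v = 4δ_v·π·r_cell³(1 − f³)/(3(2r_ves + h))
   (cross-checked to machine precision in tests).

Membrane-proximal vesicles (within 40 nm): areal density n_a = n_l/(d_v +
0.06 µm) from the linear density n_l, times the membrane area; the docked
count applies the tomographic membrane-attached fraction. Full-precision
arithmetic is the default; a "paper-rounding" mode carries each intermediate
at the precision of the printed worked example (3 significant figures on
fractions and volumes, 0.01 µm on the radius) so the stepwise chain matches
a manual recomputation; the two modes agree to 0.5% on the totals.

## Amperometric spikes

Preprocessing subtracts the per-cell flash photoelectric artifact trace
sample-wise and applies a Gaussian low-pass whose −3 dB cut-off is 500 Hz
(σ_t = √(ln 2)/(2π f_c)). Spikes are maximal contiguous excursions above
5 pA, extended to the surrounding baseline crossings. Features: peak current
above baseline (baseline = median of the 50 ms before the window), charge by
trapezoidal integration (pA·s = pC), width at half maximum,
baseline-to-baseline duration, 50–90% rise and 75–25% decay times — all
level crossings linearly interpolated. The foot (pre-spike fusion-pore
current) starts at the first sustained crossing of 2 pA above baseline
before the main upstroke and ends where the extrapolated maximal-slope line
of the upstroke meets the foot level; apparent feet shorter than 0.3 ms
(slivers of the rising flank) are discarded, and absent feet are reported as
absent, not zero. Events with a second supra-threshold peak before return to
25% of the first peak are compound: flagged, excluded from shape statistics,
and counted. The interspike interval is the median spike-to-spike interval.
The foot and compound rules are declared conventions of this package: the
original analysis used an unpublished acquisition-software macro.

## Contingency statistics and titration binning

The two-sided Fisher exact p-value sums hypergeometric point probabilities
of all tables with the observed margins whose probability does not exceed
the observed table's (within 10⁻⁷ relative, absorbing float ties); the
point probabilities are computed with log-gamma factorials and renormalised
over the support. Tests verify exact agreement with integer-arithmetic
enumeration for every table with total ≤ 40, and with an off-the-shelf
implementation. Calcium-titration binning pools per-cell burst sizes into
[0, 0.2), …, [0.6, 0.8), [0.8, 1.2] µM bins (left-closed; final bin closed
on both ends — the boundary convention is declared, not inherited), and
reports mean, SEM and n per bin, with above-range cells excluded and
counted.

## Synthetic-data generator

The generator produces exactly the structures the estimators assume:
noiseless traces equal the model functions at the grid points to machine
precision, and all randomness flows from one seeded generator (identical
seed ⇒ bit-identical output). Defaults mirror the experimental conditions:
capacitance on t ∈ [−0.5, 5] s at 1 ms steps (the lock-in runs near 1 kHz;
all fitted time constants are ≥ 10 ms, so 1 ms sampling is ample) with 2 fF
additive Gaussian noise; amperometry at 25 kHz with 1 pA RMS noise; spikes
as a Poisson process thinned by a 50 ms refractory gap. The recording noise
magnitudes are engineering defaults — the source experiments report none —
so parameter-recovery results at σ = 2 fF quantify estimator behaviour
under these declared conditions, not under any particular rig's noise.
The generator does not emulate calcium dynamics, lock-in demodulation,
correlated (1/f) noise, baseline drift, or fusion-pore physics; passing
round-trip tests therefore demonstrate estimator correctness and stability
under i.i.d. Gaussian noise, not robustness to every artefact of real
recordings.

## Problem sizes in the test suite

Monte-Carlo tests use cohort sizes chosen to match the scale of the original
experiments while keeping the suite quick: recovery cohorts use 8 intervals
(1–120 s) × 6 cells per genotype with 200 replicate cohorts for the
depriming-order statistic; model-selection cohorts use 17 cells (the
reported cohort size) × 5 replicates; single-trace Monte-Carlo uses 40
replicates. Degenerate inputs (flat traces, all-equal recovery ratios,
empty tables, zero densities) are rejected with diagnostics or produce
flagged zero-amplitude results, as described per module above.

## Known limitations

* The delayed-SRP model is the long-delay first-order limit; the full
  two-parameter delay model is intentionally not fitted (non-identifiable).
* Recovery analysis assumes k_f = 0 between stimuli and an instantaneous
  post-flash switch of the forward rate.
* The stereology module takes n_l and the docked fraction as measured
  inputs; it does not resample distance histograms or segment tomograms.
* Spike analysis assumes well-separated events at moderate rates; heavily
  overlapping trains are flagged compound rather than deconvolved.
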