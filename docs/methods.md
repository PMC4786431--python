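# Methods

This note documents the models, conventions, and numerical choices
behind `burstpause`, and what the synthetic-data generators do and do
not emulate.

## Firing-rate metrics

**Windowed rates.** The maximum firing rate is the supremum over all
placements of a rectangular window of width Δt (default 400 ms) of
(spike count in window)/Δt. The supremum over continuous placements is
always attained by a window whose left edge sits on a spike, so
`max_firing_rate` evaluates exactly those placements — the window
"slides along the spike train". This convention also fixes *Time to
Max. Firing Rate*: the earliest spike-anchored window attaining the
maximum. A free grid sweep would instead report left edges up to
(Δt − burst span) *before* a burst, which is neither unique nor
physiologically meaningful (a response beginning at stimulus onset must
score 0 ms latency). The curve form `windowed_rate` does use a grid
(default step 0.1 ms, one sample at 10 kHz) and doubles as a
peristimulus histogram with `step = Δt`. Window intervals are half-open
[t, t+Δt); a 1 ps guard on the right edge keeps float round-up from
swallowing boundary spikes.

**Kernel density.** The spike-density estimate is the sum of unit-area
Gaussians (σ = 25 ms) at the spike times, evaluated on a 0.1 ms grid.
No boundary correction is applied; the default grid extends 5σ past the
recording extent and the outermost spikes so the integral equals the
spike count to < 0.1 % (verified on random trains). An explicitly
truncated grid lets kernel mass leak out, as the naive kernel sum
implies.

**Total peak number.** Procedure: density → time derivative (central
differences on the 0.1 ms grid) → positive local maxima → restrict to
the stimulation window → keep peaks strictly above 0.5 × the largest
windowed positive local maximum ("primal peak") → count. Local maxima
are located on the full curve and then filtered by time; peak-finding on
the truncated segment would create or hide peaks at the window edges.
Only rises are counted (a peak marks a burst onset); peaks closer than
σ are not merged (no merging rule is defined for the metric, and none is
applied). With no spikes, or no positive rise, in the window the count
is 0.

The 0.5 relative threshold makes the metric sensitive to how uniform
burst sizes are across a trial. Continuous tonic drive yields one
dominant onset rise (count ≈ 1); five-pulse intermittent drive with
reliable per-pulse bursts yields exactly 5. If per-pulse spike counts
fluctuate strongly (e.g. Poisson bursts of mean 4.5 spikes), weak bursts
fall below half the strongest rise and the count drops — which is why
the pulse-locked generator below models optogenetic drive as regular,
not Poisson, firing.

## Unconventional spikes

A US is the first spike pair of a consecutive triplet with
ISI₁ < 9 ms (strict) and ISI₂ > 20 ms (strict); the blue-light variant
relaxes ISI₁ to < 15 ms. Triplets are scanned left to right and the two
spikes of an accepted pair are consumed (the next triplet starts at the
triplet's third spike); an `consume=False` mode scans every triplet for
sensitivity analyses. Detection is restricted to the stimulation window
by default (both spikes of the pair must lie inside), overridable. US
counts are monotone in both bounds, and the implementation agrees with
an exhaustive triplet-scan oracle on 1000 random trains.

## FRET pipeline

- Mask: per-frame CFP×YFP product (squares arbor contrast), mean time
  projection, white top-hat background equalisation (disk radius 8 px
  by default), Otsu threshold, suppression of components < 10 px. The
  top-hat + area-opening pair stands in for the under-specified
  "morphology filter" of acquisition software; parameters are exposed.
- ROI extraction: signal = ROI ∩ mask, background = ROI ∖ mask, both
  averaged per frame; R = (YFP_sig − YFP_bg)/(CFP_sig − CFP_bg). The
  ratio orientation is acceptor/donor (YFP/CFP), so a FRET increase —
  Ca²⁺ binding — raises R; the orientation is switchable. R₀ is the
  mean R over 1 s pre-stimulus (baseline length is a free parameter; the
  source analyses do not state one). Frames with a non-positive donor
  denominator are flagged and excluded.
- ΔR_peak = mean of 100·(R − R₀)/R₀ over 400–700 ms after stimulus
  cessation. A trial is a Ca²⁺ transient iff ΔR_peak > 10 % (strict).
  Occurrence rates carry exact (Clopper–Pearson / beta-quantile) 95 %
  intervals, which have ≥ nominal coverage by construction.
- Photobleaching baseline: f(t) = c + A·exp(−kt) fitted by nonlinear
  least squares to frames outside irradiation windows (dips during
  irradiation are heat-dependent attenuations, not bleaching); residuals
  inside the windows quantify dip depth and recovery. Non-convergence
  falls back to the linear trend, flagged.

## Thermometry

Electrode resistance R falls with solution temperature; over 20–55 °C
the relation is Arrhenius: 1/T_K = a + b·ln R, fitted by least squares
(kelvin internally, Celsius at interfaces). The log base is natural; any
base change rescales b and leaves the fit invariant. Extrapolation
outside the fitted R range warns; a non-positive fitted 1/T_K is an
error. The power model is linear: T = ambient + slope·P with ambient
25 °C and slope 0.6 °C/mW (driver-set power), so 30 mW ↦ 43 °C and the
full 0→30 mW sweep spans exactly 18 °C.

## Synthetic data

The generators define the study conditions; every one is a pure
function of (parameters, seed) and emits its ground truth.

**Spike trains.** `simulate_spike_train` is piecewise inhomogeneous
Poisson: `baseline_rate` (default 2 Hz, sparse spontaneous firing)
outside the stimulus, `evoked_rate` (default 84 Hz, the strongly driven
regime) inside it; for pulsed protocols the evoked rate applies during
on-phases only, with baseline firing in the off-phases. An optional
`evoked_mode="regular"` replaces the evoked phase with regular ISIs plus
1 ms Gaussian jitter — sustained high-frequency firing in real neurons
is quasi-regular (refractoriness), and a Poisson evoked phase at 84 Hz
would generate many chance US triplets that real tonic trains do not
show. US injection places the full triplet (s₁, s₁+5 ms, s₁+gap) at
evenly spaced anchors in the stimulus window, where the gap is the
silent pause (default 100 ms, floored at 25 ms so every injected triplet
satisfies the detector's definition); background spikes within the
triplet span plus a 6 ms guard are removed, so the injected first
interval is always the trial's shortest ISI. A post-pause
rate-depression option (fractional thinning for a configurable duration)
is available but off by default — the duration and depth of the
physiological depression after pauses are unquantified, so they are
free parameters.

**Pulse-locked trains.** `simulate_pulse_locked_train` models direct
optogenetic drive: after a per-pulse onset latency (default 25 ms,
appropriate for channelrhodopsin-family actuators at the low irradiances
used in behaviour), the neuron fires regularly at `burst_rate` (default
100 Hz) with 2 ms jitter for the rest of each on-phase. Under the
five-cycle 100 ms on/off protocol these defaults give a sliding-window
maximum firing rate in the low-40 Hz range and a total peak number of
exactly 5 in every trial; the result is insensitive to the exact
parameters (unchanged for burst rates 90–110 Hz and latencies
20–30 ms).

**Voltage traces.** A biphasic template (one sine cycle, 2 ms, positive
lobe first) is superposed at each spike time, peak-aligned to the sample
grid, plus Gaussian noise; ground-truth aligned peak times are returned.
Spacing shorter than the template support flags overlap rather than
erroring. Sampling rates are restricted to 10/20 kHz, the acquisition
rates the analysis conventions assume.

**FRET stacks.** The arbor is a random-walk skeleton dilated by 1 px
(the ground-truth mask). A transient multiplies the dendritic ratio by
1+g(t): linear rise during the stimulus, monoexponential decay
(τ = 2 s) after it; YFP is scaled by √(1+g) and CFP by 1/√(1+g), so the
channels are anti-correlated while total brightness stays near baseline.
The amplitude parameter is defined on the *ratio*, as the trial's
representative value — the mean ΔR/R₀ over the 400–700 ms post-stimulus
window — so the pipeline's ΔR_peak recovers it exactly at zero noise.
Soma pixels (optional) follow slower first-order kinetics (τ = 6 s).
Photobleaching multiplies both fluorophores equally and cancels in the
ratio; pixel noise is Gaussian (reference level sd 5 on a baseline of
100, i.e. SNR 20; mask-recovery tests use sd 20, SNR 5), clipped at
zero. What the generator does *not* emulate: motion along the z-axis,
channel misregistration, shot-noise statistics, or indicator
saturation — passing tests therefore validate the pipeline's arithmetic
and segmentation logic, not its robustness to those real-data artefacts
(the source protocol excluded movement-contaminated trials rather than
correcting them).

**Coupled trials.** One seed spawns independent streams for the spike
train and the Ca²⁺ amplitude. The amplitude is gain × (number of
embedded US triplets) + Gaussian noise, realised as a ratio trace with
the same rise/decay profile, so Spearman correlation between detected US
counts and ΔR_peak is exactly 1 at zero noise and collapses to the
permutation null when the gain is 0.

**Calibration pairs.** Temperatures are spread evenly over 25–50 °C (a
natural-cooling sweep); noise is applied to 1/T_K, the quantity linear
in ln R. Default coefficients correspond to a ~7 MΩ electrode at 25 °C
falling to ~5 MΩ at 50 °C.

## Orchestration and reproducibility

`run_pipeline` fans one master seed out to per-trial child seeds through
`numpy.random.SeedSequence.spawn`, so stages draw from independent
streams and a config re-runs bit-identically; all parameters (Δt 400 ms,
σ 25 ms, US bounds 9/20 ms, ΔR window 400–700 ms, 10 % threshold) are
echoed into the run manifest. The acceptance script derives all nine
trial seeds from its `--seed` argument the same way.

## Problem sizes

Default test and acceptance problem sizes — 9–20 trials, 48–64 px
stacks of 45–60 frames, 100–1000 random trains for oracle agreement,
10⁴ draws for interval coverage — were chosen so each suite validates
its property with margin while the whole battery runs in minutes on one
core.

## Known limitations

- The mask pipeline's binarisation rule (Otsu) and morphology
  parameters are choices; the original acquisition-software filter is
  not specified, so masks are validated against synthetic ground truth,
  not against reference software output.
- The derivative-peak metric's behaviour under strongly unequal burst
  sizes is threshold-dominated (see above); comparisons across
  conditions should hold the drive statistics fixed.
- `detect_spikes` assumes single-unit traces (no sorting) and a single
  polarity; hysteresis is not implemented.
- The US triplet consumption rule (greedy, left-to-right, non-reuse) is
  one of several defensible conventions; the all-triplets mode exists to
  check that conclusions do not hinge on it.
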