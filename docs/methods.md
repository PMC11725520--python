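# Methods

## Pacemaker models

Three limit-cycle oscillator models of the human central circadian clock are
implemented, with right-hand sides and default constants transcribed from
their original publications and shipped in a human-readable parameter file
(`src/circamp/params/models.yaml`) so any divergence is auditable.

**Van der Pol family.** `forger99` and `jewett99` evolve a pacemaker pair
(x, x_c) plus the activated photoreceptor fraction n:

    forger99:  dx/dt  = (π/12)(x_c + B)
               dx_c/dt = (π/12)[ μ(x_c − 4x_c³/3) − x((24/(0.99669 τ_x))² + kB) ]
    jewett99:  dx/dt  = (π/12)[ x_c + μ(x/3 + 4x³/3 − 256x⁷/105) + B ]
               dx_c/dt = (π/12)[ qBx_c − x((24/(0.99729 τ_x))² + kB) ]

with light drive B = G·α(I)·(1−n)·(1−0.4x)(1−0.4x_c), activation
α(I) = α₀(I/I₀)^p, and dn/dt = 60[α(I)(1−n) − βn] (α, β in min⁻¹).  The
numerical factors 0.99669/0.99729 are the published corrections that make
the dark limit-cycle period equal the τ_x parameter (24.2 h).  Amplitude is
the planar norm √(x² + x_c²); the phase angle is atan2(−x_c, x), chosen so
the angle *increases* with time (the pacemaker rotates clockwise in the
(x, x_c) plane) and phase advances are positive.

**Single-population macroscopic model.** `hannay19_sp` evolves the synchrony
order parameter R ∈ [0, 1] (which *is* the amplitude) and collective phase ψ:

    dR/dt = −γR + (K cosβ₁/2) R(1−R⁴)
            + B̂[ (A₁/2)(1−R⁴)cos(ψ+β_L1) + (A₂/2)R(1−R⁸)cos(2ψ+β_L2) ]
    dψ/dt = 2π/τ + (K sinβ₁/2)(1+R⁴)
            + B̂[ σ − (A₁/2)(R³+1/R)sin(ψ+β_L1) − (A₂/2)(1+R⁸)sin(2ψ+β_L2) ]

with B̂ = G·α(I)·(1−n) and α(I) = α₀ I^p/(I^p + I₀).  Two closed forms are
exposed and used as test oracles: the dark fixed point
R\* = (1 − 2γ/(K cosβ₁))^{1/4} ≈ 0.7012, and the dark free-running period
2π / [2π/τ + (K sinβ₁/2)(1+R\*⁴)] ≈ 24.177 h.  Note the raw τ parameter
(23.84 h) is *not* the dark period; the synchrony coupling shifts it, and
`dark_period()` always returns the realized nominal period.

## Integration

Fixed-step classical 4th-order Runge–Kutta, default dt = 0.01 h, with
piecewise-constant light evaluated at the sub-step times.  A fixed-step
scheme was chosen over an adaptive library integrator deliberately: runs are
bitwise deterministic, the order is verifiable by step-halving (the test
suite checks an error ratio of ≈ 2⁴), and paired with/without-stimulus
simulations land on identical time grids, so a zero-lux stimulus produces
*exactly* zero responses rather than solver noise.  Trajectories store the
unwrapped ψ for the macroscopic model so cycle counts are preserved.

## Markers and response curves

CBTmin is the local minimum of x (parabolic sub-step refinement) for the van
der Pol family and the crossing of a designated phase (ψ_ref, default π,
configurable) for `hannay19_sp`; there is no published convention for the
latter, so it is an explicit parameter.  DLMO = CBTmin − `dlmo_offset`, with
the classical 7-h offset as a configurable default.

Response curves are built by: (1) relaxing onto the dark attractor (~10
cycles of burn-in; convergence is asserted at < 1% amplitude drift per
cycle), (2) simulating one dark reference cycle to obtain the attractor
state at each pulse-start phase, and (3) for each of 48 pulse timings
(0.5-h spacing, pulse referenced by its center), running the pulse and its
dark twin from the same stored state and reading the phase shift
Δφ = wrap(θ_stim − θ_ref)·24/2π ∈ (−12, 12] (advances positive) and percent
amplitude change 100(A_stim − A_ref)/A_ref exactly at the pulse-end sample.
The free-run drift correction is a pure offset: interval·(24 − P)/P hours
with P the nominal dark period, subtracted from every Δφ on request; the
assessment interval is a user parameter rather than a hard-coded value.

## Sleep schedules and SRI

Schedules are binary per-epoch sequences (default 1-min epochs, 14 days —
enough days for stable 24-h-lag statistics while keeping actogram-sized
output).  The regular generator places an identical half-open sleep window
every day; because the window length is a whole number of epochs, the sleep
fraction is exact.  The irregular generator perturbs each day's onset and
duration with independent uniform draws on ±jitter (the generative process
behind real irregular sleepers is not specified anywhere; uniform jitter is
the simplest symmetric choice, and its magnitude is calibrated rather than
interpreted).  Windows are laid out in absolute time and wrap circularly
over the horizon, so sleep spilling past the final midnight is not lost.

The Sleep Regularity Index is the fraction of epoch pairs 24 h apart in the
same state, on the 0–1 scale (classical scale = 200·SRI − 100).  The lag is
applied circularly (last day also compared with the first), which makes the
index exactly invariant under circular time shifts and under sleep/wake
complementation; for the worked toy cases the circular and linear pairings
give identical values.  `calibrate_jitter` draws the uniform deviates once
per seed and rescales them, making the SRI a deterministic near-monotone
step function of the jitter magnitude; bisection (duration jitter tied at
half the onset jitter) then reaches a 0.01 tolerance in a handful of
iterations.  Calibrating to SRI 0.75 with the default 8-h sleep demands a
large onset jitter (≈ 4–5 h) — a reminder that SRI 0.75 corresponds to
substantially disrupted sleep timing.

## Amplitude-response actograms

The %ΔR map is the *instantaneous* amplitude response: at each wake-epoch
state, 100·[Ȧ(state, wake_lux) − Ȧ(state, 0)]/A(state) in percent per hour,
where Ȧ comes from the model right-hand side ((xẋ + x_c ẋ_c)/A for the van
der Pol family, Ṙ for the macroscopic model).  This derivative-based
operationalization (rather than a finite-difference of two short
simulations) is exact, cheap, and recorded in the output metadata.  Before
scoring, the model is entrained by simulating 14 repeats of the schedule's
average day (circular-mean onset, mean duration), starting from the dark
attractor with CBTmin at 04:00; on a regular schedule the scored rows repeat
day-to-day to < 10⁻⁴ %/h, confirming entrainment.  Sleep epochs are masked
and exactly zero (darkness responds like darkness).  Map integration uses
dt = 1/120 h so samples land exactly on 1-min epoch boundaries.

## Marker-profile metrics

Per-profile summaries: trapezoidal AUC over the sampled span (no
extrapolation), width between the first up-crossing and last down-crossing
of a concentration threshold with linear interpolation (default 3 pg/mL,
the classical melatonin-onset threshold; width-at-fraction-of-peak was
rejected because onset/offset of secretion is the quantity the threshold
convention defines), peak value/time, and range.  A profile that never
exceeds the threshold gets width 0 plus a warning flag instead of an error.
Ratios after/before are computed per metric; a zero baseline yields NaN with
an `undefined` flag rather than a crash.  The synthetic generator uses two
half-Gaussian limbs with independent rise/fall scales, giving closed-form
AUC (peak·√(π/2)·(rise+fall)) and threshold width
((rise+fall)·√(2·ln(peak/threshold))) used as parameter-recovery oracles.

## What the synthetic data does and does not emulate

The schedule generator reproduces controlled day-to-day variability in
sleep timing, not real actigraphy: no naps, no night-time awakenings, no
weekday/weekend structure, and a fixed 500-lux wake illuminance with true
darkness during sleep (real light exposure varies over orders of
magnitude).  The marker generator produces clean unimodal nocturnal
profiles; real melatonin assays add masking, sampling gaps, and
non-Gaussian noise.  Passing tests therefore validate the *model-level*
claims (sign structure of the response curves, exposure bookkeeping, metric
algebra), not field performance on wearable or assay data.

## Numerical choices and degenerate inputs

- dt = 0.01 h default (1/120 h for maps); the step-halving test pins the
  integrator's 4th-order convergence.
- Zero-amplitude van der Pol states have undefined phase and raise; the
  macroscopic model's R = 0 state is likewise rejected where 1/R appears
  under light.
- Light schedules are half-open, right-continuous step functions; times
  outside the listed span evaluate to a configurable background (default
  0 lux — the dim background of constant-routine protocols is not
  standardized, so it is a parameter).
- The 6.5-h "bright light" protocol's illuminance is not standardized
  either; the CLI defaults to 9500 lux and records the value in output
  metadata.
- Jittered sleep durations are clamped into (0, 24) h with a warning.
- All randomness flows through explicit integer seeds (numpy
  `default_rng`); repeated runs are bitwise reproducible.

## Problem sizes

Default analyses are desk-scale by design: 48-point response-curve grids at
0.5-h spacing, 240-h burn-ins, 14-day schedules at 1-min epochs, and
10-seed Monte-Carlo comparisons for the regular-vs-irregular exposure
contrast.  These sizes resolve every curve feature the analyses read out
(extrema locations to half an hour, SRI to < 0.001) while keeping any
single analysis under a minute on one core.

## Known limitations

- Only the single-population macroscopic model is included; the
  two-population variant is out of scope.
- Parameters are taken as published; no re-fitting to experimental PRC data
  is performed, and empirical PRC data points are not bundled.
- Melanopic illuminance conversion is not modeled; all inputs are photopic
  lux.
- The sleep–wake schedule drives light exposure only; there is no feedback
  from the circadian state onto sleep timing.
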