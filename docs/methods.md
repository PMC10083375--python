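# Methods

## Model overview

`vcapsim` is a forward model of short-latency vestibular compound action
potentials (vCAPs) generated by the utricle in response to transient
bone-conducted vibration (BCV) or air-conducted sound (ACS). It has three
stages.

**Mechanics.** The macula is reduced to two masses vibrating along one line,
both referenced to the temporal bone: the epithelium together with the
membranous labyrinth (displacement `x2`), and the otoconial layer (`x1`).
Each is a damped harmonic oscillator,

    x1'' + 2 ζ1 ω1 x1' + ω1² x1 = f1,      f1 = −β1 a_b + 2 ζ1 ω1 x2' + ω1² x2
    x2'' + 2 ζ2 ω2 x2' + ω2² x2 = f2,      f2 = −β2 a_b − α a_s

where `a_b` is temporal-bone acceleration (BCV) and `a_s` is stapes
acceleration (ACS; the package differentiates a supplied stapes velocity).
The epithelial equation is solved first and substituted into the otoconial
forcing; feedback terms of order of the mass ratio `r = m1/m2 ≪ 1` are
disabled at the default `r = 0` (setting `r > 0` enables a single
fixed-point pass, corrections beyond which are O(r²)). Solutions are causal
convolutions with the underdamped Green's function

    G(t) = H(t) e^(−ζωt) sin(ω_d t)/ω_d,   ω_d = ω √(1−ζ²),

evaluated by FFT at the grid step. Because both the kernel and any
onset-limited forcing vanish at t = 0, the rectangular rule coincides with
the trapezoidal rule; accuracy is verified against an independent 4th-order
Runge–Kutta integration of the same ODE (`solve_sdof_reference`, < 0.1 %
relative RMS at the default step).

Hair-bundle shear is `θ = atan((x1 − x2)/h)`. The arctangent is kept (no
small-angle approximation) so that blast-scale inputs saturate naturally
below π/2 while physiological responses remain linear. The shear rate `θ̇`
(central differences, post-atan) is the adequate drive for the neural stage.

**Spike generation.** A population integrate-and-fire accumulator advances
the firing probability by forward Euler,

    p_n = p_{n−1} + Δt [(−p_{n−1} + g0 + g1 θ_n)/τ] + Δt g2 θ̇_n ,

clamped below at zero. The `g0`/`g1` terms are divided by τ and the `g2`
term is not: that placement keeps every gain dimensionless and puts the
constant-rate latency closed form, `Tm = −τ ln(1 − 1/(g2 c τ))`, on the
sub-millisecond scale observed for shear rates of a few tenths of rad/s.
A crossing of p = 1 defines a population event at the linearly interpolated
time `Tm`; p is then reset and held for an absolute refractory period `T_R`.
Each event recruits `R = N (1 − exp(−θ̇/θ̇0))` units, judged from the peak
|θ̇| over the window from the previous resume time through the event's
refractory dead time — the drive *around* the event. Ending the window at
the threshold crossing instead would let stronger stimuli cross earlier and
never register their own shear-rate peak, capping the amplitude exponent
near 0.5 and destroying the acceleration-proportionality the model is meant
to exhibit. Population timing jitter is Gaussian with `σ = σ_scale / R`
(`σ_scale = 20 ms·units`): larger recruitment means tighter synchronization.
The post-stimulus histogram is the corresponding sum of Gaussian bumps.

**vCAP synthesis.** The extracellular voltage is the causal convolution of
the population histogram with a unitary response: one sine period `Te`
followed by the same sine under an exponential envelope `exp(−(s−Te)/τe)`.
Only the product A·N is identifiable from recordings, so the default output
is normalized (A·N = 1); a recorded reference peak can be used to rescale.
vCAP metrics report the first local extremum within 2 % of the global
|v| maximum — the kernel's opposite-sign lobe has identical magnitude, and
a bare argmax would pick between them on round-off grounds.

## Parameters

| symbol | default | units | role |
|---|---|---|---|
| ω1 | 2π·520 | rad/s | otoconial natural frequency |
| ω2 | 2π·1240 | rad/s | epithelial/labyrinth natural frequency |
| ζ1, ζ2 | 0.3, 0.9 | — | damping ratios (underdamped branch only) |
| α | 0.3 | — | stapes inertial coefficient (ACS gain) |
| β1, β2 | 1 | — | buoyancy/pressure factors (opened labyrinth) |
| r | 0 | — | otoconial/labyrinth mass ratio |
| γ | 0.3 | — | x→y projection for comparison with vibrometry |
| h | 5 µm | m | bundle shear lever arm |
| g0, g1, g2 | 0, 0, 4·10³ | — | IAF gains (phase-locking set) |
| τ | 10 | ms | afferent integration time constant |
| T_R | 3 | ms | absolute refractory period |
| θ̇0 | 12 | rad/s | recruitment saturation shear rate |
| N | 6000 | units | maximum population recruitment |
| σ_scale | 20 | ms·units | population jitter scale (σ = σ_scale/R) |
| Te, τe | 1, 0.3 | ms | unitary-response period and decay |

The damped modes implied by the mechanical constants are 496 Hz and 541 Hz;
the shear-rate-per-acceleration gain peaks between them at ~527 Hz, which is
the model's jerk→acceleration transition frequency (half-cycle pulse width
≈ 0.95 ms).

Four parameters are not fixed by the mechanical/neural constants above and
were calibrated once, by the following reasoning, then frozen:

- **h = 5 µm** — the lever arm converting relative layer displacement into
  bundle angular shear, taken as the stereocilia height of striolar bundles.
  A larger gel-gap reading (15–25 µm) makes the quasi-static shear per
  milli-g so small that the IAF threshold `g2·Δθ ≥ 1` is unreachable at
  stimulus strengths of a few milli-g for any pulse shape, i.e. the model
  could not fire at the stimulus levels it is meant to describe. With 5 µm
  the 0.7–2.6 mg range produces first-spike latencies on the 1–3 ms scale.
- **θ̇0 = 12 rad/s** — recruitment stays within its linear range throughout
  the physiological shear-rate range (≲ 3 rad/s), saturating only toward
  extreme drives. This is required by the model's own proportionality
  behavior: spike threshold for transient drives implies peak shear rates of
  at least several tenths of rad/s, so a sub-rad/s θ̇0 would force full
  saturation in every suprathreshold response and no stimulus quantity could
  be proportional to vCAP amplitude.
- **N = 6000** — with σ = 20 ms/R, operating recruitments of a few hundred
  units give population σ of ~30–60 µs, the only scale compatible with
  vector strengths of 0.93–0.98 at 1 kHz (VS = exp(−(2πfσ)²/2)).
- **A·N = 1** — output voltages are normalized; absolute microvolt scales
  require an experimental reference.

## Study conditions emulated by the generators

- *Width sweeps*: half-sine constant-jerk pulses, 12 log-spaced half-cycle
  widths from 0.13 to 4.6 ms, default peak jerk 43 m/s³ (jerk-regime shear
  rate ≈ 0.8 rad/s); mirrored by raised-cosine constant-acceleration ramps
  (default plateau 0.05 m/s² ≈ 5 mg). Pulses are applied in the excitatory
  shear polarity: the inertial forcing is −a, so a positive pulse deflects
  bundles in the inhibitory direction, and the model deliberately omits
  excitatory–inhibitory rectification.
- *Amplitude ladder*: raised-cosine-enveloped 500 Hz bursts (two cycles,
  ~4 ms packets near the otoconial resonance) at 10 strengths from 0.7 to
  2.6 milli-g — stand-ins for laboratory vibration packets whose exact
  envelopes are instrument-specific.
- *Blast*: a Friedlander stapes-velocity transient (instantaneous rise,
  1 ms positive phase, 0.3 ms decay) — a parametric stand-in for cadaver
  stapes recordings, which are not distributed here. Grid step 1 µs.
- *Phase locking*: sinusoidal shear applied directly to the spike model,
  1 kHz, amplitudes 1.5–2.4·10⁻⁴ rad (just above the phase-locker's
  threshold, where VS rises monotonically and saturates).

## Crossover operationalization

The jerk→acceleration switch is reported as the corner of a two-asymptote
(broken-stick) fit in log-log coordinates: a slope-1 segment (vCAP peak ∝
plateau acceleration ∝ width at fixed jerk) against a width-invariant
plateau, split chosen by least squares, corner at their intersection. With
default parameters this lands at 0.87 ms (mechanics-only, on peak shear
rate: 0.80 ms; rise-time sweep: 0.77 ms), consistent with the
frequency-domain transition at ~527 Hz ↔ 0.95 ms. A stricter flatness
detector — the smallest width whose vCAP peak changes by < 5 % per width
doubling — is also reported (`plateau_entry_width`); it lands one grid step
later (1.26 ms) because the mechanical resonance overshoots by ~25 % around
w ≈ 1.7 ms before settling, and a chord-flatness test cannot distinguish
that transition ripple from regime membership. The corner fit is the
package's headline crossover because it is the definition consistent with
the frequency-domain analysis.

## Numerical choices

- Default grid step 10 µs (blast: 1 µs); sweeps refine to ≥ 25 samples per
  pulse width. The IAF Euler step must satisfy dt < τ/10; threshold
  crossings are interpolated inside the step, making `Tm` grid-independent
  to first order.
- FFT convolution for both the mechanical solution and the vCAP synthesis;
  linearity and time-invariance hold to round-off.
- Sub-threshold sweep entries (no spike) report a zero vCAP peak and are
  excluded from corner fits and exponent ladders rather than interpolated.
- Ties at the vCAP extremum are broken toward the earliest lobe (2 %
  dominance tolerance).
- Events with zero recruitment (pure pacemaker firing without shear drive)
  carry σ = σ_scale so dispersions stay finite.

## What passing tests do and do not show

The synthetic stimuli are idealized: half-sine jerk pulses with a retained
acceleration plateau, noise-free packets, and a parametric blast shape.
They reproduce the *structure* of laboratory stimuli (durations, amplitude
ranges, frequency content) but not instrument ring-down, sensor noise, or
animal-to-animal variability. Green tests therefore certify the model
implementation and its internal consistency — closed-form limits, oracle
equivalence, regime boundaries — not quantitative agreement with any
particular recording.

## Known limitations

- One-dimensional, linear mechanics: no 3-D or rotational kinematics, no
  overdamped branch (ζ ≥ 1 is rejected), no mechanical failure model —
  blast results quantify predicted shear, not damage.
- The neural stage is deliberately empirical: no hair-cell or calyx
  biophysics, no quantal release, no excitatory–inhibitory rectification.
  It is not credible at shear saturation, which is why the blast scenario
  is mechanics-only.
- The amplitude exponent of vCAP peak versus stimulus is reliable in the
  linear recruitment range; near threshold the σ(R)–kernel interaction
  inflates it and deep saturation depresses it (visible at the extremes of
  the rise-time sweep).
- The regularly firing population's background rate with the default τ,
  T_R and g0 = 2.2 is ~110 /s (closed form `T_R − τ ln(1 − 1/g0)`), at the
  upper end of reported vestibular background rates.
- With the refractory period an exact multiple of the stimulus period
  (T_R = 3 ms at 1 kHz), very strong sinusoidal drives alias against the
  refractory clock and vector strength is non-monotonic beyond the default
  amplitude ladder.
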