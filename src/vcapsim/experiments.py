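"""End-to-end in-silico scenarios.

Each scenario chains the stimulus generators, the two-mass mechanics, the
IAF population model and the vCAP synthesis under one parameter set:

* ``run_endtoend`` — single-stimulus pipeline (BCV or ACS).
* ``bcv_amplitude_ladder`` — vibration packets of increasing strength;
  latency and amplitude-growth behavior of the vCAP.
* ``jerk_sweep`` / ``accel_sweep`` — the adequate-stimulus analysis: vary
  pulse width at constant peak jerk (or rise time at constant peak
  acceleration) and locate the width where responses switch from
  acceleration-proportional to jerk-determined.
* ``blast_scenario`` — mechanics-only response to a Friedlander stapes
  velocity transient (the linear neural stage is not meaningful at shear
  saturation).
* ``phaselock_characterize`` — sinusoidal-shear drive of the spike model
  alone; vector strength and phase histograms.

Stimuli are applied in the excitatory shear polarity (generated pulses are
sign-flipped before entering the mechanics): inertial forcing is the
negative of frame acceleration, and the spike model deliberately carries no
excitatory-inhibitory rectification, so polarity matters.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .mechanics import MechanicsResult, MechParams, simulate_mechanics
from .spikegen import (
    IAFParams,
    SpikeEvents,
    integrate_probability,
    phase_histogram,
    psth,
    sample_spike_times,
    vector_strength,
)
from .stimuli import PulseSpec, TimeGrid, constant_accel_pulse, constant_jerk_pulse, \
    friedlander_velocity, mg_to_ms2, sine_burst
from .vcap import KernelParams, VcapTrace, synthesize_vcap
from .waveform import Waveform

__all__ = [
    "SweepResult",
    "LadderResult",
    "BlastSummary",
    "run_endtoend",
    "bcv_amplitude_ladder",
    "jerk_sweep",
    "accel_sweep",
    "blast_scenario",
    "phaselock_characterize",
    "default_sweep_widths",
]

#: Default peak jerk for the width sweeps (m/s^3); places the jerk-regime
#: shear rate near 0.8 rad/s so that responses stay in the linear
#: recruitment range while widths from ~0.5 ms upward reach spike threshold.
DEFAULT_PEAK_JERK = 43.0

#: Default plateau acceleration for the rise-time sweep (m/s^2, ~5 mg).
DEFAULT_PEAK_ACCEL = 0.05


def default_sweep_widths(n: int = 12, lo: float = 0.13e-3, hi: float = 4.6e-3) -> np.ndarray:
    """Log-spaced half-cycle pulse widths, 0.13-4.6 ms by default."""
    return np.logspace(np.log10(lo), np.log10(hi), n)


@dataclass(frozen=True)
class SweepResult:
    """Outcome of a pulse-width (or rise-time) sweep."""

    widths: np.ndarray
    peak_accels: np.ndarray  # m/s^2, magnitude of the plateau/peak
    peak_jerks: np.ndarray  # m/s^3
    peak_shear_rates: np.ndarray  # rad/s
    vcap_peaks: np.ndarray  # V (0 where no spike was evoked)
    scaling_exponents: np.ndarray  # log-log slope of vCAP peak vs amplitude
    crossover_width: float | None  # s, two-asymptote corner (None if absent)
    plateau_entry_width: float | None  # s, first width with <5% change per doubling
    mech_crossover_width: float | None  # s, same corner on peak shear rate

    @property
    def responsive(self) -> np.ndarray:
        return self.vcap_peaks > 0


@dataclass(frozen=True)
class LadderResult:
    """vCAP metrics across a stimulus-amplitude ladder."""

    amplitudes: np.ndarray  # stimulus peak magnitudes (m/s^2)
    vcap_peaks: np.ndarray  # V
    vcap_latencies: np.ndarray  # s, onset to dominant extremum
    first_spike_latencies: np.ndarray  # s, onset to first mean firing time
    recruitments: np.ndarray  # units recruited by the first event


@dataclass(frozen=True)
class BlastSummary:
    """Mechanics-only summary of a blast-scale stapes transient."""

    peak_x1: float  # m
    peak_x2: float  # m
    peak_theta: float  # rad
    time_to_1rad: float | None  # s from onset, None if never reached
    saturated: bool  # peak |theta| > 1 rad


def run_endtoend(
    stimulus: Waveform,
    kind: str,
    mech: MechParams = MechParams(),
    iaf: IAFParams = IAFParams(),
    kern: KernelParams = KernelParams(),
    onset: float = 0.0,
) -> tuple[MechanicsResult, SpikeEvents, VcapTrace]:
    """Full pipeline for one stimulus.

    ``kind`` is ``"bcv"`` (stimulus = temporal-bone acceleration, m/s^2) or
    ``"acs"`` (stimulus = stapes velocity, m/s).  Deterministic: the only
    stochastic element of the package is spike-raster sampling, which is not
    used here.
    """
    if kind == "bcv":
        res = simulate_mechanics(bcv_accel=stimulus, p=mech)
    elif kind == "acs":
        res = simulate_mechanics(stapes_velocity=stimulus, p=mech)
    else:
        raise ValueError(f"kind must be 'bcv' or 'acs', got {kind!r}")
    events = integrate_probability(res.theta, res.theta_dot, iaf)
    if events.n_events == 0:
        zero = stimulus.with_values(np.zeros(stimulus.n), "V")
        return res, events, VcapTrace(zero, 0.0, 0.0, 0)
    density = psth(events, stimulus)
    trace = synthesize_vcap(density, kern, onset=onset)
    return res, events, trace


def bcv_amplitude_ladder(
    amplitudes_mg=None,
    mech: MechParams = MechParams(),
    iaf: IAFParams = IAFParams(),
    kern: KernelParams = KernelParams(),
    frequency: float = 500.0,
    n_cycles: int = 2,
    dt: float = 1e-5,
) -> LadderResult:
    """vCAP latency/amplitude across a ladder of BCV packet strengths.

    The stimulus family emulates brief laboratory vibration packets: a
    raised-cosine-enveloped sine burst (default two cycles at 500 Hz, a ~4 ms
    packet near the otoconial resonance).  The default ladder spans 0.7-2.6
    milli-g in ten steps.
    """
    if amplitudes_mg is None:
        amplitudes_mg = np.linspace(0.7, 2.6, 10)
    amplitudes = np.array([mg_to_ms2(a) for a in np.asarray(amplitudes_mg, float)])
    grid = TimeGrid(0.0, n_cycles / frequency + 0.012, dt)
    peaks, vlat, slat, recs = [], [], [], []
    for a in amplitudes:
        spec = PulseSpec("sine_burst", a, 1.0 / frequency, frequency=frequency,
                         n_cycles=n_cycles)
        stim = -1.0 * sine_burst(spec, grid)  # excitatory polarity
        _, events, trace = run_endtoend(stim, "bcv", mech, iaf, kern)
        if events.n_events == 0:
            raise ValueError(
                f"ladder amplitude {a:.3g} m/s^2 evoked no spike; "
                "increase the stimulus or lower the ladder floor"
            )
        peaks.append(trace.peak_amplitude)
        vlat.append(trace.latency_to_peak)
        slat.append(events.times[0])
        recs.append(events.recruitment[0])
    return LadderResult(amplitudes, np.array(peaks), np.array(vlat),
                        np.array(slat), np.array(recs))


def _broken_stick_corner(widths, values, rising_slope: float) -> float | None:
    """Two-asymptote corner of ``values(widths)`` in log-log coordinates.

    Fits a segment of fixed slope ``rising_slope`` (the amplitude-
    proportional regime) against a flat plateau (the width-invariant
    regime), choosing the split that minimizes squared log error, and
    returns the intersection abscissa.  Needs two points per segment.
    """
    w = np.asarray(widths, float)
    v = np.asarray(values, float)
    ok = v > 0
    w, v = w[ok], v[ok]
    if w.size < 4:
        return None
    lw, lv = np.log(w), np.log(v)
    best = None
    for k in range(2, w.size - 1):
        lc = np.mean(lv[:k] - rising_slope * lw[:k])
        lp = np.mean(lv[k:])
        sse = np.sum((lv[:k] - (lc + rising_slope * lw[:k])) ** 2)
        sse += np.sum((lv[k:] - lp) ** 2)
        if best is None or sse < best[0]:
            best = (sse, lc, lp)
    _, lc, lp = best
    return float(np.exp((lp - lc) / rising_slope))


def _plateau_entry(widths, values, tol: float = 0.05) -> float | None:
    """Smallest width whose value changes by < ``tol`` per width doubling.

    The comparison value at twice the width is interpolated in log-log
    coordinates; widths whose doubling falls outside the sweep are skipped.
    """
    w = np.asarray(widths, float)
    v = np.asarray(values, float)
    ok = v > 0
    w, v = w[ok], v[ok]
    if w.size < 2:
        return None
    lw, lv = np.log(w), np.log(v)
    for wi, vi in zip(w, v):
        if 2 * wi > w[-1]:
            break
        v2 = np.exp(np.interp(np.log(2 * wi), lw, lv))
        if abs(v2 / vi - 1.0) < tol:
            return float(wi)
    return None


def _ladder_exponent(run_one, base_amplitude: float) -> float:
    """Log-log slope of vCAP peak vs amplitude over a (x1, x2, x4) ladder."""
    amps, peaks = [], []
    for s in (1.0, 2.0, 4.0):
        v = run_one(base_amplitude * s)
        if v <= 0:
            return np.nan
        amps.append(base_amplitude * s)
        peaks.append(v)
    return float(np.polyfit(np.log(amps), np.log(peaks), 1)[0])


def _sweep_grid(width: float, dt: float) -> TimeGrid:
    # >= 25 samples per pulse width; tail long enough for spike + kernel
    return TimeGrid(0.0, width + 0.015, min(dt, width / 25.0))


def jerk_sweep(
    widths=None,
    peak_jerk: float = DEFAULT_PEAK_JERK,
    mech: MechParams = MechParams(),
    iaf: IAFParams = IAFParams(),
    kern: KernelParams = KernelParams(),
    dt: float = 1e-5,
) -> SweepResult:
    """Constant-peak-jerk pulses of varying half-cycle width.

    For each width the half-sine jerk pulse (acceleration ramping to a
    plateau ``J 2w/pi``) is run through the full pipeline.  Below the
    mechanical corner the vCAP peak grows in proportion to the plateau
    acceleration; above it the responses become width-invariant, set by the
    jerk alone.  ``crossover_width`` is the two-asymptote corner of vCAP
    peak vs width; ``plateau_entry_width`` is the first width at which the
    peak changes by <5% per width doubling (a stricter, flatness-based
    diagnostic that lands above the corner because the mechanical resonance
    overshoots before settling).  Widths too short to reach spike threshold
    at the base amplitude report a zero vCAP peak and are excluded from the
    fits.
    """
    if widths is None:
        widths = default_sweep_widths()
    widths = np.asarray(widths, float)
    if widths.size < 6:
        raise ValueError("need at least 6 widths to bracket the crossover")

    def run_one(width, jerk_peak):
        grid = _sweep_grid(width, dt)
        spec = PulseSpec("constant_jerk", jerk_peak, width)
        jerk, accel = constant_jerk_pulse(spec, grid)
        _, events, trace = run_endtoend(-1.0 * accel, "bcv", mech, iaf, kern)
        return trace.peak_amplitude

    accels, jerks, rates, peaks, slopes = [], [], [], [], []
    for w in widths:
        grid = _sweep_grid(w, dt)
        spec = PulseSpec("constant_jerk", peak_jerk, w)
        jerk, accel = constant_jerk_pulse(spec, grid)
        res = simulate_mechanics(bcv_accel=-1.0 * accel, p=mech)
        rates.append(float(np.max(np.abs(res.theta_dot.values))))
        accels.append(float(np.max(np.abs(accel.values))))
        jerks.append(float(np.max(np.abs(jerk.values))))
        peaks.append(run_one(w, peak_jerk))
        slopes.append(_ladder_exponent(lambda a, _w=w: run_one(_w, a), peak_jerk))

    peaks = np.array(peaks)
    return SweepResult(
        widths=widths,
        peak_accels=np.array(accels),
        peak_jerks=np.array(jerks),
        peak_shear_rates=np.array(rates),
        vcap_peaks=peaks,
        scaling_exponents=np.array(slopes),
        crossover_width=_broken_stick_corner(widths, peaks, rising_slope=1.0),
        plateau_entry_width=_plateau_entry(widths, peaks),
        mech_crossover_width=_broken_stick_corner(widths, rates, rising_slope=1.0),
    )


def accel_sweep(
    rise_times=None,
    peak_accel: float = DEFAULT_PEAK_ACCEL,
    mech: MechParams = MechParams(),
    iaf: IAFParams = IAFParams(),
    kern: KernelParams = KernelParams(),
    dt: float = 1e-5,
) -> SweepResult:
    """Constant-peak-acceleration ramps of varying rise time (jerk varies).

    The mirror of :func:`jerk_sweep`: short rises (high jerk) all evoke the
    acceleration-determined response; long rises scale with the peak jerk,
    which falls as 1/rise-time.  The corner fit therefore uses a plateau on
    the short-rise side against a slope ``-1`` segment on the long-rise
    side.
    """
    if rise_times is None:
        rise_times = default_sweep_widths()
    rise_times = np.asarray(rise_times, float)
    if rise_times.size < 6:
        raise ValueError("need at least 6 rise times to bracket the crossover")

    def run_one(rise, accel_peak):
        grid = _sweep_grid(rise, dt)
        spec = PulseSpec("constant_accel", accel_peak, rise)
        accel, jerk = constant_accel_pulse(spec, grid)
        _, events, trace = run_endtoend(-1.0 * accel, "bcv", mech, iaf, kern)
        return trace.peak_amplitude

    accels, jerks, rates, peaks, slopes = [], [], [], [], []
    for T in rise_times:
        grid = _sweep_grid(T, dt)
        spec = PulseSpec("constant_accel", peak_accel, T)
        accel, jerk = constant_accel_pulse(spec, grid)
        res = simulate_mechanics(bcv_accel=-1.0 * accel, p=mech)
        rates.append(float(np.max(np.abs(res.theta_dot.values))))
        accels.append(float(np.max(np.abs(accel.values))))
        jerks.append(float(np.max(np.abs(jerk.values))))
        peaks.append(run_one(T, peak_accel))
        slopes.append(_ladder_exponent(lambda a, _T=T: run_one(_T, a), peak_accel))

    peaks = np.array(peaks)
    # plateau for short rises, 1/T (slope -1) for long rises
    corner = _broken_stick_corner(rise_times[::-1], peaks[::-1], rising_slope=-1.0)
    mech_corner = _broken_stick_corner(
        rise_times[::-1], np.array(rates)[::-1], rising_slope=-1.0
    )
    return SweepResult(
        widths=rise_times,
        peak_accels=np.array(accels),
        peak_jerks=np.array(jerks),
        peak_shear_rates=np.array(rates),
        vcap_peaks=peaks,
        scaling_exponents=np.array(slopes),
        crossover_width=corner,
        plateau_entry_width=_plateau_entry(rise_times[::-1], peaks[::-1]),
        mech_crossover_width=mech_corner,
    )


def blast_scenario(
    peak_stapes_velocity: float,
    mech: MechParams = MechParams(),
    duration_td: float = 1e-3,
    decay_tau: float = 3e-4,
    dt: float = 1e-6,
) -> tuple[MechanicsResult, BlastSummary]:
    """Mechanics-only response to a Friedlander stapes-velocity transient.

    At physiological stapes velocities (~1e-4 m/s) the bundle shear stays in
    the 1e-4 rad regime; at blast scale (x1e4 above physiological) the
    relative displacement keeps growing linearly while the arctangent drives
    ``|theta|`` past 1 rad toward its pi/2 bound.  The neural stage is
    deliberately not run: the linear IAF is not credible at shear
    saturation.
    """
    grid = TimeGrid(0.0, 0.01, dt)
    spec = PulseSpec(
        "friedlander_velocity", peak_stapes_velocity, duration_td, decay_tau=decay_tau
    )
    v = friedlander_velocity(spec, grid)
    res = simulate_mechanics(stapes_velocity=v, p=mech)
    th = np.abs(res.theta.values)
    above = np.nonzero(th > 1.0)[0]
    t1 = float(res.theta.t[above[0]]) if above.size else None
    summary = BlastSummary(
        peak_x1=float(np.max(np.abs(res.x1.values))),
        peak_x2=float(np.max(np.abs(res.x2.values))),
        peak_theta=float(np.max(th)),
        time_to_1rad=t1,
        saturated=bool(above.size),
    )
    return res, summary


# parameter sets of the two illustrative afferent classes
PHASE_LOCKING_GAINS = dict(g0=0.0, g1=0.0, g2=4e3)
REGULAR_GAINS = dict(g0=2.2, g1=2e6, g2=0.0)


def phaselock_characterize(
    freq: float = 1000.0,
    amplitudes=None,
    iaf: IAFParams = IAFParams(),
    seed: int = 0,
    duration: float = 0.5,
    dt: float = 1e-5,
    n_bins: int = 32,
    regular_amplitude: float = 1e-5,
):
    """Vector strength vs drive amplitude for sinusoidal bundle shear.

    Drives the spike model directly with ``theta = theta0 sin(2 pi f t)``
    (bypassing the mechanics, as when characterizing afferent synchrony in
    isolation).  Returns a list of records for the phase-locking gain set
    and one record for the regular (pacemaker) set, each with the sampled-
    spike vector strength and phase histogram.  Deterministic for a fixed
    seed.

    The default amplitude ladder spans the range just above the
    phase-locker's threshold, where vector strength rises monotonically and
    saturates; far stronger drives alias against the absolute refractory
    period and synchrony degrades.  The regular population is driven at
    ``regular_amplitude``, weak enough that its pacemaker rhythm (not the
    stimulus) dominates spike timing.
    """
    if amplitudes is None:
        amplitudes = [1.5e-4, 1.7e-4, 2.0e-4, 2.4e-4]
    rng = np.random.default_rng(seed)
    grid = TimeGrid(0.0, duration, dt)
    t = grid.t

    def drive(theta0, gains):
        th = Waveform(0.0, dt, theta0 * np.sin(2 * np.pi * freq * t), "rad")
        thd = Waveform(
            0.0, dt, theta0 * 2 * np.pi * freq * np.cos(2 * np.pi * freq * t), "rad/s"
        )
        p = IAFParams(
            tau=iaf.tau, T_R=iaf.T_R, thetadot0=iaf.thetadot0, N=iaf.N,
            sigma_scale=iaf.sigma_scale, **gains,
        )
        events = integrate_probability(th, thd, p)
        spikes = sample_spike_times(events, rng)
        return events, spikes

    records = []
    for theta0 in np.asarray(amplitudes, float):
        events, spikes = drive(theta0, PHASE_LOCKING_GAINS)
        vs = vector_strength(spikes, freq) if spikes.size else np.nan
        hist = phase_histogram(spikes, freq, n_bins) if spikes.size else None
        records.append(
            dict(population="phase_locking", amplitude=theta0, n_events=events.n_events,
                 vector_strength=vs, phase_histogram=hist)
        )
    theta0 = float(regular_amplitude)
    events, spikes = drive(theta0, REGULAR_GAINS)
    vs = vector_strength(spikes, freq) if spikes.size else np.nan
    hist = phase_histogram(spikes, freq, n_bins) if spikes.size else None
    records.append(
        dict(population="regular", amplitude=theta0, n_events=events.n_events,
             vector_strength=vs, phase_histogram=hist)
    )
    return records
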