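"""Population spike timing from hair-bundle shear.

An empirical integrate-and-fire (IAF) accumulator converts bundle shear
``theta`` and shear rate ``theta_dot`` into the mean firing times of the
synchronized afferent population.  The firing probability obeys the Euler
update

    p_n = p_{n-1} + dt * [(-p_{n-1} + g0 + g1 theta_n) / tau] + dt * g2 theta_dot_n

clamped below at zero; a crossing of p = 1 emits a population event at the
(linearly interpolated) mean time ``Tm``, after which p is reset and held
for an absolute refractory period ``T_R``.  Each event recruits

    R = N (1 - exp(-theta_dot / thetadot0))

units, judged from the peak shear rate since the previous reset, and the
population jitter around ``Tm`` is Gaussian with ``sigma = sigma_scale / R``
(tighter synchronization when more units are recruited).  The resulting
post-stimulus time histogram is a sum of Gaussian bumps; stochastic spike
rasters, vector strength and phase histograms are derived from it.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .waveform import Waveform

__all__ = [
    "IAFParams",
    "SpikeEvents",
    "UndefinedVSError",
    "integrate_probability",
    "recruitment",
    "psth",
    "sample_spike_times",
    "vector_strength",
    "phase_histogram",
    "background_interval",
]


class UndefinedVSError(ValueError):
    """Raised when circular statistics are requested for an empty spike list."""


@dataclass(frozen=True)
class IAFParams:
    """Gains and time constants of the population IAF model.

    The default gain set (``g0 = g1 = 0``, ``g2 = 4e3``) is the
    phase-locking, shear-rate-driven population that generates short-latency
    vCAPs; the regular (pacemaker) population uses ``g0 = 2.2``,
    ``g1 = 2e6``, ``g2 = 0``.  ``thetadot0`` is the shear rate governing
    recruitment saturation and ``N`` the maximum population size; see the
    methods note for how their defaults were fixed.
    """

    g0: float = 0.0
    g1: float = 0.0
    g2: float = 4e3
    tau: float = 0.01  # s
    T_R: float = 0.003  # s, absolute refractory period
    thetadot0: float = 12.0  # rad/s, recruitment saturation shear rate
    N: float = 6000.0  # maximum units recruited per event
    sigma_scale: float = 0.020  # s * units; sigma_m = sigma_scale / R_m

    def __post_init__(self) -> None:
        if self.tau <= 0:
            raise ValueError("tau must be positive")
        if self.T_R < 0:
            raise ValueError("refractory period must be non-negative")
        if self.N < 1:
            raise ValueError("N must be at least 1")
        if self.thetadot0 <= 0:
            raise ValueError("thetadot0 must be positive")
        for g in (self.g0, self.g1, self.g2):
            if g < 0:
                raise ValueError("gains must be non-negative")


@dataclass(frozen=True)
class SpikeEvents:
    """Population events: mean times, recruitment counts and dispersions."""

    times: np.ndarray = field(default_factory=lambda: np.empty(0))
    recruitment: np.ndarray = field(default_factory=lambda: np.empty(0))
    sigma: np.ndarray = field(default_factory=lambda: np.empty(0))

    def __post_init__(self) -> None:
        object.__setattr__(self, "times", np.asarray(self.times, float))
        object.__setattr__(self, "recruitment", np.asarray(self.recruitment, float))
        object.__setattr__(self, "sigma", np.asarray(self.sigma, float))
        if not (self.times.size == self.recruitment.size == self.sigma.size):
            raise ValueError("times, recruitment and sigma must be congruent")
        if self.times.size > 1 and np.any(np.diff(self.times) <= 0):
            raise ValueError("event times must be strictly increasing")

    @property
    def n_events(self) -> int:
        return self.times.size


def recruitment(peak_shear_rate: float, p: IAFParams) -> float:
    """Saturating recruitment ``R = N (1 - exp(-theta_dot/thetadot0))``."""
    if peak_shear_rate < 0:
        raise ValueError("peak shear rate must be non-negative")
    return float(p.N * (1.0 - np.exp(-peak_shear_rate / p.thetadot0)))


def integrate_probability(
    theta: Waveform, theta_dot: Waveform, p: IAFParams
) -> SpikeEvents:
    """Forward-Euler IAF integration producing population events.

    Threshold crossings are interpolated linearly inside the Euler step so
    that event times decouple from the grid step at first order.  The
    recruitment of each event is set by the peak ``|theta_dot|`` observed
    since the previous reset; an event with zero recruitment (pure pacemaker
    firing without shear drive) carries ``sigma = sigma_scale`` so that the
    dispersion stays finite.
    """
    theta.require_grid(theta_dot)
    dt = theta.dt
    if dt >= p.tau / 10.0:
        raise ValueError(
            f"dt = {dt} too coarse for tau = {p.tau}; need dt < tau/10"
        )
    th = theta.values
    thd = theta_dot.values
    t = theta.t

    times: list[float] = []
    recs: list[float] = []
    sigs: list[float] = []

    abs_rate = np.abs(thd)
    prob = 0.0
    window_start = 0
    resume_t = -np.inf  # integration suspended until this time
    pending: int | None = None  # index closing the previous event's window
    for i in range(1, theta.n):
        if pending is not None and t[i] >= resume_t:
            # close the previous event's recruitment window at the end of
            # its refractory dead time: units are recruited by the drive
            # around Tm, including the shear-rate peak reached just after
            # threshold crossing
            r = recruitment(float(abs_rate[window_start:i].max(initial=0.0)), p)
            recs.append(r)
            sigs.append(p.sigma_scale / r if r > 0 else p.sigma_scale)
            window_start = i
            pending = None
        if t[i] < resume_t:
            continue
        dp = dt * ((-prob + p.g0 + p.g1 * th[i]) / p.tau) + dt * p.g2 * thd[i]
        new = prob + dp
        if new < 0.0:
            new = 0.0
        if new >= 1.0:
            frac = (1.0 - prob) / (new - prob) if new > prob else 1.0
            tm = t[i - 1] + frac * dt
            times.append(tm)
            prob = 0.0
            resume_t = tm + p.T_R
            pending = i
        else:
            prob = new
    if pending is not None:
        r = recruitment(float(abs_rate[window_start:].max(initial=0.0)), p)
        recs.append(r)
        sigs.append(p.sigma_scale / r if r > 0 else p.sigma_scale)
    return SpikeEvents(np.array(times), np.array(recs), np.array(sigs))


def psth(events: SpikeEvents, grid) -> Waveform:
    """Post-stimulus histogram: sum of Gaussian bumps (units/s).

    Integrates to the total recruitment when the grid covers every bump out
    to +/- 5 sigma; a bump clipped beyond 3 sigma triggers a coverage
    warning.
    """
    t = np.asarray(grid.t, dtype=float)
    out = np.zeros_like(t)
    for tm, r, s in zip(events.times, events.recruitment, events.sigma):
        if tm - 3 * s < t[0] or tm + 3 * s > t[-1]:
            warnings.warn(
                f"grid clips the PSTH bump at t={tm:.6g} beyond 3 sigma",
                RuntimeWarning,
                stacklevel=2,
            )
        out += r / (s * np.sqrt(2 * np.pi)) * np.exp(-0.5 * ((t - tm) / s) ** 2)
    return Waveform(float(t[0]), grid.dt, out, "units/s")


def sample_spike_times(events: SpikeEvents, seed) -> np.ndarray:
    """Stochastic raster: ``round(Rm)`` Normal(Tm, sigma_m) draws per event.

    Identical seeds give byte-identical output (sorted within each event).
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    draws = []
    for tm, r, s in zip(events.times, events.recruitment, events.sigma):
        k = int(round(r))
        if k > 0:
            draws.append(np.sort(rng.normal(tm, s, size=k)))
    if not draws:
        return np.empty(0)
    return np.concatenate(draws)


def vector_strength(spike_times, stimulus_freq: float) -> float:
    """Circular synchronization index ``|sum exp(i 2 pi f t_k)| / n`` in [0, 1]."""
    t = np.asarray(spike_times, dtype=float)
    if t.size == 0:
        raise UndefinedVSError("vector strength is undefined for an empty spike list")
    ph = np.exp(2j * np.pi * stimulus_freq * t)
    return float(np.abs(ph.mean()))


def phase_histogram(spike_times, stimulus_freq: float, n_bins: int = 32):
    """Normalized histogram of spike phases ``2 pi f t mod 2 pi``.

    Returns ``(bin_centers_rad, probability)`` with the probabilities
    summing to one — usable directly for both cartesian and polar plots.
    """
    if n_bins < 8:
        raise ValueError("need at least 8 phase bins")
    t = np.asarray(spike_times, dtype=float)
    if t.size == 0:
        raise UndefinedVSError("phase histogram is undefined for an empty spike list")
    phases = np.mod(2 * np.pi * stimulus_freq * t, 2 * np.pi)
    counts, edges = np.histogram(phases, bins=n_bins, range=(0.0, 2 * np.pi))
    centers = 0.5 * (edges[:-1] + edges[1:])
    return centers, counts / counts.sum()


def background_interval(p: IAFParams) -> float:
    """Closed-form pacemaker interval ``T_R - tau ln(1 - 1/g0)`` for g0 > 1.

    Without stimulus the probability relaxes toward ``g0``; with ``g0 > 1``
    it crosses threshold periodically at this interval.
    """
    if p.g0 <= 1:
        raise ValueError("background firing requires g0 > 1")
    return float(p.T_R - p.tau * np.log(1.0 - 1.0 / p.g0))
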