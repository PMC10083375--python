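"""Stimulus waveform generators.

Bone-conducted vibration (BCV) enters the mechanical model as temporal-bone
acceleration; air-conducted sound (ACS) enters as stapes velocity.  The
generators here produce the parametric pulse families used throughout:
half-sine constant-jerk pulses, cosine-ramp constant-acceleration pulses,
enveloped sine bursts, and a Friedlander blast-like velocity transient.

All generators are exactly linear in their ``peak`` parameter and are zero
before stimulus onset.  Accelerations are stored in m/s^2; convenience
conversion from g / milli-g is provided (1 g = 9.81 m/s^2).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .waveform import (
    GridError,
    UnitError,
    Waveform,
    differentiate,
    integrate,
    read_waveform,
    write_waveform,
)

__all__ = [
    "G_STANDARD",
    "PulseSpec",
    "TimeGrid",
    "InvalidSpecError",
    "ResolutionError",
    "constant_jerk_pulse",
    "constant_accel_pulse",
    "sine_burst",
    "friedlander_velocity",
    "mg_to_ms2",
    # re-exported signal calculus / IO
    "Waveform",
    "GridError",
    "UnitError",
    "differentiate",
    "integrate",
    "read_waveform",
    "write_waveform",
]

#: Standard gravity used for g <-> m/s^2 conversion.
G_STANDARD = 9.81


def mg_to_ms2(mg: float) -> float:
    """Convert milli-g to m/s^2."""
    return mg * 1e-3 * G_STANDARD


class InvalidSpecError(ValueError):
    """Raised for out-of-contract pulse specifications."""


class ResolutionError(ValueError):
    """Raised when the time grid is too coarse for the requested stimulus."""


@dataclass(frozen=True)
class TimeGrid:
    """Uniform simulation grid: ``t_start`` .. ``t_end`` at step ``dt`` (s)."""

    t_start: float
    t_end: float
    dt: float = 1e-5

    def __post_init__(self) -> None:
        if not self.dt > 0 or not self.t_end > self.t_start:
            raise GridError("require dt > 0 and t_end > t_start")

    @property
    def n(self) -> int:
        return int(round((self.t_end - self.t_start) / self.dt)) + 1

    @property
    def t(self) -> np.ndarray:
        return self.t_start + self.dt * np.arange(self.n)

    def zeros(self, unit: str) -> Waveform:
        return Waveform(self.t_start, self.dt, np.zeros(self.n), unit)


@dataclass(frozen=True)
class PulseSpec:
    """Parametric stimulus description.

    ``kind`` selects the family; ``peak`` is in m/s^3 (constant_jerk),
    m/s^2 (constant_accel, sine bursts) or m/s (friedlander_velocity).
    ``width_or_rise`` is the half-sine width, cosine rise time, or blast
    positive-phase duration, in seconds.
    """

    kind: str
    peak: float
    width_or_rise: float
    frequency: float | None = None  # Hz, sine_burst only
    n_cycles: int | None = None  # sine_burst only
    decay_tau: float | None = None  # s, friedlander only
    onset: float = 0.0  # stimulus onset time (s)

    def __post_init__(self) -> None:
        if not np.isfinite(self.peak):
            raise InvalidSpecError("peak must be finite")
        if not self.width_or_rise > 0:
            raise InvalidSpecError("width_or_rise must be positive")
        if self.n_cycles is not None and self.n_cycles < 1:
            raise InvalidSpecError("n_cycles must be >= 1")


def _check_resolution(grid: TimeGrid, width: float, samples: int = 20) -> None:
    if width / grid.dt < samples:
        raise ResolutionError(
            f"grid too coarse: {width / grid.dt:.1f} samples per pulse width, "
            f"need at least {samples}"
        )


def constant_jerk_pulse(spec: PulseSpec, grid: TimeGrid) -> tuple[Waveform, Waveform]:
    """Half-sine jerk pulse and its exact running integral (acceleration).

    The jerk is ``J sin(pi (t - onset)/w)`` for one half cycle of width ``w``.
    Its integral ramps the acceleration smoothly from zero to the plateau
    ``J * 2w/pi``, where it stays (a unipolar jerk pulse leaves a net
    acceleration); peak acceleration is therefore ``peak_jerk * 2w/pi``.
    """
    if spec.kind != "constant_jerk":
        raise InvalidSpecError(f"expected kind='constant_jerk', got {spec.kind!r}")
    if not 1e-5 <= spec.width_or_rise <= 1e-1:
        raise InvalidSpecError("jerk pulse width must lie in [1e-5, 1e-1] s")
    _check_resolution(grid, spec.width_or_rise)
    w = spec.width_or_rise
    tau = grid.t - spec.onset
    jerk = np.where(
        (tau >= 0) & (tau <= w), spec.peak * np.sin(np.pi * tau / w), 0.0
    )
    # closed-form integral of the half sine, then plateau
    accel = np.where(
        tau < 0,
        0.0,
        np.where(
            tau <= w,
            spec.peak * (w / np.pi) * (1.0 - np.cos(np.pi * np.minimum(tau, w) / w)),
            spec.peak * 2.0 * w / np.pi,
        ),
    )
    return (
        Waveform(grid.t_start, grid.dt, jerk, "m/s^3"),
        Waveform(grid.t_start, grid.dt, accel, "m/s^2"),
    )


def constant_accel_pulse(spec: PulseSpec, grid: TimeGrid) -> tuple[Waveform, Waveform]:
    """Raised-cosine ramp to an acceleration plateau, plus its exact jerk.

    The acceleration rises as ``a0/2 (1 - cos(pi t/T))`` over rise time ``T``
    and then holds the plateau ``a0``.  The jerk is the analytic derivative,
    a half-sine of peak ``a0 pi / (2T)`` — inversely proportional to the
    rise time at fixed plateau.
    """
    if spec.kind != "constant_accel":
        raise InvalidSpecError(f"expected kind='constant_accel', got {spec.kind!r}")
    _check_resolution(grid, spec.width_or_rise)
    T = spec.width_or_rise
    a0 = spec.peak
    tau = grid.t - spec.onset
    accel = np.where(
        tau < 0,
        0.0,
        np.where(tau <= T, 0.5 * a0 * (1.0 - np.cos(np.pi * np.minimum(tau, T) / T)), a0),
    )
    jerk = np.where(
        (tau >= 0) & (tau <= T), 0.5 * a0 * (np.pi / T) * np.sin(np.pi * tau / T), 0.0
    )
    return (
        Waveform(grid.t_start, grid.dt, accel, "m/s^2"),
        Waveform(grid.t_start, grid.dt, jerk, "m/s^3"),
    )


def sine_burst(
    spec: PulseSpec, grid: TimeGrid, unit: str = "m/s^2", ramp_cycles: float = 1.0
) -> Waveform:
    """Sinusoidal burst of ``n_cycles`` full cycles, zero elsewhere.

    A raised-cosine onset/offset envelope of ``ramp_cycles`` cycles (default
    one) avoids spectral splatter; set ``ramp_cycles=0`` for a hard gate.
    """
    if spec.frequency is None or spec.n_cycles is None:
        raise InvalidSpecError("sine_burst requires frequency and n_cycles")
    f = spec.frequency
    if f <= 0:
        raise InvalidSpecError("frequency must be positive")
    if f >= 0.5 / grid.dt:
        raise ResolutionError(
            f"frequency {f} Hz is at or above the grid Nyquist {0.5 / grid.dt} Hz"
        )
    dur = spec.n_cycles / f
    tau = grid.t - spec.onset
    carrier = np.sin(2 * np.pi * f * tau)
    env = np.ones_like(tau)
    if ramp_cycles > 0:
        ramp = min(ramp_cycles / f, dur / 2)
        env = np.minimum(tau / ramp, 1.0)
        env = np.minimum(env, (dur - tau) / ramp)
        env = 0.5 * (1.0 - np.cos(np.pi * np.clip(env, 0.0, 1.0)))
    gate = (tau >= 0) & (tau <= dur)
    return Waveform(grid.t_start, grid.dt, np.where(gate, spec.peak * carrier * env, 0.0), unit)


def friedlander_velocity(spec: PulseSpec, grid: TimeGrid) -> Waveform:
    """Blast-like stapes velocity ``v = peak (1 - t/td) exp(-t/tau)``.

    The classic Friedlander shape: instantaneous rise to ``peak`` at onset,
    exponential decay with time constant ``decay_tau``, and a negative phase
    after the positive-phase duration ``td = width_or_rise``.  A parametric
    stand-in for measured blast stapes-velocity records, which are not
    distributed with the package.
    """
    if spec.kind != "friedlander_velocity":
        raise InvalidSpecError(f"expected kind='friedlander_velocity', got {spec.kind!r}")
    if spec.decay_tau is None or spec.decay_tau <= 0:
        raise InvalidSpecError("friedlander_velocity requires decay_tau > 0")
    td = spec.width_or_rise
    tau = grid.t - spec.onset
    v = np.where(tau < 0, 0.0, spec.peak * (1.0 - tau / td) * np.exp(-np.maximum(tau, 0.0) / spec.decay_tau))
    return Waveform(grid.t_start, grid.dt, v, "m/s")
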