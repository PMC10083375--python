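"""Two-degree-of-freedom otoconial / epithelial vibration model.

The utricular macula is modelled as two tethered masses vibrating along a
line: the epithelium-plus-membranous-labyrinth (displacement ``x2`` relative
to the temporal bone) and the otoconial layer (``x1``).  Each obeys a damped
oscillator

    x''_n + 2 zeta_n omega_n x'_n + omega_n^2 x_n = f_n(t)

driven by inertial forcing from temporal-bone acceleration (BCV) and/or
stapes acceleration (ACS).  The epithelial equation is solved first and its
motion enters the otoconial forcing; mass-ratio feedback of order ``r`` is
neglected by default (``r = 0``).  Solutions are causal Green's-function
convolutions with the underdamped kernel

    G(t) = H(t) exp(-zeta omega t) sin(omega_d t) / omega_d,
    omega_d = omega sqrt(1 - zeta^2).

Hair-bundle shear is ``theta = atan((x1 - x2)/h)`` with ``h`` the shear
lever arm of the bundles, and the shear rate ``theta_dot`` is the adequate
drive for synchronized afferent firing downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.signal import fftconvolve

from .waveform import GridError, Waveform
from .waveform import differentiate as _ddt

__all__ = [
    "MechParams",
    "MechanicsResult",
    "UnsupportedDampingError",
    "NoStimulusError",
    "greens_kernel",
    "solve_sdof",
    "solve_sdof_reference",
    "force_epithelium",
    "force_otoconia",
    "simulate_mechanics",
    "natural_frequencies",
    "transfer_functions",
    "transfer_crossover",
]


class UnsupportedDampingError(ValueError):
    """Raised for zeta outside the underdamped range (0, 1)."""


class NoStimulusError(ValueError):
    """Raised when neither a BCV nor an ACS stimulus is supplied."""


@dataclass(frozen=True)
class MechParams:
    """Mechanical constants of the two-mass model.

    Defaults are the guinea-pig estimates: otoconial mode ``omega1 = 2*pi*520``
    rad/s with ``zeta1 = 0.3``, epithelial/labyrinth mode ``omega2 = 2*pi*1240``
    rad/s with ``zeta2 = 0.9``, stapes inertial coefficient ``alpha = 0.3``,
    mass ratio ``r = 0``, and opened-labyrinth buoyancy factors
    ``beta1 = beta2 = 1``.  ``h`` is the hair-bundle shear lever arm (m) and
    ``gamma`` projects tangential (x) epithelial motion onto the out-of-plane
    (y) direction probed by laser vibrometry.
    """

    omega1: float = 2 * np.pi * 520.0
    omega2: float = 2 * np.pi * 1240.0
    zeta1: float = 0.3
    zeta2: float = 0.9
    alpha: float = 0.3
    beta1: float = 1.0
    beta2: float = 1.0
    r: float = 0.0
    gamma: float = 0.3
    h: float = 5e-6

    def __post_init__(self) -> None:
        if self.omega1 <= 0 or self.omega2 <= 0:
            raise ValueError("natural frequencies must be positive")
        for z in (self.zeta1, self.zeta2):
            if not 0 < z < 1:
                raise UnsupportedDampingError(
                    f"damping ratio {z} outside the underdamped range (0, 1)"
                )
        if self.h <= 0:
            raise ValueError("h must be positive")
        if not 0 <= self.r < 1:
            raise ValueError("mass ratio r must lie in [0, 1)")
        for name in ("alpha", "beta1", "beta2"):
            v = getattr(self, name)
            if not 0 < v <= 2:
                raise ValueError(f"{name} must lie in (0, 2], got {v}")


@dataclass(frozen=True)
class MechanicsResult:
    """Layer kinematics and hair-bundle shear on a shared grid."""

    x1: Waveform  # otoconial layer displacement re: temporal bone (m)
    x2: Waveform  # epithelium displacement re: temporal bone (m)
    theta: Waveform  # bundle shear angle (rad)
    theta_dot: Waveform  # bundle shear rate (rad/s)
    epithelium_velocity_y: Waveform  # gamma * dx2/dt (m/s)


def greens_kernel(omega: float, zeta: float, grid) -> Waveform:
    """Impulse response of the underdamped oscillator sampled on ``grid``.

    ``G(0) = 0`` and ``G'(0+) = 1``; valid only for ``0 < zeta < 1``.
    """
    if not 0 < zeta < 1:
        raise UnsupportedDampingError(
            f"zeta={zeta}: only the underdamped branch (0 < zeta < 1) is modelled"
        )
    if not (hasattr(grid, "t") and hasattr(grid, "dt")):
        raise TypeError("grid must expose .t and .dt")
    omega_d = omega * np.sqrt(1.0 - zeta**2)
    t = np.asarray(grid.t, dtype=float)
    tt = t - t[0]
    g = np.exp(-zeta * omega * tt) * np.sin(omega_d * tt) / omega_d
    return Waveform(float(t[0]), grid.dt, g, "s")


def solve_sdof(f: Waveform, omega: float, zeta: float) -> Waveform:
    """Causal convolution solution ``x = G * f`` of one oscillator.

    Uses FFT convolution at the grid step; since both the kernel and any
    physically onset-limited forcing vanish at the first sample, the
    rectangular rule coincides with the trapezoidal rule here.
    """
    g = greens_kernel(omega, zeta, f)
    x = fftconvolve(f.values, g.values)[: f.n] * f.dt
    return f.with_values(x, "m")


def solve_sdof_reference(f: Waveform, omega: float, zeta: float) -> Waveform:
    """Classical RK4 time stepping of the same oscillator (test oracle).

    Kept deliberately independent of :func:`solve_sdof`: it integrates the
    second-order ODE directly, with linear interpolation of the forcing at
    half steps.  Requires ``dt * omega <= 0.1`` for accuracy/stability.
    """
    if not 0 < zeta < 1:
        raise UnsupportedDampingError(f"zeta={zeta} outside (0, 1)")
    if f.dt * omega > 0.1:
        raise ValueError(
            f"dt*omega = {f.dt * omega:.3f} > 0.1: grid too coarse for the RK4 oracle"
        )
    dt = f.dt
    fv = f.values
    n = f.n
    x = np.zeros(n)
    v = np.zeros(n)

    def acc(xi, vi, fi):
        return fi - 2 * zeta * omega * vi - omega**2 * xi

    for i in range(n - 1):
        f0, f1 = fv[i], fv[i + 1]
        fh = 0.5 * (f0 + f1)
        k1x = v[i]
        k1v = acc(x[i], v[i], f0)
        k2x = v[i] + 0.5 * dt * k1v
        k2v = acc(x[i] + 0.5 * dt * k1x, v[i] + 0.5 * dt * k1v, fh)
        k3x = v[i] + 0.5 * dt * k2v
        k3v = acc(x[i] + 0.5 * dt * k2x, v[i] + 0.5 * dt * k2v, fh)
        k4x = v[i] + dt * k3v
        k4v = acc(x[i] + dt * k3x, v[i] + dt * k3v, f1)
        x[i + 1] = x[i] + dt / 6.0 * (k1x + 2 * k2x + 2 * k3x + k4x)
        v[i + 1] = v[i] + dt / 6.0 * (k1v + 2 * k2v + 2 * k3v + k4v)
    return f.with_values(x, "m")


def force_epithelium(
    bcv_accel: Waveform | None,
    stapes_accel: Waveform | None,
    p: MechParams,
    x1: Waveform | None = None,
) -> Waveform:
    """Forcing of the epithelial equation: ``f2 = -beta2 a_b - alpha a_s``.

    A missing input is treated as zero.  When ``p.r > 0`` and the otoconial
    motion ``x1`` is supplied, the mass-ratio feedback
    ``+ 2 zeta1 omega1 r x1' + omega1^2 r x1`` is included.
    """
    if bcv_accel is None and stapes_accel is None:
        raise NoStimulusError("need at least one of bcv_accel, stapes_accel")
    ref = bcv_accel if bcv_accel is not None else stapes_accel
    assert ref is not None
    total = np.zeros(ref.n)
    if bcv_accel is not None:
        total -= p.beta2 * bcv_accel.values
    if stapes_accel is not None:
        ref.require_grid(stapes_accel)
        total -= p.alpha * stapes_accel.values
    if p.r > 0 and x1 is not None:
        ref.require_grid(x1)
        dx1 = _ddt(x1)
        total += p.r * (2 * p.zeta1 * p.omega1 * dx1.values + p.omega1**2 * x1.values)
    return ref.with_values(total, "m/s^2")


def force_otoconia(
    bcv_accel: Waveform | None, x2: Waveform, p: MechParams
) -> Waveform:
    """Forcing of the otoconial equation.

    ``f1 = -beta1 a_b + 2 zeta1 omega1 x2' + omega1^2 x2`` — the epithelium
    drags the otoconial layer through its spring and damper.
    """
    dx2 = _ddt(x2)
    total = 2 * p.zeta1 * p.omega1 * dx2.values + p.omega1**2 * x2.values
    if bcv_accel is not None:
        bcv_accel.require_grid(x2)
        total = total - p.beta1 * bcv_accel.values
    return x2.with_values(total, "m/s^2")


def simulate_mechanics(
    bcv_accel: Waveform | None = None,
    stapes_velocity: Waveform | None = None,
    p: MechParams = MechParams(),
) -> MechanicsResult:
    """Run the full mechanical chain for BCV and/or ACS stimulation.

    The epithelial equation is solved first (neglecting the ``r`` feedback),
    its motion is substituted into the otoconial forcing, and bundle shear
    follows as ``theta = atan((x1 - x2)/h)`` — the arctangent keeps blast-
    scale responses bounded below pi/2 while physiological responses remain
    in the linear small-angle regime.  For ``r > 0`` a single fixed-point
    pass feeds ``x1`` back into the epithelial forcing (corrections beyond
    one pass are of order ``r**2``).
    """
    if bcv_accel is None and stapes_velocity is None:
        raise NoStimulusError("need at least one of bcv_accel, stapes_velocity")
    stapes_accel = _ddt(stapes_velocity) if stapes_velocity is not None else None
    if bcv_accel is not None and stapes_accel is not None:
        bcv_accel.require_grid(stapes_accel)

    f2 = force_epithelium(bcv_accel, stapes_accel, p)
    x2 = solve_sdof(f2, p.omega2, p.zeta2)
    f1 = force_otoconia(bcv_accel, x2, p)
    x1 = solve_sdof(f1, p.omega1, p.zeta1)

    if p.r > 0:
        f2 = force_epithelium(bcv_accel, stapes_accel, p, x1=x1)
        x2 = solve_sdof(f2, p.omega2, p.zeta2)
        f1 = force_otoconia(bcv_accel, x2, p)
        x1 = solve_sdof(f1, p.omega1, p.zeta1)

    rel = x1.values - x2.values
    theta = x1.with_values(np.arctan(rel / p.h), "rad")
    theta_dot = _ddt(theta)
    vy = _ddt(x2) * p.gamma
    return MechanicsResult(x1=x1, x2=x2, theta=theta, theta_dot=theta_dot,
                           epithelium_velocity_y=vy)


def natural_frequencies(p: MechParams) -> tuple[float, float]:
    """Damped natural frequencies of the two (decoupled, ``r=0``) modes, Hz.

    Returned ascending.  With the default parameters the lower mode is
    ``520 sqrt(1 - 0.3^2) = 496`` Hz and the upper ``1240 sqrt(1 - 0.9^2)
    = 541`` Hz.
    """
    f1 = p.omega1 * np.sqrt(1 - p.zeta1**2) / (2 * np.pi)
    f2 = p.omega2 * np.sqrt(1 - p.zeta2**2) / (2 * np.pi)
    lo, hi = sorted((float(f1), float(f2)))
    return lo, hi


def _chain_response(p: MechParams, omega: np.ndarray) -> np.ndarray:
    """Complex small-angle shear per unit BCV acceleration, theta(w)/a(w)."""
    s = 1j * omega
    H1 = 1.0 / (p.omega1**2 - omega**2 + 2j * p.zeta1 * p.omega1 * omega)
    H2 = 1.0 / (p.omega2**2 - omega**2 + 2j * p.zeta2 * p.omega2 * omega)
    x2 = -p.beta2 * H2
    f1 = -p.beta1 + (2 * p.zeta1 * p.omega1 * s + p.omega1**2) * x2
    x1 = H1 * f1
    return (x1 - x2) / p.h


def transfer_functions(p: MechParams, freqs) -> tuple[np.ndarray, np.ndarray]:
    """Analytic gains (theta_dot per unit acceleration, per unit jerk).

    For sinusoids, jerk is ``i w`` times acceleration, so the shear rate per
    unit jerk equals the shear per unit acceleration.  The jerk gain is flat
    at low frequency with DC value ``beta1 / (omega1^2 h)``; the acceleration
    gain dominates above the mechanical corner.
    """
    omega = 2 * np.pi * np.asarray(freqs, dtype=float)
    if np.any(omega <= 0):
        raise ValueError("frequencies must be positive")
    theta_per_a = _chain_response(p, omega)
    g_accel = 1j * omega * theta_per_a  # theta_dot per unit acceleration
    g_jerk = theta_per_a  # theta_dot per unit jerk
    return g_accel, g_jerk


def transfer_crossover(p: MechParams, f_lo: float = 10.0, f_hi: float = 5000.0) -> float:
    """Frequency (Hz) where jerk sensitivity hands over to acceleration.

    Operationalized as the peak of the shear-rate-per-unit-acceleration
    magnitude ``|theta_dot / a|``.  Below this frequency that gain rises in
    proportion to frequency — equivalently ``|theta_dot / jerk|`` is flat,
    so a stimulus of given jerk fixes the response; above it the jerk gain
    rolls off and acceleration determines the response.  With the default
    parameters the peak sits between the two damped modes, near 530 Hz,
    corresponding to a half-cycle pulse width of ~0.9 ms.
    """
    f = np.logspace(np.log10(f_lo), np.log10(f_hi), 4000)
    g_a, _ = transfer_functions(p, f)
    mag = np.abs(g_a)
    i = int(np.argmax(mag))
    if i == 0 or i == f.size - 1:
        raise ValueError("no jerk/acceleration crossover in the probed band")
    # parabolic refinement in log-frequency
    lf = np.log(f[i - 1 : i + 2])
    m = mag[i - 1 : i + 2]
    denom = m[0] - 2 * m[1] + m[2]
    shift = 0.0 if denom == 0 else 0.5 * (m[0] - m[2]) / denom
    return float(np.exp(lf[1] + shift * (lf[1] - lf[0])))


def export_result(res: MechanicsResult, path) -> None:
    """Write (t, x1, x2, theta, theta_dot) as delimited text."""
    data = np.column_stack(
        [res.x1.t, res.x1.values, res.x2.values, res.theta.values, res.theta_dot.values]
    )
    np.savetxt(
        path,
        data,
        delimiter=",",
        header="time_s,x1_m,x2_m,theta_rad,theta_dot_rad_s",
        comments="",
        fmt="%.9g",
    )
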