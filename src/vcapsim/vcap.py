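"""Compound action potential synthesis.

The extracellular vCAP is the causal convolution of the population spike
density P(t) with a stereotyped unitary voltage waveform — the field
contribution of a single action potential:

    u(s) = A sin(2 pi s / Te)                       for 0 <= s < Te,
    u(s) = A sin(2 pi s / Te) exp(-(s - Te)/tau_e)  for s >= Te,

one full oscillation period ``Te`` followed by the same oscillation under an
exponential envelope with decay ``tau_e`` (both branches vanish at
``s = Te``, so the kernel is continuous there).  Amplitudes are reported on
a normalized scale by default: only the product of kernel amplitude and
population size is identifiable from recordings, so ``A`` defaults to the
reciprocal of the population maximum and may be recalibrated against a
measured reference peak.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import fftconvolve

from .waveform import Waveform

__all__ = [
    "KernelParams",
    "VcapTrace",
    "NoPeakError",
    "unit_response",
    "synthesize_vcap",
    "vcap_metrics",
]


class NoPeakError(ValueError):
    """Raised when peak metrics are requested on an all-zero trace."""


@dataclass(frozen=True)
class KernelParams:
    """Unitary-response parameters: amplitude scale A (V s), period Te (s),
    decay constant tau_e (s)."""

    A: float = 1.0 / 6000.0  # V*s per unit; A*N = 1 with the default population size
    Te: float = 1e-3
    tau_e: float = 3e-4

    def __post_init__(self) -> None:
        if self.Te <= 0 or self.tau_e <= 0:
            raise ValueError("Te and tau_e must be positive")
        if not np.isfinite(self.A):
            raise ValueError("A must be finite")


@dataclass(frozen=True)
class VcapTrace:
    """Synthesized extracellular voltage with summary metrics."""

    voltage: Waveform
    peak_amplitude: float  # V (absolute value of the dominant extremum)
    latency_to_peak: float  # s from stimulus onset
    peak_polarity: int  # +1 / -1 sign of the dominant extremum


def unit_response(k: KernelParams, grid) -> Waveform:
    """Sample the unitary extracellular waveform on ``grid``.

    ``u(Te/4) = A`` (the pre-decay sine peak); for ``s >= Te`` the sine is
    continued under the exponential envelope, decaying by 1/e per ``tau_e``.
    """
    if grid.dt > k.Te / 50:
        raise ValueError(
            f"dt = {grid.dt} too coarse for kernel period Te = {k.Te}; need dt <= Te/50"
        )
    t = np.asarray(grid.t, dtype=float)
    s = t - t[0]
    sine = np.sin(2 * np.pi * s / k.Te)
    env = np.where(s < k.Te, 1.0, np.exp(-(s - k.Te) / k.tau_e))
    return Waveform(float(t[0]), grid.dt, k.A * sine * env, "V")


def synthesize_vcap(P: Waveform, k: KernelParams, onset: float = 0.0) -> VcapTrace:
    """Convolve the spike density with the unitary kernel (dt-scaled, causal).

    Linear in P; the output grid matches the input grid.
    """
    u = unit_response(k, P)
    v = fftconvolve(P.values, u.values)[: P.n] * P.dt
    voltage = P.with_values(v, "V")
    if np.max(np.abs(v)) == 0.0:
        return VcapTrace(voltage, 0.0, 0.0, 0)
    peak, latency, pol = vcap_metrics(voltage, onset)
    return VcapTrace(voltage, peak, latency, pol)


def vcap_metrics(trace: Waveform | VcapTrace, onset: float = 0.0):
    """Dominant-extremum metrics after ``onset``.

    Returns ``(peak_amplitude, latency_to_peak, polarity)`` where the peak
    is the largest ``|v|`` at or after the stimulus onset and the latency is
    measured from the onset.
    """
    voltage = trace.voltage if isinstance(trace, VcapTrace) else trace
    t = voltage.t
    mask = t >= onset
    v = voltage.values[mask]
    if v.size == 0 or np.max(np.abs(v)) == 0.0:
        raise NoPeakError("trace has no extremum after the stimulus onset")
    mag = np.abs(v)
    vmax = mag.max()
    # first local extremum within 2% of the global one ("first dominant
    # extremum"): the kernel's opposite-sign lobe has the same magnitude, so
    # a bare argmax could report a later lobe on round-off grounds
    d = np.diff(mag)
    local = np.nonzero((np.hstack([d, -1.0]) <= 0) & (np.hstack([1.0, d]) >= 0))[0]
    candidates = local[mag[local] >= 0.98 * vmax]
    i = int(candidates[0]) if candidates.size else int(np.argmax(mag))
    return float(abs(v[i])), float(t[mask][i] - onset), int(np.sign(v[i]))


def export_trace(trace: VcapTrace, path) -> None:
    """Write (t, voltage) delimited text."""
    data = np.column_stack([trace.voltage.t, trace.voltage.values])
    np.savetxt(path, data, delimiter=",", header="time_s,vcap_V", comments="", fmt="%.9g")
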