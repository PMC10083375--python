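"""Uniformly sampled time series with unit bookkeeping.

The :class:`Waveform` is the signal currency of the whole pipeline:
temporal-bone accelerations, stapes velocities, layer displacements,
hair-bundle shear, spike probability densities and extracellular voltage
are all carried on a uniform time grid with an explicit unit tag.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "Waveform",
    "GridError",
    "UnitError",
    "differentiate",
    "integrate",
    "read_waveform",
    "write_waveform",
]

#: Unit produced by one differentiation step, keyed by input unit.
_DERIVATIVE_UNIT = {
    "m": "m/s",
    "m/s": "m/s^2",
    "m/s^2": "m/s^3",
    "rad": "rad/s",
    "rad/s": "rad/s^2",
    "dimensionless": "1/s",
}
_INTEGRAL_UNIT = {v: k for k, v in _DERIVATIVE_UNIT.items()}


class GridError(ValueError):
    """Raised when time grids are non-uniform or incompatible."""


class UnitError(ValueError):
    """Raised when unit bookkeeping fails."""


@dataclass(frozen=True)
class Waveform:
    """A uniformly sampled real-valued signal.

    Parameters
    ----------
    t0 : float
        Time of the first sample (s).
    dt : float
        Sample interval (s), strictly positive.
    values : ndarray
        Ordered samples; at least two, all finite.
    unit : str
        Physical unit tag, e.g. ``"m/s^2"``, ``"rad/s"``, ``"V"``.
    """

    t0: float
    dt: float
    values: np.ndarray = field(repr=False)
    unit: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))
        if not self.dt > 0:
            raise GridError(f"dt must be positive, got {self.dt}")
        if self.values.ndim != 1 or self.values.size < 2:
            raise ValueError("waveform needs at least 2 samples in a 1-d array")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("waveform samples must be finite")

    # -- grid ---------------------------------------------------------------

    @property
    def n(self) -> int:
        return self.values.size

    @property
    def t(self) -> np.ndarray:
        """Sample times (s)."""
        return self.t0 + self.dt * np.arange(self.n)

    @property
    def duration(self) -> float:
        return self.dt * (self.n - 1)

    def same_grid(self, other: "Waveform") -> bool:
        return (
            self.n == other.n
            and abs(self.dt - other.dt) <= 1e-12 * self.dt
            and abs(self.t0 - other.t0) <= 1e-9 * max(self.dt, abs(self.t0) + 1.0)
        )

    def require_grid(self, other: "Waveform") -> None:
        if not self.same_grid(other):
            raise GridError(
                "waveforms are on different grids "
                f"(t0={self.t0}/{other.t0}, dt={self.dt}/{other.dt}, "
                f"n={self.n}/{other.n})"
            )

    # -- arithmetic ---------------------------------------------------------

    def with_values(self, values: np.ndarray, unit: str | None = None) -> "Waveform":
        return replace(self, values=np.asarray(values, float), unit=unit or self.unit)

    def __add__(self, other: "Waveform") -> "Waveform":
        self.require_grid(other)
        if self.unit != other.unit:
            raise UnitError(f"cannot add {self.unit!r} to {other.unit!r}")
        return self.with_values(self.values + other.values)

    def __sub__(self, other: "Waveform") -> "Waveform":
        self.require_grid(other)
        if self.unit != other.unit:
            raise UnitError(f"cannot subtract {other.unit!r} from {self.unit!r}")
        return self.with_values(self.values - other.values)

    def __mul__(self, scalar: float) -> "Waveform":
        return self.with_values(self.values * float(scalar))

    __rmul__ = __mul__

    def __neg__(self) -> "Waveform":
        return self.with_values(-self.values)


def _shift_unit(unit: str, table: dict, op: str) -> str:
    try:
        return table[unit]
    except KeyError:
        raise UnitError(f"do not know how to {op} unit {unit!r}") from None


def differentiate(w: Waveform) -> Waveform:
    """Central-difference time derivative (one-sided at the ends).

    The unit tag advances one time derivative, e.g. ``m/s`` -> ``m/s^2``.
    """
    if w.n < 3:
        raise ValueError("differentiate needs at least 3 samples")
    d = np.gradient(w.values, w.dt)
    return w.with_values(d, _shift_unit(w.unit, _DERIVATIVE_UNIT, "differentiate"))


def integrate(w: Waveform) -> Waveform:
    """Cumulative trapezoidal integral starting from zero at ``t0``."""
    from scipy.integrate import cumulative_trapezoid

    v = cumulative_trapezoid(w.values, dx=w.dt, initial=0.0)
    return w.with_values(v, _shift_unit(w.unit, _INTEGRAL_UNIT, "integrate"))


# -- delimited-text IO ------------------------------------------------------

def write_waveform(w: Waveform, path, quantity: str | None = None) -> None:
    """Write ``time_s,<quantity>`` CSV with 12 significant digits.

    ``#`` comment lines record the unit so that a round trip is lossless.
    """
    name = quantity or w.unit.replace("/", "_per_").replace("^", "")
    header = f"# unit: {w.unit}\ntime_s,{name}"
    data = np.column_stack([w.t, w.values])
    np.savetxt(path, data, delimiter=",", header=header, comments="", fmt="%.12g")


def read_waveform(path, unit: str | None = None, time_column=0, value_column=1) -> Waveform:
    """Read a 2-column delimited text file (comma or tab, ``#`` comments).

    The time column must be strictly increasing and uniform to a relative
    tolerance of 1e-6; otherwise a :class:`GridError` suggests resampling.
    Columns may be named in a header line (e.g. ``time_s,accel_ms2``) and
    selected by name through ``time_column``/``value_column``.
    """
    path = str(path)
    with open(path) as fh:
        lines = fh.readlines()

    file_unit = None
    rows = []
    names: list[str] | None = None
    for line in lines:
        line = line.strip()
        if not line:
            continue
        if line.startswith("#"):
            if "unit:" in line:
                file_unit = line.split("unit:", 1)[1].strip()
            continue
        delim = "," if "," in line else "\t"
        parts = [p.strip() for p in line.split(delim)]
        try:
            rows.append([float(p) for p in parts])
        except ValueError:
            if names is None:
                names = parts
            else:
                raise ValueError(f"unparseable line in {path}: {line!r}")

    if isinstance(time_column, str) or isinstance(value_column, str):
        if names is None:
            raise ValueError("named columns requested but file has no header row")
        time_column = names.index(time_column) if isinstance(time_column, str) else time_column
        value_column = names.index(value_column) if isinstance(value_column, str) else value_column

    data = np.asarray(rows, dtype=float)
    if data.ndim != 2 or data.shape[1] <= max(time_column, value_column):
        raise ValueError(f"{path}: expected at least 2 delimited columns")

    t = data[:, time_column]
    v = data[:, value_column]
    steps = np.diff(t)
    if np.any(steps <= 0):
        raise GridError(f"{path}: time column is not strictly increasing")
    dt = float(np.mean(steps))
    if np.max(np.abs(steps - dt)) > 1e-6 * dt:
        raise GridError(
            f"{path}: non-uniform time grid (jitter exceeds 1e-6 relative); "
            "resample onto a uniform grid before loading"
        )
    return Waveform(t0=float(t[0]), dt=dt, values=v, unit=unit or file_unit or "dimensionless")
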