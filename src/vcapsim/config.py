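"""Run configuration: validated JSON serialization of all parameter sets.

A :class:`RunConfig` bundles the mechanical constants, IAF gains, vCAP
kernel, simulation grid, random seed and output directory.  The shipped
defaults are the guinea-pig parameter set (see the methods note for the
provenance of every value).  Configurations round-trip through JSON
bit-identically; unknown keys are rejected by name.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

from .mechanics import MechParams
from .spikegen import IAFParams
from .stimuli import TimeGrid
from .vcap import KernelParams

__all__ = ["ConfigError", "RunConfig", "default_config", "load_config", "save_config"]


class ConfigError(ValueError):
    """Raised for malformed or out-of-contract configuration documents."""


@dataclass(frozen=True)
class RunConfig:
    mech: MechParams = field(default_factory=MechParams)
    iaf: IAFParams = field(default_factory=IAFParams)
    kernel: KernelParams = field(default_factory=KernelParams)
    grid: TimeGrid = field(default_factory=lambda: TimeGrid(0.0, 0.02, 1e-5))
    seed: int = 0
    output_dir: str = "vcapsim_out"

    def to_dict(self) -> dict:
        return {
            "mech": dataclasses.asdict(self.mech),
            "iaf": dataclasses.asdict(self.iaf),
            "kernel": dataclasses.asdict(self.kernel),
            "grid": dataclasses.asdict(self.grid),
            "seed": self.seed,
            "output_dir": self.output_dir,
        }

    def digest(self) -> str:
        """Stable hash of the configuration (for run manifests)."""
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def default_config() -> RunConfig:
    """The shipped guinea-pig parameter set."""
    return RunConfig()


def _build(cls, payload: dict, section: str):
    if not isinstance(payload, dict):
        raise ConfigError(f"section {section!r} must be a JSON object")
    allowed = {f.name for f in dataclasses.fields(cls)}
    unknown = set(payload) - allowed
    if unknown:
        raise ConfigError(
            f"unknown key(s) {sorted(unknown)} in section {section!r}; "
            f"allowed: {sorted(allowed)}"
        )
    try:
        return cls(**payload)
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"invalid value in section {section!r}: {exc}") from exc


def load_config(path) -> RunConfig:
    """Read and fully validate a JSON configuration file."""
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"config file not found: {path}")
    try:
        doc = json.loads(path.read_text())
    except json.JSONDecodeError as exc:
        raise ConfigError(f"{path}: not valid JSON ({exc})") from exc
    if not isinstance(doc, dict):
        raise ConfigError(f"{path}: top level must be a JSON object")
    known = {"mech", "iaf", "kernel", "grid", "seed", "output_dir"}
    unknown = set(doc) - known
    if unknown:
        raise ConfigError(f"unknown top-level key(s) {sorted(unknown)}; allowed: {sorted(known)}")
    cfg = default_config()
    mech = _build(MechParams, doc.get("mech", {}), "mech")
    iaf = _build(IAFParams, doc.get("iaf", {}), "iaf")
    kernel = _build(KernelParams, doc.get("kernel", {}), "kernel")
    grid = _build(TimeGrid, doc.get("grid", dataclasses.asdict(cfg.grid)), "grid")
    seed = doc.get("seed", cfg.seed)
    if not isinstance(seed, int):
        raise ConfigError(f"'seed' must be an integer, got {seed!r}")
    output_dir = doc.get("output_dir", cfg.output_dir)
    if not isinstance(output_dir, str):
        raise ConfigError(f"'output_dir' must be a string, got {output_dir!r}")
    return RunConfig(mech=mech, iaf=iaf, kernel=kernel, grid=grid, seed=seed,
                     output_dir=output_dir)


def save_config(cfg: RunConfig, path) -> None:
    Path(path).write_text(json.dumps(cfg.to_dict(), indent=2, sort_keys=True) + "\n")
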