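"""Run configuration: a flat YAML key-value document, one config per
scenario run.  Every key has a documented default matching the
illustrative model's standard conditions (200×200 grid, u = 5 m/s,
H = 100 m, E0 = 10 g/s, T = 1000 linear steps)."""

from __future__ import annotations

import dataclasses
import hashlib
from dataclasses import dataclass
from pathlib import Path

import yaml

from .errors import ValidationError

__all__ = ["RunConfig", "load_config", "save_config"]


@dataclass(frozen=True)
class RunConfig:
    """Validated parameters for one scenario run.

    Grid/dispersion keys: ``n, sigma, u, H, k, cell_length,
    normalization``; city shape: ``peak_density``; source/schedule:
    ``x0, y0, E0, n_steps``; scenario: ``scenario, margin``; reporting:
    ``out, report_at``.
    """

    n: int = 200
    sigma: float = 40.0
    u: float = 5.0
    H: float = 100.0
    k: float = 0.0
    cell_length: float = 100.0
    normalization: str = "side"
    peak_density: float = 100.0
    x0: float = 150.0
    y0: float = 100.0
    E0: float = 10.0
    n_steps: int = 1000
    scenario: str = "reduce_E"
    margin: float = 25.0
    out: str | None = None
    report_at: float = 0.5

    def __post_init__(self):
        positive = ("sigma", "u", "H", "cell_length", "peak_density",
                    "E0", "report_at")
        for key in positive:
            if not getattr(self, key) > 0:
                raise ValidationError(f"config key {key!r} must be positive")
        if self.n < 3:
            raise ValidationError("config key 'n' must be at least 3")
        if self.k < 0:
            raise ValidationError("config key 'k' must be nonnegative")
        if self.n_steps < 2:
            raise ValidationError("config key 'n_steps' must be at least 2")
        if not (0 <= self.x0 <= self.n - 1 and 0 <= self.y0 <= self.n - 1):
            raise ValidationError("config keys 'x0'/'y0' must lie inside the grid")
        if self.margin < 0 or self.margin >= self.n / 2:
            raise ValidationError("config key 'margin' must lie in [0, n/2)")
        if self.report_at > 1:
            raise ValidationError("config key 'report_at' must lie in (0, 1]")

    def digest(self) -> str:
        """Stable hash of the configuration, for logging provenance."""
        payload = ",".join(f"{k}={v!r}" for k, v in
                           sorted(dataclasses.asdict(self).items()))
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


_FIELDS = {f.name: f for f in dataclasses.fields(RunConfig)}
_INT_KEYS = {"n", "n_steps"}


def load_config(path: str | Path) -> RunConfig:
    """Read a flat YAML config; unset keys take the documented defaults,
    unknown keys are rejected by name."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"config file {path} does not exist")
    data = yaml.safe_load(path.read_text()) or {}
    if not isinstance(data, dict):
        raise ValidationError("config must be a flat key-value document")
    kwargs = {}
    for key, value in data.items():
        if key not in _FIELDS:
            raise ValidationError(f"unknown config key {key!r}")
        if key in _INT_KEYS:
            if value != int(value):
                raise ValidationError(f"config key {key!r} must be an integer")
            value = int(value)
        kwargs[key] = value
    return RunConfig(**kwargs)


def save_config(config: RunConfig, path: str | Path) -> None:
    Path(path).write_text(
        yaml.safe_dump(dataclasses.asdict(config), sort_keys=True))
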