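"""Run configuration: validated defaults for the CLI, loadable from YAML."""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import yaml

__all__ = ["RunConfig", "load_config"]


@dataclass
class RunConfig:
    """Validated settings shared by the CLI subcommands.

    Unknown keys in a config file are rejected outright: a typo in
    ``bootsrap_b`` should fail loudly, not silently run with defaults.
    """

    dose_col: str = "dose"
    response_col: str = "response"
    replicate_col: Optional[str] = None
    candidates: Optional[list[str]] = None
    bootstrap_b: int = 1000
    alpha: float = 0.10
    seed: int = 0
    outdir: str = "linlogfit_out"
    plot: bool = False
    treatments: Optional[list[float]] = None
    collapse_replicates: bool = False

    def __post_init__(self) -> None:
        if self.bootstrap_b < 50:
            raise ValueError("bootstrap_b must be >= 50")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must be in (0, 1)")
        if self.treatments is not None:
            self.treatments = [float(t) for t in self.treatments]

    def merged(self, **overrides) -> "RunConfig":
        """New config with non-None overrides applied."""
        values = dataclasses.asdict(self)
        values.update({k: v for k, v in overrides.items() if v is not None})
        return RunConfig(**values)


def load_config(path) -> RunConfig:
    """Load a RunConfig from a YAML file, rejecting unknown keys."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise ValueError(f"config {path} must be a mapping")
    known = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(
            f"unknown config key(s) in {path}: {sorted(unknown)}; "
            f"known keys: {sorted(known)}"
        )
    return RunConfig(**raw)
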