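"""Run configuration: defaults, YAML overrides, and a provenance hash."""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .constants import (
    DEFAULT_MATCH_TOLERANCE,
    ION_TRAP_ISOLATION_CEILING,
    PROTON_MASS,
    QUADRUPOLE_ISOLATION_CEILING,
)

__all__ = ["RunConfig", "load_config"]


@dataclass
class RunConfig:
    seed: int = 0
    match_tolerance: float = DEFAULT_MATCH_TOLERANCE
    proton_mass: float = PROTON_MASS
    quadrupole_ceiling: float = QUADRUPOLE_ISOLATION_CEILING
    ion_trap_ceiling: float = ION_TRAP_ISOLATION_CEILING
    scenario: str = "dosed_2h"
    phantom_width: int = 16
    phantom_height: int = 16
    reaction_extent: float = 0.5
    max_reductions: int = 2
    mz_range: tuple[float, float] = (1500.0, 3000.0)
    complex_scales: dict = field(
        default_factory=lambda: {"control": 0.0, "dosed_2h": 1.0, "dosed_6h": 0.3}
    )
    output_dir: str = "tptcr_output"

    def __post_init__(self) -> None:
        if self.match_tolerance <= 0:
            raise ValueError("match_tolerance must be positive")

    def hash(self) -> str:
        """Short stable hash of the scientific configuration (output paths
        excluded), for output provenance."""
        d = asdict(self)
        d.pop("output_dir", None)
        blob = json.dumps(d, sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]

    def provenance_header(self) -> str:
        return f"config_hash: {self.hash()}\nseed: {self.seed}"


def load_config(path: str | Path | None, **overrides) -> RunConfig:
    """Build a RunConfig: defaults < YAML file < explicit overrides."""
    data: dict = {}
    if path is not None:
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
    data.update({k: v for k, v in overrides.items() if v is not None})
    if "mz_range" in data:
        data["mz_range"] = tuple(data["mz_range"])
    try:
        return RunConfig(**data)
    except TypeError as exc:
        raise ValueError(f"invalid configuration: {exc}") from exc
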