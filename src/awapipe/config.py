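"""Pipeline configuration: the printed analysis constants in one place.

Defaults mirror the analysis parameters of the study design: fourfold DE
cutoff, 5% reporter tails, 10-frame moving median, 5th-percentile baseline,
0.5 mm distance bins, 3.5 mm exploration grid. Unknown keys in a config file
are errors (fail-fast) so defaults cannot drift silently.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field

import yaml

SCHEMA_VERSION = 1


@dataclass
class PipelineConfig:
    schema_version: int = SCHEMA_VERSION
    seed: int = 0
    # enrichment
    de_threshold: float = 4.0
    de_pseudocount: float = 0.5
    atlas_alpha: float = 0.05
    # reporter
    reporter_tail_percent: float = 5.0
    control_group: str = "fed_WT"
    roi_halfwidth: int = 10
    # calcium
    median_window: int = 10
    baseline_percentile: float = 5.0
    bin_width_mm: float = 0.5
    peak_min_amplitude: float = 0.2
    peak_min_separation_s: float = 2.0
    epoch_pre: tuple = (0.0, 4.9)
    epoch_stim: tuple = (5.0, 15.0)
    epoch_post: tuple = (15.1, 29.9)
    f0_window: tuple = (2.0, 3.0)
    # behavior
    grid_square_mm: float = 3.5
    plate_diameter_mm: float = 60.0

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return {k: (list(v) if isinstance(v, tuple) else v) for k, v in d.items()}

    @property
    def hash(self) -> str:
        """Stable short hash of the canonical JSON form of the config."""
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if int(d.get("schema_version", SCHEMA_VERSION)) != SCHEMA_VERSION:
            raise ValueError("unsupported config schema_version")
        tuple_fields = {f.name for f in dataclasses.fields(cls)
                        if isinstance(f.default, tuple)}
        kwargs = {k: tuple(v) if k in tuple_fields and isinstance(v, list) else v
                  for k, v in d.items()}
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ValueError("config file must contain a mapping")
        return cls.from_dict(data)
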