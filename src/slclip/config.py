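"""Flat pipeline configuration: every numeric rule of the analysis lives
here with its default, so it is discoverable and overridable in one place.
Round-trips through YAML unchanged."""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .synthetic_data import SimConfig


@dataclass
class PipelineConfig:
    seed: int = 0
    sim: SimConfig = field(default_factory=SimConfig)
    # SL detection
    match: int = 1
    mismatch: int = -1
    gap_open: int = -2
    gap_extend: int = -2
    window_len: int = 100            # upstream window searched for SLs
    min_truncated_len: int = 7       # trimming stops below this SL length
    confident_score: int = 9         # confident iff score > 9 ...
    confident_offset: int = 2        # ... or end offset <= 2
    sl1_primed: bool = False
    # hairpin detection
    hairpin_window: int = 30
    hairpin_min_matched: int = 12    # of the 15-nt (-13..+2) probe
    # gene summaries
    min_discriminable: int = 10
    sl2_favored: float = 0.60
    sl1_favored: float = 0.40
    min_reads_gene: int = 20
    sl_majority: float = 0.5
    low_sl_min_reads: int = 100
    low_sl_max_frac: float = 0.10
    # metrics
    profile_range: tuple[int, int] = (-600, 600)
    profile_sample_n: int = 50_000

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["sim"] = dataclasses.asdict(self.sim)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        sim = d.pop("sim", {})
        if isinstance(sim, dict):
            for key in ("isolated_gap_range", "copy_len_range", "tx_len_range"):
                if key in sim and sim[key] is not None:
                    sim[key] = tuple(sim[key])
            sim = SimConfig(**sim)
        if "profile_range" in d and d["profile_range"] is not None:
            d["profile_range"] = tuple(d["profile_range"])
        return cls(sim=sim, **d)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))
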