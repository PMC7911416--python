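"""Pipeline configuration: a flat key:value text format that round-trips
losslessly, plus a stable hash embedded in every output header."""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, fields

from .calling import ClassificationThresholds


@dataclass
class PipelineConfig:
    bin_size: int = 20_000
    dup_min: float = 2.8
    del_max: float = 1.2
    disomy_low: float = 1.8
    disomy_high: float = 2.2
    smooth_window: int = 5
    min_segment_bins: int = 5
    gap_bins: int = 2
    seg_min_z: float = 4.0
    gc_correction: bool = True
    gc_mask_low: float = 0.28
    gc_mask_high: float = 0.60
    mcc_threshold: float = 5.0
    min_median_depth: float = 5.0
    seed: int = 0

    def thresholds(self) -> ClassificationThresholds:
        return ClassificationThresholds(
            dup_min=self.dup_min,
            del_max=self.del_max,
            disomy_low=self.disomy_low,
            disomy_high=self.disomy_high,
        )

    def to_text(self) -> str:
        lines = []
        for f in fields(self):
            v = getattr(self, f.name)
            lines.append(f"{f.name}: {v}")
        return "\n".join(lines) + "\n"

    @classmethod
    def from_text(cls, text: str) -> "PipelineConfig":
        types = {f.name: f.type for f in fields(cls)}
        kwargs = {}
        for line in text.splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            key, _, raw = line.partition(":")
            key, raw = key.strip(), raw.strip()
            if key not in types:
                raise ValueError(f"unknown config key {key!r}")
            t = types[key]
            if t == "bool":
                kwargs[key] = raw.lower() in ("true", "1", "yes", "on")
            elif t == "int":
                kwargs[key] = int(raw)
            else:
                kwargs[key] = float(raw)
        return cls(**kwargs)

    def sha1(self) -> str:
        return hashlib.sha1(self.to_text().encode()).hexdigest()[:12]

    def header_lines(self, version: str) -> list[str]:
        return [f"bincnv v{version}", f"config_sha1={self.sha1()}"]
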