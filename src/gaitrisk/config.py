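"""Flat key-value pipeline configuration with lossless file round-trip.

The config file is deliberately simple — one ``key = value`` pair per
line, ``#`` comments, a schema version — so that a run is reproducible
bit-for-bit from (config file, seed, input files) alone.  Unknown keys
are rejected rather than ignored.
"""

from __future__ import annotations

import hashlib
from dataclasses import asdict, dataclass, fields
from pathlib import Path

from .errors import FormatError, ParameterError

SCHEMA_VERSION = 1


@dataclass
class PipelineConfig:
    """Every tunable constant of the end-to-end pipeline."""

    schema_version: int = SCHEMA_VERSION
    sample_rate: float = 50.0  # Hz, uniform grid after resampling
    filter_order: int = 4
    filter_cutoff: float = 4.0  # Hz
    lock_clamp_low: int = 10  # frames
    lock_clamp_high: int = 35  # frames
    gap_factor: float = 1.5  # missed-step gap threshold vs previous step
    tolerance_frames: int = 2  # strike-matching tolerance
    turn_threshold: float = 45.0  # deg/s mean |rotation rate|
    exclude_turns: bool = True
    spectral_nfft: int = 256
    cfs_variant: str = "pearson"
    cfs_patience: int = 5
    n_trees: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sample_rate <= 0 or self.filter_cutoff <= 0 or self.filter_order < 1:
            raise ParameterError("invalid preprocessing settings")
        if not 0 < self.lock_clamp_low <= self.lock_clamp_high:
            raise ParameterError("locking clamp bounds must satisfy 0 < low <= high")
        if self.gap_factor <= 1.0:
            raise ParameterError("gap factor must exceed 1")
        if self.cfs_variant not in ("pearson",):
            raise ParameterError(f"unknown CFS variant {self.cfs_variant!r}")
        if self.n_trees < 1 or self.tolerance_frames < 0:
            raise ParameterError("invalid classifier settings")

    def to_text(self) -> str:
        lines = [f"{f.name} = {getattr(self, f.name)}" for f in fields(self)]
        return "\n".join(lines) + "\n"

    def save(self, path: str | Path) -> None:
        Path(path).write_text(self.to_text())

    @classmethod
    def load(cls, path: str | Path) -> "PipelineConfig":
        return cls.from_text(Path(path).read_text())

    @classmethod
    def from_text(cls, text: str) -> "PipelineConfig":
        field_types = {f.name: f.type for f in fields(cls)}
        kwargs: dict = {}
        for lineno, raw in enumerate(text.splitlines(), start=1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise FormatError(f"config line {lineno}: expected 'key = value'")
            key, value = (part.strip() for part in line.split("=", 1))
            if key not in field_types:
                raise FormatError(f"config line {lineno}: unknown key {key!r}")
            kwargs[key] = _parse(value, field_types[key])
        cfg = cls(**kwargs)
        if cfg.schema_version != SCHEMA_VERSION:
            raise FormatError(
                f"unsupported config schema version {cfg.schema_version}"
            )
        return cfg

    def digest(self) -> str:
        return hashlib.sha256(self.to_text().encode()).hexdigest()[:16]

    def as_dict(self) -> dict:
        return asdict(self)


def _parse(value: str, annotation: str | type):
    name = annotation if isinstance(annotation, str) else annotation.__name__
    if name == "bool":
        if value in ("True", "true", "1"):
            return True
        if value in ("False", "false", "0"):
            return False
        raise FormatError(f"expected a boolean, got {value!r}")
    if name == "int":
        return int(value)
    if name == "float":
        return float(value)
    return value
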