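"""Run configuration for the end-to-end pipeline.

Every analysis decision that the underlying methods leave open (class
precedence, RPM denominator, ordination axis, cluster count, exclusion
rules) is surfaced as an explicit config key with its documented
default, so a run is fully described by its config plus a seed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .annotate import DEFAULT_PRECEDENCE
from .simulate import DEFAULT_DEPTH, SCENARIOS


class ConfigError(ValueError):
    pass


@dataclass
class RunConfig:
    scenario: str = "mouse_5group"
    seed: int = 0
    depth: int = DEFAULT_DEPTH
    outdir: str = "sncaging_run"
    # feature granularity for the ordination: 'family' or 'species'
    granularity: str = "family"
    alpha: float = 0.05
    axis: int = 1  # ordination axis fed to the stage F-statistic
    k_clusters: int = 5
    # generative model knobs (study-condition defaults)
    beta: float = 0.004
    cliff_scale: float = 1.3862943611198906  # ln 4
    cliff_cutoff: float = 60.0
    mt_factor_sd: float = 1.4
    noise_sd: float = 0.25
    bin_noise_sd: float = 0.15
    # annotation decisions
    precedence: list[str] = field(
        default_factory=lambda: list(DEFAULT_PRECEDENCE))
    max_mismatch: int = 1
    rpm_denominator: str = "clean"  # 'clean' or 'annotated'
    # run the full read-level annotator (slower) instead of truth counts
    use_annotator: bool = True
    figures: bool = True
    read_format: str = "fasta"

    def validate(self) -> "RunConfig":
        if self.scenario not in SCENARIOS:
            raise ConfigError(f"unknown scenario {self.scenario!r}")
        if self.granularity not in ("family", "species"):
            raise ConfigError(f"unknown granularity {self.granularity!r}")
        if self.rpm_denominator not in ("clean", "annotated"):
            raise ConfigError(f"bad rpm_denominator {self.rpm_denominator!r}")
        if not 0 < self.alpha < 1:
            raise ConfigError("alpha must be in (0, 1)")
        if self.axis < 1:
            raise ConfigError("axis must be >= 1")
        if self.k_clusters < 2:
            raise ConfigError("k_clusters must be >= 2")
        if self.max_mismatch not in (0, 1):
            raise ConfigError("max_mismatch must be 0 or 1")
        return self

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True)
        return hashlib.sha1(payload.encode()).hexdigest()[:12]

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data).validate()
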