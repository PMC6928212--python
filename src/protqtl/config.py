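"""Run configuration: one flat, defaulted, YAML-round-trippable record."""

from __future__ import annotations

import hashlib
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import yaml

__all__ = ["RunConfig"]


@dataclass
class RunConfig:
    """Every pipeline parameter with its default.

    The config round-trips losslessly through YAML; ``digest()`` is a stable
    hash of the parameter values that is stamped into every output file.
    """

    # stage selection and global seed
    stages: list[str] = field(default_factory=lambda: ["simulate", "scan", "bsa", "retain"])
    seed: int = 1

    # simulated map
    n_chrom: int = 20
    n_markers_per_chrom: int = 13
    chrom_length_cm: float = 120.0

    # RIL population and phenotypes
    ril_n_lines: int = 100
    derived_generation: int = 5
    n_trials: int = 3
    total_variance_fraction: float = 0.70

    # genome scan
    scan_mode: str = "SIM"
    step_cm: float = 1.0
    n_permutations: int = 1000
    alpha: float = 0.05
    window_cm: float = 20.0

    # bulked-segregant analysis
    bsa_n_populations: int = 4
    tail_fraction: float = 0.1
    min_bulk: int = 8
    delta_threshold: float = 0.4
    bsa_alpha: float = 0.05
    fixed_threshold: float = 0.95
    merge_window_cm: float = 10.0

    # retention scan
    panel_n_lines: int = 300
    snp_density: int = 500
    n_retained_blocks: int = 4
    snps_per_block: int = 8
    n_scattered_rare: int = 40
    rare_frequency: float = 1 / 300
    retention_probability_outside: float = 0.125
    n_derivatives: int = 7
    max_panel_frequency: float = 0.02
    min_ratio: float = 0.66
    min_informative: int = 4
    max_gap_bp: int = 500_000
    min_snps: int = 2

    def __post_init__(self) -> None:
        known = {"simulate", "scan", "bsa", "retain"}
        bad = set(self.stages) - known
        if bad:
            raise ValueError(f"unknown stage(s): {sorted(bad)}")

    # -- round-trip -------------------------------------------------------
    def to_yaml(self, path=None) -> str:
        text = yaml.safe_dump(asdict(self), sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_yaml(cls, source) -> "RunConfig":
        p = Path(str(source))
        text = p.read_text() if p.exists() else str(source)
        data = yaml.safe_load(text) or {}
        valid = {f.name for f in fields(cls)}
        unknown = set(data) - valid
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**data)

    def digest(self) -> str:
        return hashlib.sha256(self.to_yaml().encode()).hexdigest()[:16]
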