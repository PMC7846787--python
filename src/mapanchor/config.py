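"""Pipeline configuration: every numeric threshold used by the stages."""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path

import yaml


class ConfigError(ValueError):
    """Raised when a configuration value violates an invariant."""


@dataclass
class PipelineConfig:
    """All tunable thresholds of the anchoring pipeline.

    Defaults follow common practice for GBS-based RIL maps: Phred-30 genotype
    quality, MAF 0.3 / het 0.05 / 100-individual variant filters, a
    2-state imputation HMM with per-marker switch probability 0.003,
    an LD threshold of r^2 > 0.8 for contig linkage, centimorgans from
    breakpoint counts assuming five generations of crossover, a 1 Mbp /
    200 kbp Marey sliding window, and a 2 Mbp/cM pericentromere rule.
    """

    min_genotype_quality: int = 30
    min_maf: float = 0.3
    max_het_rate: float = 0.05
    min_genotyped_individuals: int = 100
    hmm_switch_prob: float = 0.003
    hmm_states: int = 2
    hmm_error_rate: float = 0.01
    hmm_het_emission: float = 0.05
    r2_threshold: float = 0.8
    min_ld_pairs: int = 3
    ld_pair_cap: int = 200
    generations_of_crossover: float = 5
    crossovers_per_chr_per_gen: float = 1.0
    end_window_bp: int = 20_000
    min_shared_barcodes: int = 5
    max_end_occurrences: int = 4
    misassembly_scan_step_bp: int = 10_000
    misassembly_max_span_barcodes: int = 5
    conflict_minority_share: float = 0.2
    marey_window_bp: int = 1_000_000
    marey_step_bp: int = 200_000
    pericentromere_mbp_per_cm: float = 2.0
    agp_gap_bp: int = 100
    seed: int = 0

    _FRACTIONS = (
        "min_maf",
        "max_het_rate",
        "hmm_switch_prob",
        "hmm_error_rate",
        "hmm_het_emission",
        "r2_threshold",
        "conflict_minority_share",
    )
    _POSITIVE_INTS = (
        "min_genotyped_individuals",
        "min_ld_pairs",
        "ld_pair_cap",
        "end_window_bp",
        "min_shared_barcodes",
        "max_end_occurrences",
        "misassembly_scan_step_bp",
        "misassembly_max_span_barcodes",
        "marey_window_bp",
        "marey_step_bp",
        "agp_gap_bp",
        "hmm_states",
    )

    def __post_init__(self) -> None:
        for name in self._FRACTIONS:
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name} must lie in [0, 1], got {v!r}")
        for name in self._POSITIVE_INTS:
            v = getattr(self, name)
            if not (isinstance(v, int) and v > 0):
                raise ConfigError(f"{name} must be a positive integer, got {v!r}")
        if self.min_genotype_quality < 0:
            raise ConfigError("min_genotype_quality must be non-negative")
        if self.generations_of_crossover <= 0:
            raise ConfigError("generations_of_crossover must be positive")
        if self.crossovers_per_chr_per_gen <= 0:
            raise ConfigError("crossovers_per_chr_per_gen must be positive")
        if self.pericentromere_mbp_per_cm <= 0:
            raise ConfigError("pericentromere_mbp_per_cm must be positive")
        if self.marey_step_bp > self.marey_window_bp:
            raise ConfigError(
                "marey_step_bp must not exceed marey_window_bp "
                f"({self.marey_step_bp} > {self.marey_window_bp})"
            )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        """Load a configuration from a YAML mapping; absent keys keep defaults."""
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ConfigError(f"config file {path} must contain a mapping")
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=False)

    def replace(self, **kwargs) -> "PipelineConfig":
        return dataclasses.replace(self, **kwargs)
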