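"""Pipeline configuration.

Every threshold the pipeline applies lives in one dataclass so a run is fully
described by a single YAML file plus the input paths.  Defaults are the
conventional values for exploratory protein similarity networks: an e-value
cutoff of 1e-5, a 30 % coverage-rescaled identity floor, a mutual-coverage
floor of 80 % of both sequences, a per-domain conductance cutoff of 0.4 for
nucleus families, and a 60 % closest-published-relative identity cutoff below
which an environmental sequence counts as highly divergent.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import yaml


@dataclass
class PipelineConfig:
    max_evalue: float = 1e-5
    min_adjusted_identity: float = 30.0      # percent, inclusive bound
    min_mutual_coverage: float = 0.80        # fraction of BOTH sequences
    conductance_threshold: float = 0.4       # strict upper bound, per domain
    conductance_domains: tuple[str, ...] = ("Archaea", "Bacteria")
    cpr_divergence_cutoff: float = 60.0      # percent; CPR below this = divergent
    recruitment_rounds: int = 2
    recruit_hit_cap: int = 500               # hits kept per seed per round
    all_vs_all_hit_cap: int = 5000           # hits kept per query, network build
    min_clique_size: int = 3
    min_block_len: int = 10                  # conserved-block filter
    conserved_fraction: float = 0.5          # majority fraction for "conserved"
    max_gap_fraction: float = 0.0            # per retained column
    min_align_score: float = 40.0            # built-in aligner floor (raw score)
    include_no_cpr_in_divergent: bool = False
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.min_adjusted_identity <= 100:
            raise ValueError("min_adjusted_identity must be in (0, 100]")
        if not 0 < self.min_mutual_coverage <= 1:
            raise ValueError("min_mutual_coverage must be in (0, 1]")
        if self.max_evalue <= 0:
            raise ValueError("max_evalue must be positive")
        if self.conductance_threshold < 0:
            raise ValueError("conductance_threshold must be non-negative")
        if not 0 < self.cpr_divergence_cutoff <= 100:
            raise ValueError("cpr_divergence_cutoff must be in (0, 100]")
        if self.recruitment_rounds < 1:
            raise ValueError("recruitment_rounds must be >= 1")
        if self.min_clique_size < 2:
            raise ValueError("min_clique_size must be >= 2")
        self.conductance_domains = tuple(self.conductance_domains)

    def with_updates(self, **kwargs) -> "PipelineConfig":
        return replace(self, **kwargs)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["conductance_domains"] = list(self.conductance_domains)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(data)
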