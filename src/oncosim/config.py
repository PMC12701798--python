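"""Run configuration: schema, defaults, validation, YAML round-trip.

No input files are required — a run is fully specified by model choices and
parameters plus one integer seed.  Every field has a documented default;
unknown keys are rejected so typos cannot silently fall back to defaults.
"""

from __future__ import annotations

import math
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import yaml

from .genome import ConfigurationError

__all__ = ["RunConfig", "load_config", "save_config"]


def _from_mapping(cls, data: dict, section: str):
    known = {f.name for f in fields(cls)}
    unknown = set(data) - known
    if unknown:
        raise ConfigurationError(
            f"unknown keys in [{section}]: {', '.join(sorted(unknown))}"
        )
    return cls(**data)


@dataclass
class GenomeSection:
    n_chromosomes: int = 10
    regions_per_arm: int = 5
    region_length: int = 1_000_000
    frac_og: float = 0.1
    frac_tsg: float = 0.1
    frac_essential: float = 0.05


@dataclass
class SelectionSection:
    model: str = "arm"  # region | arm | hybrid
    s_max: float = 0.1
    divergence: float = 0.2
    snv_essential_penalty: float = 0.95


@dataclass
class GrowthSection:
    growth_rate: float = 0.4
    carrying_capacity: float = 100_000.0
    turnover_rate: float = 1.0


@dataclass
class MigrationSection:
    n_sites: int = 3
    model: str = "static"  # static | genotype
    p_base: float = 1e-5
    d_max: float = 10.0
    genotype_floor: float = 0.1
    distance_matrix: list | None = None  # optional explicit matrix


@dataclass
class RatesSection:
    snv: float = 2e-3
    segmental: float = 1e-3
    arm_misseg: float = 5e-4
    chrom_misseg: float = 5e-4
    wgd: float = 1e-4
    segment_mean_length: float = 5.0


@dataclass
class PassengerSection:
    snv: float = 0.02
    segmental: float = 0.002
    segment_mean_length: float = 5.0


@dataclass
class ViabilitySection:
    max_mean_cn: float = 8.0
    max_region_cn: int = 10
    max_wgd: int = 2


@dataclass
class EngineSection:
    n_min_detectable: int = 50_000
    max_generations: int = 5_000
    max_restart_attempts: int = 50


@dataclass
class SamplingSection:
    n_per_site: int = 50


@dataclass
class CoverageSection:
    mode: str = "single_cell"  # single_cell | bulk
    mean_reads_per_cell: float = 500_000.0
    total_depth: float = 5_000_000.0
    sigma_bias: float = 0.2
    overdispersion: float | None = None  # None => Poisson
    normal_fraction: float = 0.0

    @property
    def overdispersion_value(self) -> float:
        return math.inf if self.overdispersion is None else self.overdispersion


_SECTIONS = {
    "genome": GenomeSection,
    "selection": SelectionSection,
    "growth": GrowthSection,
    "migration": MigrationSection,
    "rates": RatesSection,
    "passengers": PassengerSection,
    "viability": ViabilitySection,
    "engine": EngineSection,
    "sampling": SamplingSection,
    "coverage": CoverageSection,
}


@dataclass
class RunConfig:
    genome: GenomeSection = field(default_factory=GenomeSection)
    selection: SelectionSection = field(default_factory=SelectionSection)
    growth: GrowthSection = field(default_factory=GrowthSection)
    migration: MigrationSection = field(default_factory=MigrationSection)
    rates: RatesSection = field(default_factory=RatesSection)
    passengers: PassengerSection = field(default_factory=PassengerSection)
    viability: ViabilitySection = field(default_factory=ViabilitySection)
    engine: EngineSection = field(default_factory=EngineSection)
    sampling: SamplingSection = field(default_factory=SamplingSection)
    coverage: CoverageSection = field(default_factory=CoverageSection)
    seed: int = 0
    outdir: str = "oncosim_out"
    reference: str | None = None
    read_simulator: str | None = None

    def validate(self) -> "RunConfig":
        if self.sampling.n_per_site > self.engine.n_min_detectable:
            raise ConfigurationError(
                "sampling.n_per_site exceeds engine.n_min_detectable: "
                "cannot sample more cells than a site is guaranteed to hold"
            )
        if self.selection.model not in ("region", "arm", "hybrid"):
            raise ConfigurationError(
                f"selection.model must be region/arm/hybrid, "
                f"got {self.selection.model!r}"
            )
        if self.migration.n_sites < 1:
            raise ConfigurationError("migration.n_sites must be >= 1")
        if not 0 <= self.migration.p_base <= 1:
            raise ConfigurationError("migration.p_base must lie in [0, 1]")
        return self

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        data = dict(data or {})
        top_known = {f.name for f in fields(cls)}
        unknown = set(data) - top_known
        if unknown:
            raise ConfigurationError(
                f"unknown top-level keys: {', '.join(sorted(unknown))}"
            )
        kwargs = {}
        for name, section_cls in _SECTIONS.items():
            if name in data:
                kwargs[name] = _from_mapping(section_cls, data.pop(name) or {}, name)
        kwargs.update(data)
        return cls(**kwargs).validate()


def load_config(path: str | Path | None = None) -> RunConfig:
    """Load a YAML config (or the full defaults when no path is given)."""
    if path is None:
        return RunConfig().validate()
    raw = yaml.safe_load(Path(path).read_text())
    return RunConfig.from_dict(raw or {})


def save_config(cfg: RunConfig, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(cfg.to_dict(), sort_keys=True))
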