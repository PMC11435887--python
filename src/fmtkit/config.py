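"""Pipeline configuration: YAML in, validated dataclasses out.

Every stage parameter defaults to the value the analysis protocol states
(prevalence cutoff 30%, winsorization quantile 0.97, low-count filter
min_count 4 / prevalence 20%, IQR bottom-10% variance filter, "Other"
thresholds 1% at genus and 1.4% at species level). Unknown keys are
rejected with their full path so typos never silently fall back to
defaults.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .synthetic import TrialSimConfig


class ConfigError(ValueError):
    pass


@dataclass
class InputPaths:
    feature_table: str = ""
    taxonomy: str = ""
    metadata: str = ""
    ccecai: str = ""
    fcs_diary: str = ""
    fdm: str = ""
    disposition: str = ""

    @classmethod
    def from_dir(cls, directory) -> "InputPaths":
        d = Path(directory)
        return cls(
            feature_table=str(d / "feature_table.tsv"),
            taxonomy=str(d / "taxonomy.tsv"),
            metadata=str(d / "metadata.tsv"),
            ccecai=str(d / "ccecai.csv"),
            fcs_diary=str(d / "fcs_diary.csv"),
            fdm=str(d / "fdm.csv"),
            disposition=str(d / "disposition.csv"),
        )


@dataclass
class FeatureTableParams:
    rare_max_total: int = 2
    min_count: int = 4
    min_prevalence: float = 0.20
    low_variance_drop: float = 0.10
    aggregate_rank: str = "genus"
    other_threshold_genus: float = 0.01
    other_threshold_species: float = 0.014
    # processing order for the diversity/DA branch; rare-ASV removal always
    # runs first (the engraftment branch consumes its output directly)
    order: list[str] = field(
        default_factory=lambda: ["low_count", "aggregate", "low_variance", "scale"]
    )


@dataclass
class DiversityParams:
    n_permutations: int = 999
    log_base: float | None = None  # natural log
    adjust_pairwise: bool = False


@dataclass
class DaParams:
    prevalence_cutoff: float = 0.30
    winsor_quantile: float = 0.97
    pseudocount: float = 0.5


@dataclass
class EngraftmentParams:
    baseline_visit_overrides: dict = field(default_factory=dict)  # dog_id -> visit


@dataclass
class ClinicalParams:
    fdm_convention: str = "dry_over_wet"
    fcs_window_days: int = 3


ALL_STAGES = ("composition", "diversity", "differential_abundance", "engraftment", "clinical")


@dataclass
class PipelineConfig:
    seed: int = 0
    inputs: InputPaths | None = None
    simulate: TrialSimConfig | None = None
    stages: list[str] = field(default_factory=lambda: list(ALL_STAGES))
    feature_table: FeatureTableParams = field(default_factory=FeatureTableParams)
    diversity: DiversityParams = field(default_factory=DiversityParams)
    differential_abundance: DaParams = field(default_factory=DaParams)
    engraftment: EngraftmentParams = field(default_factory=EngraftmentParams)
    clinical: ClinicalParams = field(default_factory=ClinicalParams)

    def __post_init__(self) -> None:
        if (self.inputs is None) == (self.simulate is None):
            raise ConfigError("exactly one of 'inputs' and 'simulate' must be given")
        unknown = set(self.stages) - set(ALL_STAGES)
        if unknown:
            raise ConfigError(f"unknown stage(s): {sorted(unknown)}; valid: {list(ALL_STAGES)}")

    def echo(self) -> dict:
        """Effective parameters, fully expanded, for the run report."""
        return dataclasses.asdict(self)


_SECTION_TYPES = {
    "inputs": InputPaths,
    "simulate": TrialSimConfig,
    "feature_table": FeatureTableParams,
    "diversity": DiversityParams,
    "differential_abundance": DaParams,
    "engraftment": EngraftmentParams,
    "clinical": ClinicalParams,
}


def _build_section(cls, data: dict, path: str):
    valid = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - valid
    if unknown:
        raise ConfigError(f"unknown key(s) under '{path}': {sorted(unknown)}")
    return cls(**data)


def load_config(path) -> PipelineConfig:
    """Load and validate a YAML pipeline config; defaults fill every
    omitted key and unknown keys are rejected with their path."""
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise ConfigError(f"{path}: top level must be a mapping")
    return config_from_dict(data)


def config_from_dict(data: dict) -> PipelineConfig:
    top_valid = {f.name for f in dataclasses.fields(PipelineConfig)}
    unknown = set(data) - top_valid
    if unknown:
        raise ConfigError(f"unknown top-level key(s): {sorted(unknown)}")
    kwargs = {}
    for key, value in data.items():
        if key in _SECTION_TYPES:
            if not isinstance(value, dict):
                raise ConfigError(f"'{key}' must be a mapping")
            kwargs[key] = _build_section(_SECTION_TYPES[key], value, key)
        else:
            kwargs[key] = value
    return PipelineConfig(**kwargs)
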