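"""Run configuration: defaults, validation, YAML round-tripping.

A :class:`RunConfig` carries everything needed to reproduce a simulation:
geometry, initial composition, model variant and its target composition,
activity settings, and execution parameters.  Defaults follow the model's
standard conditions — a 300 px endplate tiled by 100 sites of 30 px, nine
axons, newborn (P0) initial composition, a P3 stationary target with
P_VS = 0.6, selection divisor 2, and 100 replicates.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import yaml

from .geometry import (
    DEFAULT_MIN_SEPARATION_FACTOR,
    DEFAULT_N_AXONS,
    DEFAULT_NEIGHBOR_FACTOR,
    DEFAULT_REGION_DIAMETER,
    DEFAULT_SITE_DIAMETER,
    AreaRatios,
    EndplateLayout,
    apportion_site_counts,
    place_sites,
)
from .markov import DEFAULT_P_VS, VacancyMediatedProbs, solve_stationary_probabilities

__all__ = [
    "GeometryConfig",
    "CompositionConfig",
    "ModelConfig",
    "ActivitySettings",
    "ExecutionConfig",
    "RunConfig",
    "build_layout",
    "resolve_probs",
    "stage_config",
]


@dataclass(frozen=True)
class GeometryConfig:
    region_diameter: float = DEFAULT_REGION_DIAMETER
    site_diameter: float = DEFAULT_SITE_DIAMETER
    n_sites: int = 100
    min_separation_factor: float = DEFAULT_MIN_SEPARATION_FACTOR
    neighbor_distance: float | None = None  # default: 1.25 x site_diameter

    def resolved_neighbor_distance(self) -> float:
        if self.neighbor_distance is not None:
            return self.neighbor_distance
        return DEFAULT_NEIGHBOR_FACTOR * self.site_diameter


@dataclass(frozen=True)
class CompositionConfig:
    #: Initial (tSC, vacancy, axon) composition; default is the newborn (P0)
    #: measurement 31/17/52.
    initial_ratios: tuple[float, float, float] = (0.31, 0.17, 0.52)
    n_axons: int = DEFAULT_N_AXONS


@dataclass(frozen=True)
class ModelConfig:
    #: One of "vacancy_mediated", "random", "equal".
    variant: str = "vacancy_mediated"
    #: Stationary target composition; default is the P3 measurement 57/18/25.
    target_ratios: tuple[float, float, float] = (0.57, 0.18, 0.25)
    p_vs: float = DEFAULT_P_VS


@dataclass(frozen=True)
class ActivitySettings:
    #: Number of active axons, redrawn uniformly per replicate; or an
    #: explicit fixed set of ids (overrides n_active when non-empty).
    n_active: int = 0
    active_axon_ids: tuple[int, ...] = ()
    selection_divisor: float = 2.0


@dataclass(frozen=True)
class ExecutionConfig:
    max_iter: int = 50_000
    n_reps: int = 100
    base_seed: int = 0
    series_stride: int = 0  # 0 disables series recording in the CLI
    record_events: bool = False


@dataclass(frozen=True)
class RunConfig:
    geometry: GeometryConfig = field(default_factory=GeometryConfig)
    composition: CompositionConfig = field(default_factory=CompositionConfig)
    model: ModelConfig = field(default_factory=ModelConfig)
    activity: ActivitySettings = field(default_factory=ActivitySettings)
    execution: ExecutionConfig = field(default_factory=ExecutionConfig)

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        def build(section_cls, key):
            section = dict(data.get(key) or {})
            known = {f for f in section_cls.__dataclass_fields__}
            unknown = set(section) - known
            if unknown:
                raise ValueError(f"unknown {key} config keys: {sorted(unknown)}")
            for tuple_field in ("initial_ratios", "target_ratios", "active_axon_ids"):
                if tuple_field in section and section[tuple_field] is not None:
                    section[tuple_field] = tuple(section[tuple_field])
            return section_cls(**section)

        unknown = set(data) - {
            "geometry",
            "composition",
            "model",
            "activity",
            "execution",
        }
        if unknown:
            raise ValueError(f"unknown config sections: {sorted(unknown)}")
        return cls(
            geometry=build(GeometryConfig, "geometry"),
            composition=build(CompositionConfig, "composition"),
            model=build(ModelConfig, "model"),
            activity=build(ActivitySettings, "activity"),
            execution=build(ExecutionConfig, "execution"),
        )

    def to_yaml(self, path: str | Path | None = None) -> str:
        text = yaml.safe_dump(self.to_dict(), sort_keys=False)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_yaml(cls, source: str | Path) -> "RunConfig":
        path = Path(source)
        text = path.read_text() if path.exists() else str(source)
        data = yaml.safe_load(text)
        if not isinstance(data, dict):
            raise ValueError("config file must hold a mapping of sections")
        return cls.from_dict(data)


def build_layout(config: RunConfig, seed=None) -> EndplateLayout:
    """Place a fresh initial layout according to the configuration."""
    ratios = AreaRatios.from_values(config.composition.initial_ratios)
    counts = apportion_site_counts(
        ratios, config.composition.n_axons, config.geometry.n_sites
    )
    return place_sites(
        counts,
        region_diameter=config.geometry.region_diameter,
        site_diameter=config.geometry.site_diameter,
        min_separation_factor=config.geometry.min_separation_factor,
        seed=seed,
        neighbor_distance=config.geometry.resolved_neighbor_distance(),
    )


def resolve_probs(config: RunConfig) -> VacancyMediatedProbs | None:
    """Transition probabilities implied by the configuration.

    Only the vacancy-mediated variant has constant probabilities to solve;
    the random and equal variants draw theirs inside the engine.
    """
    if config.model.variant != "vacancy_mediated":
        return None
    target = AreaRatios.from_values(config.model.target_ratios)
    return solve_stationary_probabilities(target, config.model.p_vs)


def stage_config(stage: str = "P3", **overrides) -> RunConfig:
    """Canonical configuration for a developmental-stage experiment.

    Newborn (P0) initial layouts with the stationary target taken from the
    named stage.  ``max_iter`` defaults to 400,000 here — large enough that
    replicates at every stage essentially always run to completion.
    Keyword overrides replace whole sections, e.g.
    ``stage_config("P7", execution=ExecutionConfig(n_reps=20))``.
    """
    from .experiments import STAGE_RATIOS  # local import to avoid a cycle

    if stage not in STAGE_RATIOS:
        raise KeyError(f"unknown stage {stage!r}")
    config = RunConfig(
        model=ModelConfig(target_ratios=STAGE_RATIOS[stage].as_tuple()),
        execution=ExecutionConfig(max_iter=400_000),
    )
    return replace(config, **overrides) if overrides else config
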