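"""Scenario configuration: pydantic schema + YAML loading.

A scenario is a set of genome populations of differing vitality, the 2x2
library grid (iDNA/eDNA x repaired/unrepaired), optional racemization
observations, classification thresholds, and one master seed.  Validation
errors carry dotted field paths.
"""

from __future__ import annotations

import math
from typing import Literal, Optional

import yaml
from pydantic import BaseModel, Field, model_validator

from . import simulate as sim
from .classify import Thresholds
from .racemization import ArrheniusParams, celsius_to_kelvin

__all__ = ["ScenarioConfig", "load_config", "default_scenario",
           "ConfigError"]


class ConfigError(ValueError):
    pass


class DamageConfig(BaseModel):
    delta_ss: float = 0.0
    delta_ds: float = 0.0
    q: float = 0.6
    nick_rate: float = 0.0
    blocker_rate: float = 0.0
    frag_mu: float = math.log(200.0)
    frag_sigma: float = 0.5

    def to_params(self) -> sim.DamageParams:
        return sim.DamageParams(**self.model_dump())


class PopulationConfig(BaseModel):
    genome_id: str
    genome_length: int = Field(gt=0)
    gc_fraction: float = Field(gt=0.0, lt=1.0)
    relative_abundance: float = Field(default=1.0, ge=0.0)
    vitality: Literal["living", "dead_intact", "lysed"] = "living"
    damage: DamageConfig = DamageConfig()
    ptr: float = Field(default=1.0, ge=1.0)
    ori_position: int = 0
    ter_position: Optional[int] = None
    leakage: Optional[float] = None  # None -> per-vitality default
    age_yr: float = Field(default=0.0, ge=0.0)

    def to_spec(self) -> sim.PopulationSpec:
        return sim.PopulationSpec(
            genome_id=self.genome_id, genome_length=self.genome_length,
            gc_fraction=self.gc_fraction,
            relative_abundance=self.relative_abundance,
            vitality=self.vitality, damage=self.damage.to_params(),
            ptr=self.ptr, ori_position=self.ori_position,
            ter_position=self.ter_position)


class LibraryConfig(BaseModel):
    fraction: Literal["iDNA", "eDNA"]
    repaired: bool
    read_length: int = Field(default=100, ge=30)
    target_depth: float = Field(default=8.0, ge=0.0)
    repair_efficiency: float = Field(default=1.0, ge=0.0, le=1.0)
    block_prob: float = Field(default=0.9, ge=0.0, le=1.0)
    seq_error_rate: float = Field(default=0.001, ge=0.0, lt=1.0)
    yield_factor: float = Field(default=1.0, gt=0.0, le=1.0)
    max_insert: int = Field(default=500, ge=30)

    def to_spec(self, seed: int) -> sim.LibrarySpec:
        return sim.LibrarySpec(seed=seed, **self.model_dump())


class RacemizationConfig(BaseModel):
    Ea: float = Field(default=101.7, gt=0)
    A: float = Field(default=1.43e15, ge=0)
    T_celsius: float = -7.7
    dl0: float = Field(default=0.0, ge=0.0, lt=1.0)
    ages: dict[str, float] = {}
    observations: dict[str, dict[str, float]] = {}

    def to_params(self) -> ArrheniusParams:
        return ArrheniusParams(Ea=self.Ea, A=self.A,
                               T=celsius_to_kelvin(self.T_celsius))


class ThresholdsConfig(BaseModel):
    damage_max: float = Field(default=0.1, gt=0.0, lt=1.0)
    delta_max: float = Field(default=0.05, gt=0.0, lt=1.0)

    def to_thresholds(self) -> Thresholds:
        return Thresholds(damage_max=self.damage_max,
                          delta_max=self.delta_max)


class ScenarioConfig(BaseModel):
    seed: int = Field(ge=0)
    populations: list[PopulationConfig] = Field(min_length=1)
    libraries: list[LibraryConfig] = Field(min_length=1)
    racemization: Optional[RacemizationConfig] = None
    thresholds: ThresholdsConfig = ThresholdsConfig()
    pool_coverage: float = Field(default=5.0, gt=0.0)  # fragment-pool depth
    grid_bin_size: int = Field(default=1000, ge=100)
    grid_smoothing: int = Field(default=10, ge=1)

    @model_validator(mode="after")
    def _check_library_grid(self) -> "ScenarioConfig":
        for fraction in ("iDNA", "eDNA"):
            for repaired in (True, False):
                n = sum(1 for lib in self.libraries
                        if lib.fraction == fraction and lib.repaired == repaired)
                if n != 1:
                    raise ValueError(
                        f"libraries: need exactly one "
                        f"{'repaired' if repaired else 'unrepaired'} "
                        f"{fraction} library, found {n}")
        return self

    @model_validator(mode="after")
    def _check_abundances(self) -> "ScenarioConfig":
        if sum(p.relative_abundance for p in self.populations) <= 0:
            raise ValueError("populations: abundances must sum to > 0")
        ids = [p.genome_id for p in self.populations]
        if len(set(ids)) != len(ids):
            raise ValueError("populations: genome_id values must be unique")
        return self

    def population_specs(self) -> list[sim.PopulationSpec]:
        return [p.to_spec() for p in self.populations]

    def library_specs(self) -> list[sim.LibrarySpec]:
        return [lib.to_spec(self.seed) for lib in self.libraries]


def load_config(path) -> ScenarioConfig:
    """Load and validate a YAML scenario config."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise ConfigError(f"{path}: config must be a mapping")
    try:
        return ScenarioConfig.model_validate(raw)
    except Exception as exc:  # pydantic.ValidationError
        raise ConfigError(str(exc)) from exc


def default_scenario(seed: int = 0) -> ScenarioConfig:
    """The canonical three-population scenario.

    One living young-stratum population (intact >10 kb fragments, no
    lesions), one intact-dead fossil population and one lysed relic
    population (both with short fragments and strong terminal deamination),
    sequenced as the 2x2 iDNA/eDNA x +/- repair grid, with the permafrost
    racemization block attached.  Leakage 0 keeps the three classes
    separable by construction.
    """
    fossil = DamageConfig(delta_ss=0.3, delta_ds=0.01, q=0.6,
                          nick_rate=0.001, blocker_rate=0.002,
                          frag_mu=math.log(200.0), frag_sigma=0.5)
    living = DamageConfig(delta_ss=0.0, delta_ds=0.0, q=0.6,
                          frag_mu=math.log(15_000.0), frag_sigma=0.35)
    populations = [
        PopulationConfig(genome_id="bin_living", genome_length=50_000,
                         gc_fraction=0.50, vitality="living", damage=living,
                         ptr=1.4, leakage=0.0, age_yr=26_000),
        PopulationConfig(genome_id="bin_fossil", genome_length=50_000,
                         gc_fraction=0.55, vitality="dead_intact",
                         damage=fossil, leakage=0.0, age_yr=100_000),
        PopulationConfig(genome_id="bin_relic", genome_length=50_000,
                         gc_fraction=0.45, vitality="lysed", damage=fossil,
                         leakage=0.0, age_yr=100_000),
    ]
    libraries = [
        LibraryConfig(fraction=f, repaired=r)
        for f in ("iDNA", "eDNA") for r in (False, True)
    ]
    racemization = RacemizationConfig(
        ages={"3.4": 26_000, "5.8": 100_000, "14.8": 100_000},
        observations={
            "3.4": {"dl_bulk": 0.12, "dl_cells": 0.06},
            "5.8": {"dl_bulk": 0.15, "dl_cells": 0.10},
            "14.8": {"dl_bulk": 0.25, "dl_cells": 0.15},
        })
    return ScenarioConfig(seed=seed, populations=populations,
                          libraries=libraries, racemization=racemization)
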