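"""Schema-validated run configuration (YAML/JSON).

Unknown keys are rejected so typos fail loudly; the resolved configuration
(defaults included) is serialized into every results file for provenance.
"""

from __future__ import annotations

from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict, Field

from .ensembles import FitConfig, SearchConfig
from .geometry import MembraneFrame, StateDefinition
from .pre import PREModelParams, SpinLabelLayer


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class MembraneSection(_Strict):
    phosphate_plane_z: float = 0.0
    label_depth_d: float = 8.0
    area_density_sigma: float = 0.05 / 65.0
    include_trans_leaflet: bool = True
    bilayer_phosphate_separation: float = 38.0

    def frame(self) -> MembraneFrame:
        return MembraneFrame(phosphate_plane_z=self.phosphate_plane_z)

    def layer(self) -> SpinLabelLayer:
        return SpinLabelLayer(
            label_depth_d=self.label_depth_d,
            area_density_sigma=self.area_density_sigma,
            include_trans_leaflet=self.include_trans_leaflet,
            bilayer_phosphate_separation=self.bilayer_phosphate_separation,
        )


class PRESection(_Strict):
    tau_pre_ns: float = 5.0
    proton_frequency_mhz: float = 850.0
    r2_dia: float = 20.0
    transfer_delay_t: float = 8e-3

    def params(self) -> PREModelParams:
        return PREModelParams(
            tau_pre_ns=self.tau_pre_ns,
            proton_frequency_mhz=self.proton_frequency_mhz,
            r2_dia=self.r2_dia,
            transfer_delay_t=self.transfer_delay_t,
        )


class StateSection(_Strict):
    name: str
    beta_range: tuple[float, float]
    gamma_range: tuple[float, float]

    def definition(self) -> StateDefinition:
        return StateDefinition(self.name, tuple(self.beta_range), tuple(self.gamma_range))


_DEFAULT_STATE_SECTIONS = [
    StateSection(name="S1", beta_range=(57, 73), gamma_range=(115, 187)),
    StateSection(name="S2", beta_range=(8, 20), gamma_range=(64, 118)),
    StateSection(name="S3", beta_range=(20, 30), gamma_range=(0, 50)),
]


class FitSection(_Strict):
    ensemble_size: int = 16
    repeats: int = 100
    noise_fraction: float = 0.15
    restarts: int = 20
    proposals: int = 2000
    polish: bool = True
    perturb: str = "data"

    def fit_config(self, seed: int) -> FitConfig:
        return FitConfig(
            ensemble_size=self.ensemble_size,
            repeats=self.repeats,
            noise_fraction=self.noise_fraction,
            seed=seed,
            search=SearchConfig(
                restarts=self.restarts, proposals=self.proposals, polish=self.polish
            ),
            perturb=self.perturb,
        )


class RunConfig(_Strict):
    membrane: MembraneSection = Field(default_factory=MembraneSection)
    pre: PRESection = Field(default_factory=PRESection)
    states: list[StateSection] = Field(
        default_factory=lambda: list(_DEFAULT_STATE_SECTIONS)
    )
    fit: FitSection = Field(default_factory=FitSection)
    seed: int = 0
    log_level: str = "INFO"

    def state_definitions(self) -> tuple[StateDefinition, ...]:
        return tuple(s.definition() for s in self.states)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls.model_validate(data)

    def resolved(self) -> dict:
        return self.model_dump()
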