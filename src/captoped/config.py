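"""Run configuration: schema-validated (unknown keys rejected), JSON or YAML."""

from __future__ import annotations

import json
from pathlib import Path

import pydantic
import yaml

from .errors import ConfigError
from .pbpk import CompoundParams
from .renal import DiseaseOverlay


class _Strict(pydantic.BaseModel):
    model_config = pydantic.ConfigDict(extra="forbid")


class CompoundBlock(_Strict):
    name: str = "captopril"
    fa: float = 0.65
    ka: float = 1.5
    lag: float = 0.0
    vss_per_kg: float = 0.8
    kp_scalar: float = 1.0
    cl_iv_adult: float = 49.5
    cl_renal_adult: float = 22.2
    cl_additional_adult: float = 27.3
    fu_plasma: float = 0.70
    reference_weight: float = 70.0
    reference_gfr: float = 120.0
    allometric_exponent: float = 0.75
    central_fraction: float = 0.5
    q_adult: float = 20.0

    def to_params(self) -> CompoundParams:
        return CompoundParams(**self.model_dump())


class OverlayBlock(_Strict):
    nonrenal_cl_fraction: float = 1.0
    fu_multiplier: float = 1.0
    hematocrit_delta: float = 0.0
    gastric_emptying_multiplier: float = 1.0
    kp_scalar: float = 1.0

    def to_overlay(self) -> DiseaseOverlay:
        return DiseaseOverlay(**self.model_dump())


class DiseaseBlock(_Strict):
    healthy: OverlayBlock = OverlayBlock()
    mild: OverlayBlock = OverlayBlock(
        nonrenal_cl_fraction=0.8,
        fu_multiplier=1.05,
        hematocrit_delta=-0.02,
        gastric_emptying_multiplier=1.1,
    )
    moderate: OverlayBlock = OverlayBlock(
        nonrenal_cl_fraction=0.7,
        fu_multiplier=1.10,
        hematocrit_delta=-0.04,
        gastric_emptying_multiplier=1.2,
    )
    severe: OverlayBlock = OverlayBlock(
        nonrenal_cl_fraction=0.6,
        fu_multiplier=1.15,
        hematocrit_delta=-0.06,
        gastric_emptying_multiplier=1.3,
    )

    def to_overlays(self) -> dict[str, DiseaseOverlay]:
        return {
            stage: getattr(self, stage).to_overlay()
            for stage in ("healthy", "mild", "moderate", "severe")
        }


class PopulationBlock(_Strict):
    n_virtual: int = 100  # virtual subjects per reference subject
    weight_cv: float = 0.15
    height_cv: float = 0.04
    hematocrit_cv: float = 0.05
    fu_cv: float = 0.10
    gfr_cv: float = 0.15
    bsa_formula: str = "haycock"


class RegimenBlock(_Strict):
    interval_h: float = 8.0  # q8h is standard pediatric captopril practice
    sampling_times: list[float] = pydantic.Field(
        default_factory=lambda: [0.0, 0.25, 0.5, 0.75, 1.0, 1.5, 2.0, 3.0, 4.0, 6.0, 8.0]
    )
    steady_state_for_mg_per_kg: bool = True  # renal-failure study sampled at steady state


class SolverBlock(_Strict):
    integrator: str = "expm"
    auc_rtol: float = 1e-3
    max_days: float = 90.0


class RunConfig(_Strict):
    """Full pipeline configuration."""

    compound: CompoundBlock = CompoundBlock()
    disease: DiseaseBlock = DiseaseBlock()
    population: PopulationBlock = PopulationBlock()
    regimen: RegimenBlock = RegimenBlock()
    solver: SolverBlock = SolverBlock()
    seed: int = 0
    output_dir: str = "captoped_out"
    demographics_csv: str | None = None  # None -> packaged reference table
    observed_csv: str | None = None  # None -> packaged PK-parameter table


def load_config(path: str | Path | None = None, **overrides) -> RunConfig:
    """Load and validate a JSON/YAML config file; missing path gives defaults."""
    data: dict = {}
    if path is not None:
        text = Path(path).read_text()
        if str(path).endswith((".yaml", ".yml")):
            data = yaml.safe_load(text) or {}
        else:
            data = json.loads(text)
    data.update(overrides)
    try:
        return RunConfig.model_validate(data)
    except pydantic.ValidationError as exc:
        raise ConfigError(str(exc)) from exc
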