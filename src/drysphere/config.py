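"""Validated run configuration, YAML loading and packaged experiment presets.

Configs are YAML with three blocks (``material``, ``program``, ``solver``)
plus an optional ``output`` block.  Validation is strict: unknown keys are
rejected and units are part of the key names (temperatures in Celsius and
lengths in centimetres in the files, kelvin and metres internally, matching
how the experiments are reported).  The packaged presets reproduce the
seven continuous/intermittent drying experiments on spherical Rocha pears
(initial moisture X0, diameter d0, stage temperatures/humidities/speeds and
number of cycles).
"""

from __future__ import annotations

import importlib.resources
from typing import List, Literal, Optional, Union

import yaml
from pydantic import BaseModel, ConfigDict, Field, model_validator

from . import core, schedule, thermophysical as tp

__all__ = [
    "RunConfig",
    "load_config",
    "load_preset",
    "available_presets",
]


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class ArrheniusConfig(_Strict):
    type: Literal["arrhenius"] = "arrhenius"
    D0: float = Field(4.00012e-5, gt=0, description="pre-exponential diffusivity [m2/s]")
    E_over_Rg: float = Field(-3872.63, description="activation temperature E/Rg [K]")

    def build(self) -> tp.ArrheniusLaw:
        return tp.ArrheniusLaw(D0=self.D0, E_over_Rg=self.E_over_Rg)


class PhiDependentConfig(_Strict):
    type: Literal["phi_dependent"] = "phi_dependent"
    D_phi0: float = Field(..., gt=0, description="diffusivity at initial moisture [m2/s]")
    beta: float = Field(0.0, ge=0)
    phi0: float = Field(..., gt=0, le=1)
    phi_inf: float = Field(0.0, ge=0)

    def build(self) -> tp.PhiDependentLaw:
        return tp.PhiDependentLaw(
            D_phi0=self.D_phi0, beta=self.beta, phi0=self.phi0, phi_inf=self.phi_inf
        )


class MaterialConfig(_Strict):
    X0: float = Field(..., gt=0, description="initial dry-basis moisture [kg/kg]")
    d0_cm: float = Field(..., gt=0, description="initial diameter [cm]")
    T0_C: float = Field(15.0, description="initial sample temperature [degC]")
    alpha0: float = Field(1.0, ge=0, description="shrinkage factor (1 = ideal)")
    rho_w: float = Field(1000.0, gt=0)
    rho_s: float = Field(1500.0, gt=0, description="dry-solid density [kg/m3] (generic default)")
    Cp_w: float = Field(4186.0, gt=0)
    Cp_s: float = Field(1600.0, gt=0)
    k_w: float = Field(0.63, gt=0)
    k_s: float = Field(0.21, gt=0)
    isotherm_a: float = Field(0.033, gt=0, description="Henderson a [1/(K (kg/kg)^b)]; synthetic default")
    isotherm_b: float = Field(1.29, gt=0, description="Henderson exponent; synthetic default")
    diffusivity: Union[ArrheniusConfig, PhiDependentConfig] = Field(
        default_factory=ArrheniusConfig, discriminator="type"
    )

    def build(self) -> core.MaterialParams:
        return core.MaterialParams(
            X0=self.X0,
            d0=self.d0_cm / 100.0,
            T0=self.T0_C + 273.15,
            alpha0=self.alpha0,
            composition=tp.ProductComposition(
                rho_w=self.rho_w, rho_s=self.rho_s,
                Cp_w=self.Cp_w, Cp_s=self.Cp_s,
                k_w=self.k_w, k_s=self.k_s,
            ),
            isotherm=tp.HendersonIsotherm(a=self.isotherm_a, b=self.isotherm_b),
            diffusivity=self.diffusivity.build(),
        )


class StageConfig(_Strict):
    label: str = "C"
    duration_h: float = Field(..., gt=0)
    T_inf_C: float
    RH_inf: float = Field(..., ge=0, le=1)
    U_inf: float = Field(..., ge=0)

    def build(self) -> schedule.Stage:
        return schedule.Stage(
            duration_h=self.duration_h,
            T_inf=self.T_inf_C + 273.15,
            RH_inf=self.RH_inf,
            U_inf=self.U_inf,
            label=self.label,
        )


class StartupConfig(_Strict):
    T_inf_C: float = 15.0
    RH_inf: float = Field(0.80, ge=0, le=1)
    U_inf: float = Field(0.1, ge=0)

    def build(self) -> schedule.AmbientConditions:
        return schedule.AmbientConditions(
            T_inf=self.T_inf_C + 273.15, RH_inf=self.RH_inf, U_inf=self.U_inf
        )


class ProgramConfig(_Strict):
    stages: List[StageConfig]
    n_cycles: int = Field(1, ge=1)
    delta_h: float = Field(0.1, gt=0, description="smooth-switch half-width [h]")
    startup: Optional[StartupConfig] = Field(
        default_factory=StartupConfig,
        description="ambient the chamber ramps from at t=0; null disables the switch-on ramp",
    )
    extra_stages: List[StageConfig] = Field(
        default_factory=list, description="optional trailing partial cycle"
    )

    @model_validator(mode="after")
    def _nonempty(self):
        if not self.stages:
            raise ValueError("program needs at least one stage")
        return self

    def build(self) -> schedule.CycleProgram:
        return schedule.CycleProgram(
            stages=tuple(s.build() for s in self.stages),
            n_cycles=self.n_cycles,
            delta_h=self.delta_h,
            startup=self.startup.build() if self.startup is not None else None,
            extra_stages=tuple(s.build() for s in self.extra_stages),
        )


class SolverConfig(_Strict):
    variant: Literal["isothermal", "full", "lumped"] = "full"
    n_nodes: int = Field(200, ge=16)
    grid_stretch: float = Field(0.05, gt=0, le=1)
    rtol: float = Field(1e-4, gt=0)
    atol: float = Field(1e-7, gt=0)
    t_end_h: Optional[float] = Field(None, gt=0)
    output_dt_h: float = Field(0.25, gt=0)
    switch_output_dt_h: float = Field(0.05, gt=0)

    def build(self, variant_override: Optional[str] = None) -> core.SolverSettings:
        return core.SolverSettings(
            variant=variant_override or self.variant,
            n_nodes=self.n_nodes,
            grid_stretch=self.grid_stretch,
            rtol=self.rtol,
            atol=self.atol,
            t_end_h=self.t_end_h,
            output_dt_h=self.output_dt_h,
            switch_output_dt_h=self.switch_output_dt_h,
        )


class OutputConfig(_Strict):
    directory: str = "run_output"
    profile_times_h: Optional[List[float]] = None


class RunConfig(_Strict):
    """One fully validated simulation run."""

    name: str = "run"
    material: MaterialConfig
    program: ProgramConfig
    solver: SolverConfig = Field(default_factory=SolverConfig)
    output: OutputConfig = Field(default_factory=OutputConfig)


def load_config(path) -> RunConfig:
    """Load and validate a YAML run configuration."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise ValueError(f"config file {path} does not contain a mapping")
    return RunConfig.model_validate(raw)


def available_presets() -> List[str]:
    root = importlib.resources.files("drysphere") / "presets"
    return sorted(p.name[:-5] for p in root.iterdir() if p.name.endswith(".yaml"))


def load_preset(name: str) -> RunConfig:
    """Load one of the packaged experiment presets by name (e.g. 'C-50')."""
    root = importlib.resources.files("drysphere") / "presets"
    path = root / f"{name}.yaml"
    try:
        text = path.read_text()
    except FileNotFoundError:
        raise KeyError(
            f"unknown preset {name!r}; available: {', '.join(available_presets())}"
        ) from None
    return RunConfig.model_validate(yaml.safe_load(text))
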